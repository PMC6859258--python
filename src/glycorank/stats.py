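"""Experiment execution and exact statistics.

The experiment asks a single question: does swapping a few distinctive
marker phenotypes into simulated patient profiles raise the frequency
with which the target disease is ranked first? Both arms are run through
the same ranker, rank-1 outcomes are tabulated into a 2×2 contingency
table (arm × rank-1 yes/no), and the arms are compared with a two-sided
Fisher exact test. A profile tied for the top score counts as rank 1 in
both arms, so the tie rule cannot favor either arm.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma
from typing import Dict, List, Optional, Sequence, Tuple

from .corpus import AnnotationCorpus, ICTable
from .errors import ValidationError
from .ontology import OntologyGraph
from .similarity import Ranker
from .simulate import (
    GENERATOR_NAME,
    ExperimentConfig,
    sample_profiles,
    substitute_profiles,
)

# Relative slack for detecting probability ties among tables; exact ties
# computed in floating point land within ~1 ulp of each other, far inside
# this band, while genuinely distinct tables on small margins sit far
# outside it.
_TIE_RTOL = 1e-12


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value by probability ordering.

    Sums the hypergeometric probabilities (computed in log space, so
    arbitrarily large margins are fine) of every table with the observed
    margins whose probability does not exceed the observed table's, with
    a small relative tolerance for ties.
    """
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValidationError(f"2x2 table cells must be non-negative integers: {cells}")
    a, b, c, d = (int(x) for x in cells)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n < 1:
        raise ValidationError("2x2 table grand total must be >= 1")

    def log_choose(m: int, k: int) -> float:
        return lgamma(m + 1) - lgamma(k + 1) - lgamma(m - k + 1)

    denom = log_choose(n, c1)

    def logpmf(k: int) -> float:
        return log_choose(r1, k) + log_choose(r2, c1 - k) - denom

    k_min = max(0, c1 - r2)
    k_max = min(c1, r1)
    l_obs = logpmf(a)
    threshold = l_obs + _TIE_RTOL * (1.0 + abs(l_obs))
    p = sum(exp(lk) for k in range(k_min, k_max + 1) if (lk := logpmf(k)) <= threshold)
    return min(1.0, p)


def term_space_size(n_phenotypes_per_disease: int, n_diseases: int) -> int:
    """Upper bound on distinct marker-phenotype terms a corpus could need:
    one per (phenotype-class, disease) pair."""
    if n_phenotypes_per_disease < 0 or n_diseases < 0:
        raise ValidationError("counts must be non-negative")
    return n_phenotypes_per_disease * n_diseases


@dataclass(frozen=True)
class ExperimentResult:
    """Paired two-arm outcome of one substitution experiment.

    ``table`` is ``[[rank1_subst, non_rank1_subst], [rank1_base,
    non_rank1_base]]``; ``rank1_freq`` maps arm name to rank-1 fraction;
    ``p_value`` is the two-sided Fisher exact p on ``table``.
    """

    per_profile: Tuple[Tuple[int, str, int], ...]  # (base_id, arm, rank of target)
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    rank1_freq: Dict[str, float]
    p_value: float
    config: ExperimentConfig
    generator: str = GENERATOR_NAME


def run_experiment(
    graph: OntologyGraph,
    ic: ICTable,
    corpus: AnnotationCorpus,
    config: ExperimentConfig,
    ranker: Optional[Ranker] = None,
) -> ExperimentResult:
    """Sample both arms, rank every profile, tabulate and test.

    Fully determined by ``config.seed``. A prebuilt :class:`Ranker` may be
    passed to amortize setup across repeated runs on the same corpus.
    """
    config.validate()
    if config.target_disease not in corpus:
        raise ValidationError(f"target disease {config.target_disease!r} not in corpus")
    for t in (*config.pool, *config.substitutes):
        if t not in graph:
            raise ValidationError(f"config term {t!r} not in ontology")
    if ranker is None:
        ranker = Ranker(graph, ic, corpus, aggregation=config.aggregation)
    elif ranker.aggregation != config.aggregation:
        raise ValidationError(
            "ranker aggregation does not match config.aggregation"
        )

    baseline = sample_profiles(config)
    substituted = substitute_profiles(baseline, config)

    per_profile: List[Tuple[int, str, int]] = []
    rank1 = {"baseline": 0, "substituted": 0}
    for prof in (*baseline, *substituted):
        rank = ranker.rank(prof.terms).rank_of[config.target_disease]
        per_profile.append((prof.base_id, prof.arm, rank))
        if rank == 1:
            rank1[prof.arm] += 1

    n = config.n
    table = (
        (rank1["substituted"], n - rank1["substituted"]),
        (rank1["baseline"], n - rank1["baseline"]),
    )
    return ExperimentResult(
        per_profile=tuple(per_profile),
        table=table,
        rank1_freq={arm: rank1[arm] / n for arm in ("baseline", "substituted")},
        p_value=fisher_exact_2x2(table),
        config=config,
    )
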