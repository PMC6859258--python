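"""Simulated patient profiles and the paired substitution design.

A simulated patient is an unweighted set of ``k`` phenotype terms drawn
uniformly without replacement from a disease's pool of ``P`` frequently
associated phenotypes (the shipped defaults, n=1000 profiles of k=10 from
a P=16 pool with m=2 substitutions, mirror the fucosidosis case study
this package was built around). The substituted arm replaces ``m``
randomly chosen members of each baseline profile with ``m`` distinctive
marker terms — molecular glycophenotypes in the motivating use case — so
the two arms are paired: same base profiles, differing in exactly ``m``
members.

Randomness is drawn from NumPy's PCG64 via per-profile substreams keyed
``(master_seed, stream, profile_index)``, so profile ``i`` is identical
regardless of how many profiles are requested, and runs are bit-identical
across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import FrozenSet, List, Sequence, Tuple

import numpy as np

from .corpus import DiseaseId
from .errors import ValidationError
from .ontology import TermId

GENERATOR_NAME = "numpy-pcg64"
_BASELINE_STREAM = 0
_SUBSTITUTION_STREAM = 1


@dataclass(frozen=True)
class PatientProfile:
    """One simulated patient: a set of phenotype terms plus provenance.

    ``base_id`` pairs a substituted profile with its baseline; ``seed_path``
    records generator, master seed, and substream so any single profile can
    be regenerated in isolation.
    """

    terms: FrozenSet[TermId]
    base_id: int
    arm: str  # "baseline" | "substituted"
    seed_path: str


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of one paired substitution experiment.

    ``pool`` is the ordered list of P common phenotypes of the target
    disease; ``substitutes`` the m distinctive marker terms swapped in.
    Defaults follow the fucosidosis setting: 1000 profiles of 10 terms
    sampled from a 16-term pool, 2 substitutions.
    """

    target_disease: DiseaseId
    pool: Tuple[TermId, ...]
    substitutes: Tuple[TermId, ...]
    n: int = 1000
    k: int = 10
    m: int = 2
    seed: int = 0
    paired: bool = True
    aggregation: str = "symmetric"

    def __post_init__(self):
        object.__setattr__(self, "pool", tuple(self.pool))
        object.__setattr__(self, "substitutes", tuple(self.substitutes))

    def validate(self) -> None:
        if len(set(self.pool)) != len(self.pool):
            raise ValidationError("pool contains duplicate terms")
        if self.k > len(self.pool):
            raise ValidationError(
                f"profile size k={self.k} exceeds pool size P={len(self.pool)}"
            )
        if self.m > self.k:
            raise ValidationError(f"substitution count m={self.m} exceeds k={self.k}")
        if len(self.substitutes) != self.m:
            raise ValidationError(
                f"expected m={self.m} substitute terms, got {len(self.substitutes)}"
            )
        if set(self.substitutes) & set(self.pool):
            raise ValidationError("substitute terms must be disjoint from the pool")
        if self.n < 1:
            raise ValidationError("profile count n must be >= 1")


def _profile_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, stream, index))))


def sample_profiles(config: ExperimentConfig) -> List[PatientProfile]:
    """Draw the baseline arm: n independent uniform k-subsets of the pool."""
    config.validate()
    profiles = []
    pool = np.array(config.pool, dtype=object)
    for i in range(config.n):
        rng = _profile_rng(config.seed, _BASELINE_STREAM, i)
        terms = frozenset(rng.choice(pool, size=config.k, replace=False).tolist())
        profiles.append(
            PatientProfile(
                terms=terms,
                base_id=i,
                arm="baseline",
                seed_path=f"{GENERATOR_NAME}:{config.seed}/{_BASELINE_STREAM}/{i}",
            )
        )
    return profiles


def substitute_profiles(
    baseline: Sequence[PatientProfile], config: ExperimentConfig
) -> List[PatientProfile]:
    """Build the substituted arm paired to *baseline*.

    For each baseline profile, m members chosen uniformly without
    replacement are removed and the m substitute terms are added, so the
    symmetric difference with the baseline has exactly 2m members. With
    ``config.paired=False`` a fresh baseline arm is drawn first (from the
    substitution substream) and substituted instead, giving two
    independent arms.
    """
    config.validate()
    source = baseline
    if not config.paired:
        indep = replace(config, seed=config.seed + 1, paired=True)
        source = sample_profiles(indep)
    out = []
    for prof in source:
        rng = _profile_rng(config.seed, _SUBSTITUTION_STREAM, prof.base_id)
        members = sorted(prof.terms)
        drop = rng.choice(len(members), size=config.m, replace=False)
        kept = frozenset(
            t for j, t in enumerate(members) if j not in set(drop.tolist())
        )
        new_terms = kept | set(config.substitutes)
        if len(new_terms) != len(prof.terms):
            raise ValidationError(
                f"substitute term already present in profile {prof.base_id}"
            )
        out.append(
            PatientProfile(
                terms=new_terms,
                base_id=prof.base_id,
                arm="substituted",
                seed_path=f"{GENERATOR_NAME}:{config.seed}/{_SUBSTITUTION_STREAM}/{prof.base_id}",
            )
        )
    return out
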