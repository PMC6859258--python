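"""Seeded synthetic ontologies and annotation corpora.

The generator emulates the statistical structure the substitution
experiment assumes: one *target* disease annotated with a pool of P
common phenotypes — each shared with many of the other diseases, hence
low information content — plus a few deep *marker* terms annotated to
(almost) no other disease, hence high information content. Distinctive
markers stand in for molecular glycophenotypes such as oligosacchariduria:
observable, highly disease-specific abnormalities that ordinary clinical
phenotype pools lack.

``marker_exclusivity`` controls how distinctive the markers are: 0 makes
them unique to the target; at 1 every other disease carries them too and
the substitution experiment has nothing to detect. ``exchangeable=True``
builds a null corpus instead, in which the "markers" are constructed
exactly like pool terms (same ontology stratum, equalized annotation
counts), so substitution should have no systematic effect — the
construction used for calibration tests.

Ontologies are trees of the given depth and branching with a small rate
of extra cross-edges (each pointing to a strictly shallower term, so the
result stays a rooted DAG); trees keep ancestor sets interpretable and
hand-checkable.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Set, Tuple

import numpy as np

from .corpus import AnnotationCorpus
from .errors import ValidationError
from .ontology import OntologyGraph, TermId
from .simulate import ExperimentConfig

TARGET_DISEASE = "SYND:0000"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic ontology + corpus.

    Defaults give the shipped distinctive-marker corpus: a depth-4,
    branching-3 DAG (121 terms), 50 diseases with 10 annotations each, a
    16-term common pool and 2 markers unique to the target — the same
    pool/profile geometry as the fucosidosis case study, at a corpus size
    small enough to regenerate in milliseconds.
    """

    depth: int = 4
    branching: int = 3
    n_diseases: int = 50
    annots_per_disease: int = 10
    pool_size: int = 16
    n_markers: int = 2
    marker_exclusivity: float = 0.0
    cross_edge_rate: float = 0.1
    exchangeable: bool = False
    seed: int = 17

    def validate(self) -> None:
        if self.depth < 2:
            raise ValidationError("ontology depth must be >= 2")
        if self.branching < 1:
            raise ValidationError("branching must be >= 1")
        if self.n_diseases < 2:
            raise ValidationError("need at least a target and one other disease")
        if not (0.0 <= self.marker_exclusivity <= 1.0):
            raise ValidationError("marker_exclusivity must lie in [0, 1]")
        if not (0.0 <= self.cross_edge_rate <= 1.0):
            raise ValidationError("cross_edge_rate must lie in [0, 1]")
        if self.n_markers < 1 or self.pool_size < 1 or self.annots_per_disease < 1:
            raise ValidationError("pool_size, n_markers, annots_per_disease must be >= 1")


def _term_id(i: int) -> TermId:
    return f"SYN:{i:07d}"


def generate_ontology(spec: SyntheticSpec) -> OntologyGraph:
    """Rooted tree of ``depth`` levels and ``branching`` children per node,
    with extra cross-edges to shallower terms at ``cross_edge_rate``.
    Deterministic per ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    terms: Dict[TermId, str] = {}
    parents: Dict[TermId, Set[TermId]] = {}
    level_nodes: List[List[TermId]] = []
    counter = 1
    root = _term_id(counter)
    terms[root] = "synthetic root"
    parents[root] = set()
    level_nodes.append([root])
    for level in range(1, spec.depth + 1):
        nodes = []
        for parent in level_nodes[level - 1]:
            for _ in range(spec.branching):
                counter += 1
                t = _term_id(counter)
                terms[t] = f"synthetic term level {level} #{counter}"
                parents[t] = {parent}
                nodes.append(t)
        level_nodes.append(nodes)
    # Cross-edges always point to a strictly shallower level, preserving
    # acyclicity and the rooted-DAG invariants.
    for level in range(2, spec.depth + 1):
        for t in level_nodes[level]:
            if rng.random() < spec.cross_edge_rate:
                shallow_level = int(rng.integers(1, level))
                extra = level_nodes[shallow_level][
                    int(rng.integers(len(level_nodes[shallow_level])))
                ]
                if extra not in parents[t]:
                    parents[t].add(extra)
    graph = OntologyGraph(
        terms=terms, parents={t: frozenset(ps) for t, ps in parents.items()}
    )
    graph.validate()
    return graph


def _levels(graph: OntologyGraph) -> Dict[TermId, int]:
    """Shortest is_a distance of each term from a root."""
    children: Dict[TermId, List[TermId]] = {t: [] for t in graph.terms}
    for t, ps in graph.parents.items():
        for p in ps:
            children[p].append(t)
    depth = {r: 0 for r in graph.roots}
    queue = deque(sorted(graph.roots))
    while queue:
        t = queue.popleft()
        for c in children[t]:
            if c not in depth:
                depth[c] = depth[t] + 1
                queue.append(c)
    return depth


def generate_corpus(
    graph: OntologyGraph, spec: SyntheticSpec
) -> Tuple[AnnotationCorpus, ExperimentConfig]:
    """Annotate diseases onto *graph* and return a ready experiment config.

    The target disease receives the P pool terms plus the markers; every
    other disease draws ``annots_per_disease`` terms weighted toward the
    pool (so pool terms are common and carry low IC), and each marker is
    additionally shared with ``floor(marker_exclusivity × (n_diseases−1))``
    other diseases. The returned config has ``pool`` = the P common terms
    and ``substitutes`` = the markers, with the package-default profile
    geometry (n=1000, k=10, m=n_markers).
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    levels = _levels(graph)
    children_count: Dict[TermId, int] = {t: 0 for t in graph.terms}
    for t, ps in graph.parents.items():
        for p in ps:
            children_count[p] += 1
    leaves = sorted(t for t, c in children_count.items() if c == 0)
    internal_mid = sorted(
        t
        for t in graph.terms
        if children_count[t] > 0 and levels[t] >= 2
    )

    if spec.exchangeable:
        return _generate_null_corpus(graph, spec, rng, internal_mid)

    if len(internal_mid) < spec.pool_size:
        raise ValidationError(
            f"ontology has only {len(internal_mid)} mid-level internal terms; "
            f"cannot draw a pool of {spec.pool_size}"
        )
    pool = sorted(
        rng.choice(np.array(internal_mid, dtype=object), spec.pool_size, replace=False).tolist()
    )
    max_depth = max(levels[t] for t in leaves)
    marker_candidates = [
        t
        for t in leaves
        if levels[t] == max_depth and not (graph.parents[t] & set(pool))
    ]
    if len(marker_candidates) < spec.n_markers:
        raise ValidationError("not enough deep leaves to serve as markers")
    markers = sorted(
        rng.choice(
            np.array(marker_candidates, dtype=object), spec.n_markers, replace=False
        ).tolist()
    )

    diseases: Dict[str, Tuple[str, FrozenSet[TermId]]] = {
        TARGET_DISEASE: ("synthetic target disease", frozenset(pool) | frozenset(markers))
    }
    # Weighted draws for the other diseases: pool terms are modestly more
    # likely than other internal terms and leaves, which keeps pool ICs low
    # (each pool term shared by many diseases) while leaving the target
    # genuinely contested at baseline — the target wins a middling fraction
    # of draws before substitution, as in the motivating case study.
    other_terms = np.array(
        sorted(t for t in graph.terms if t not in graph.roots and t not in markers),
        dtype=object,
    )
    weights = np.array(
        [3.0 if t in set(pool) else (2.0 if children_count[t] > 0 else 1.0) for t in other_terms]
    )
    weights /= weights.sum()
    n_share = int(np.floor(spec.marker_exclusivity * (spec.n_diseases - 1)))
    other_ids = [f"SYND:{i:04d}" for i in range(1, spec.n_diseases)]
    marker_carriers = {
        m: set(
            rng.choice(np.array(other_ids, dtype=object), n_share, replace=False).tolist()
        )
        for m in markers
    }
    for did in other_ids:
        terms = set(
            rng.choice(other_terms, spec.annots_per_disease, replace=False, p=weights).tolist()
        )
        for m in markers:
            if did in marker_carriers[m]:
                terms.add(m)
        diseases[did] = (f"synthetic disease {did}", frozenset(terms))

    corpus = AnnotationCorpus(diseases)
    corpus.validate(graph)
    config = ExperimentConfig(
        target_disease=TARGET_DISEASE,
        pool=tuple(pool),
        substitutes=tuple(markers),
        m=spec.n_markers,
        seed=spec.seed,
    )
    config.validate()
    return corpus, config


def _generate_null_corpus(
    graph: OntologyGraph,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    internal_mid: List[TermId],
) -> Tuple[AnnotationCorpus, ExperimentConfig]:
    """Exchangeable construction: substitutes are built exactly like pool
    terms, so the substitution experiment has no true effect.

    P + n_markers common terms are drawn from the same mid-depth stratum
    and the whole corpus is generated exactly as in the distinctive mode,
    except that there are no rare marker terms: the target's annotations
    are the common terms themselves, every common term enters the other
    diseases' weighted draws with the same weight, and the m terms labeled
    "substitutes" are an arbitrary subset of the exchangeable commons.
    Substitution then swaps interchangeable terms, and neither arm holds a
    systematic advantage.
    """
    n_common = spec.pool_size + spec.n_markers
    if len(internal_mid) < n_common:
        raise ValidationError(
            f"ontology has only {len(internal_mid)} mid-level internal terms; "
            f"cannot draw {n_common} exchangeable common terms"
        )
    common = rng.choice(
        np.array(internal_mid, dtype=object), n_common, replace=False
    ).tolist()
    pool = tuple(common[: spec.pool_size])
    substitutes = tuple(common[spec.pool_size :])

    diseases: Dict[str, Tuple[str, FrozenSet[TermId]]] = {
        TARGET_DISEASE: ("synthetic target disease", frozenset(common))
    }
    children_count: Dict[TermId, int] = {t: 0 for t in graph.terms}
    for t, ps in graph.parents.items():
        for p in ps:
            children_count[p] += 1
    other_terms = np.array(
        sorted(t for t in graph.terms if t not in graph.roots), dtype=object
    )
    weights = np.array(
        [
            3.0 if t in set(common) else (2.0 if children_count[t] > 0 else 1.0)
            for t in other_terms
        ]
    )
    weights /= weights.sum()
    for i in range(1, spec.n_diseases):
        terms = frozenset(
            rng.choice(
                other_terms, spec.annots_per_disease, replace=False, p=weights
            ).tolist()
        )
        diseases[f"SYND:{i:04d}"] = (f"synthetic disease SYND:{i:04d}", terms)

    corpus = AnnotationCorpus(diseases)
    corpus.validate(graph)
    config = ExperimentConfig(
        target_disease=TARGET_DISEASE,
        pool=pool,
        substitutes=substitutes,
        m=spec.n_markers,
        seed=spec.seed,
    )
    config.validate()
    return corpus, config
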