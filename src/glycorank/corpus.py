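"""Disease→phenotype annotation corpora and corpus-based information content.

Information content (IC) is the specificity currency of the whole package:
``IC(t) = -ln(d(t)/N)`` where ``d(t)`` counts diseases whose *propagated*
annotation set (the union of the reflexive ancestor closures of their
direct terms) contains ``t`` and ``N`` is the corpus size. A term shared
by every disease (a root, typically) has IC 0; a term unique to one
disease has IC ``ln N``. Terms no disease annotates are given the
additive-smoothing ceiling ``ln(N+1)`` instead of infinity so that
arbitrary query terms always yield finite scores.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Dict, FrozenSet, Set, Tuple

from .errors import ValidationError
from .ontology import OntologyGraph, TermId

DiseaseId = str


@dataclass
class AnnotationCorpus:
    """Disease→phenotype associations validated against an ontology.

    ``diseases`` maps each disease id to a ``(label, direct_terms)`` pair;
    ``direct_terms`` are the directly curated annotations, never the
    propagated closure (propagation happens inside IC computation and
    term similarity).
    """

    diseases: Dict[DiseaseId, Tuple[str, FrozenSet[TermId]]]

    @property
    def size(self) -> int:
        return len(self.diseases)

    def __contains__(self, disease: DiseaseId) -> bool:
        return disease in self.diseases

    def label(self, disease: DiseaseId) -> str:
        return self.diseases[disease][0]

    def direct_terms(self, disease: DiseaseId) -> FrozenSet[TermId]:
        return self.diseases[disease][1]

    def validate(self, graph: OntologyGraph) -> None:
        if self.size < 1:
            raise ValidationError("annotation corpus is empty")
        for d, (_, terms) in self.diseases.items():
            if not terms:
                raise ValidationError(f"disease {d!r} has no annotations")
            unknown = sorted(t for t in terms if t not in graph)
            if unknown:
                raise ValidationError(
                    f"disease {d!r} annotated with terms absent from the ontology: "
                    + ", ".join(unknown)
                )

    def propagated_terms(self, graph: OntologyGraph, disease: DiseaseId) -> FrozenSet[TermId]:
        """Union of reflexive ancestor closures of the disease's direct terms."""
        out: Set[TermId] = set()
        for t in self.direct_terms(disease):
            out |= graph.ancestors(t)
        return frozenset(out)


def read_annotations(path, graph: OntologyGraph) -> AnnotationCorpus:
    """Read a disease–phenotype TSV (columns disease_id, disease_label,
    phenotype_id; ``#`` comment lines skipped) and validate it.

    Rows that annotate via an obsolete/alternate id are rejected with an
    error listing the offending rows: annotation files are expected to use
    canonical, current identifiers.
    """
    diseases: Dict[DiseaseId, Tuple[str, Set[TermId]]] = {}
    bad_rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 3:
                raise ValidationError(f"{path}:{lineno}: expected 3 tab-separated columns")
            disease_id, label, term = row[0], row[1], row[2]
            if term in graph.alt_ids or term not in graph:
                bad_rows.append(f"line {lineno}: {disease_id} -> {term}")
                continue
            entry = diseases.setdefault(disease_id, (label, set()))
            entry[1].add(term)
    if bad_rows:
        raise ValidationError(
            "annotation rows reference obsolete, alternate or unknown term ids:\n  "
            + "\n  ".join(bad_rows)
        )
    corpus = AnnotationCorpus(
        {d: (label, frozenset(terms)) for d, (label, terms) in diseases.items()}
    )
    corpus.validate(graph)
    return corpus


def write_annotations(corpus: AnnotationCorpus, path) -> None:
    """Write the TSV dialect :func:`read_annotations` reads."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        fh.write("# disease_id\tdisease_label\tphenotype_id\n")
        for d in sorted(corpus.diseases):
            label, terms = corpus.diseases[d]
            for t in sorted(terms):
                writer.writerow([d, label, t])


@dataclass
class ICTable:
    """Per-term information content in nats.

    ``attested`` lists terms annotated (after propagation) by at least one
    disease; every other term carries the smoothing ceiling ``ln(N+1)``.
    """

    ic: Dict[TermId, float]
    attested: FrozenSet[TermId]
    n_diseases: int

    def __getitem__(self, term: TermId) -> float:
        return self.ic[term]

    def max_attested(self) -> float:
        return max(self.ic[t] for t in self.attested)


def compute_ic(graph: OntologyGraph, corpus: AnnotationCorpus) -> ICTable:
    """Corpus-frequency information content with ancestor propagation.

    See the module docstring for the definition. Raises
    :class:`ValidationError` on an empty corpus.
    """
    import math

    if corpus.size < 1:
        raise ValidationError("cannot compute IC on an empty corpus")
    corpus.validate(graph)
    counts: Dict[TermId, int] = {}
    for d in corpus.diseases:
        for t in corpus.propagated_terms(graph, d):
            counts[t] = counts.get(t, 0) + 1
    n = corpus.size
    ceiling = math.log(n + 1)
    ic = {
        t: -math.log(counts[t] / n) if t in counts else ceiling
        for t in graph.terms
    }
    return ICTable(ic=ic, attested=frozenset(counts), n_diseases=n)
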