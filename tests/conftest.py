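from pathlib import Path

import numpy as np
import pytest

from glycorank import AnnotationCorpus, compute_ic, parse_obo, read_annotations

DATA = Path(__file__).parent / "data"

# Readable aliases for the toy ontology committed in tests/data/toy.obo:
# R is the root; A and B are its children; A1, A2 under A; A1a under A1.
R = "TOY:0000001"
A = "TOY:0000002"
B = "TOY:0000003"
A1 = "TOY:0000004"
A2 = "TOY:0000005"
A1a = "TOY:0000006"


@pytest.fixture(scope="session")
def toy_graph():
    return parse_obo(DATA / "toy.obo")


@pytest.fixture(scope="session")
def toy_corpus(toy_graph):
    return read_annotations(DATA / "toy_annotations.tsv", toy_graph)


@pytest.fixture(scope="session")
def toy_ic(toy_graph, toy_corpus):
    return compute_ic(toy_graph, toy_corpus)


def random_small_corpus(rng: np.random.Generator):
    """A random small ontology (tree, <= ~40 terms) and annotation corpus
    (<= 20 diseases), built directly from primitive draws so it shares no
    code with the synthetic_data generator."""
    from glycorank import OntologyGraph

    n_terms = int(rng.integers(8, 41))
    terms = {f"RND:{i:07d}": f"random term {i}" for i in range(n_terms)}
    ids = sorted(terms)
    parents = {ids[0]: frozenset()}
    for i in range(1, n_terms):
        n_parents = 1 + (rng.random() < 0.15)
        choices = rng.choice(i, size=min(n_parents, i), replace=False)
        parents[ids[i]] = frozenset(ids[j] for j in choices)
    graph = OntologyGraph(terms=terms, parents=parents)
    graph.validate()

    n_dis = int(rng.integers(3, 21))
    non_root = ids[1:]
    while True:
        diseases = {}
        for d in range(n_dis):
            k = int(rng.integers(1, min(8, len(non_root)) + 1))
            annots = frozenset(rng.choice(non_root, size=k, replace=False).tolist())
            diseases[f"RNDD:{d:04d}"] = (f"random disease {d}", annots)
        corpus = AnnotationCorpus(diseases)
        corpus.validate(graph)
        # a disease whose every annotation is shared by all diseases has a
        # zero self-match optimum and is (correctly) unrankable; redraw
        counts = {}
        for d in diseases:
            for t in corpus.propagated_terms(graph, d):
                counts[t] = counts.get(t, 0) + 1
        if all(
            any(counts[t] < n_dis for t in corpus.direct_terms(d)) for d in diseases
        ):
            return graph, corpus
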