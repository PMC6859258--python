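"""Term-pair scoring, profile matching, and disease ranking."""

import math

import numpy as np
import pytest

from glycorank import (
    AnnotationCorpus,
    Ranker,
    ValidationError,
    profile_match,
    rank_diseases,
    term_similarity,
)

from .conftest import A1, A1a, A2, B, random_small_corpus
from .oracles import naive_ranking


class TestTermSimilarity:
    def test_hand_enumerated_pair_a1_a2(self, toy_graph, toy_ic):
        s = term_similarity(toy_graph, toy_ic, A1, A2)
        assert s.jaccard == pytest.approx(0.5)
        assert s.mica_ic == pytest.approx(-math.log(3 / 4))
        assert s.score == pytest.approx(math.sqrt(0.5 * -math.log(3 / 4)))

    def test_hand_enumerated_pair_a1_a1a(self, toy_graph, toy_ic):
        s = term_similarity(toy_graph, toy_ic, A1, A1a)
        assert s.jaccard == pytest.approx(0.75)
        assert s.score == pytest.approx(math.sqrt(0.75 * math.log(2)))

    def test_self_similarity_is_sqrt_ic(self, toy_graph, toy_ic):
        for t in toy_graph.terms:
            s = term_similarity(toy_graph, toy_ic, t, t)
            assert s.jaccard == 1.0
            assert s.score == pytest.approx(math.sqrt(toy_ic[t]))

    def test_symmetric_and_bounded_by_max_attested_ic(self):
        rng = np.random.default_rng(3)
        from glycorank import compute_ic

        for _ in range(10):
            graph, corpus = random_small_corpus(rng)
            ic = compute_ic(graph, corpus)
            attested_bound = math.sqrt(ic.max_attested())
            # unattested terms carry the smoothing ceiling -ln(1/(N+1))
            global_bound = math.sqrt(math.log(corpus.size + 1))
            terms = sorted(graph.terms)
            picks = rng.choice(terms, size=(15, 2))
            for t1, t2 in picks:
                s12 = term_similarity(graph, ic, t1, t2)
                s21 = term_similarity(graph, ic, t2, t1)
                assert s12 == s21
                assert s12.score <= max(attested_bound, global_bound) + 1e-12
                if t1 in ic.attested and t2 in ic.attested:
                    assert s12.score <= attested_bound + 1e-12


class TestProfileMatch:
    def test_self_match_is_100(self, toy_graph, toy_ic, toy_corpus):
        for d in toy_corpus.diseases:
            m = profile_match(
                toy_graph, toy_ic, toy_corpus.direct_terms(d), d, toy_corpus
            )
            assert m.normalized == pytest.approx(100.0)

    def test_root_only_overlap_scores_zero(self, toy_graph, toy_ic, toy_corpus):
        # query B shares only the IC-0 root with D1's annotation A1
        m = profile_match(toy_graph, toy_ic, {B}, "TOYD:0001", toy_corpus)
        assert m.normalized == 0.0

    def test_hand_computed_cross_match(self, toy_graph, toy_ic, toy_corpus):
        # query {A1} against D2 ({A2}): both best-match vectors hold the
        # single pair score; optimum is D2's self-score sqrt(IC(A2))
        m = profile_match(toy_graph, toy_ic, {A1}, "TOYD:0002", toy_corpus)
        pair = math.sqrt(0.5 * -math.log(3 / 4))
        opt = math.sqrt(-math.log(1 / 4))
        assert m.max_score == pytest.approx(pair)
        assert m.avg_score == pytest.approx(pair)
        assert m.normalized == pytest.approx(100.0 * pair / opt)
        assert m.normalized < 100.0

    def test_empty_query_rejected(self, toy_graph, toy_ic, toy_corpus):
        with pytest.raises(ValidationError):
            profile_match(toy_graph, toy_ic, set(), "TOYD:0001", toy_corpus)

    def test_max_at_least_avg(self, toy_graph, toy_ic, toy_corpus):
        m = profile_match(toy_graph, toy_ic, {A1, B}, "TOYD:0004", toy_corpus)
        assert m.max_score >= m.avg_score >= 0.0


class TestRankDiseases:
    def test_self_query_ranks_first(self, toy_graph, toy_ic, toy_corpus):
        r = rank_diseases(
            toy_graph, toy_ic, toy_corpus.direct_terms("TOYD:0003"), toy_corpus
        )
        assert r.rank_of["TOYD:0003"] == 1

    def test_identical_diseases_tie_at_rank_1(self, toy_graph, toy_ic):
        corpus = AnnotationCorpus(
            {
                "TOYD:0010": ("twin 1", frozenset({A1})),
                "TOYD:0011": ("twin 2", frozenset({A1})),
                "TOYD:0012": ("other", frozenset({B})),
            }
        )
        r = rank_diseases(toy_graph, compute_ic_for(toy_graph, corpus), {A1}, corpus)
        assert r.rank_of["TOYD:0010"] == 1
        assert r.rank_of["TOYD:0011"] == 1
        assert r.rank_of["TOYD:0012"] == 3

    def test_rank_counts_strictly_greater_scores(self, toy_graph, toy_ic, toy_corpus):
        r = rank_diseases(toy_graph, toy_ic, {A1}, toy_corpus)
        scores = dict(r.ordered)
        for d, s in scores.items():
            assert r.rank_of[d] == 1 + sum(1 for x in scores.values() if x > s)

    def test_adding_unique_marker_never_worsens_rank(self):
        # weak monotonicity: a high-IC term annotated only to disease d
        # cannot push d down the ranking when added to the query
        rng = np.random.default_rng(23)
        from glycorank import compute_ic

        checked = 0
        for _ in range(20):
            graph, corpus = random_small_corpus(rng)
            ic = compute_ic(graph, corpus)
            ranker = Ranker(graph, ic, corpus)
            all_annotated = {}
            for d in corpus.diseases:
                for t in corpus.direct_terms(d):
                    all_annotated.setdefault(t, set()).add(d)
            unique = [(t, ds) for t, ds in all_annotated.items() if len(ds) == 1]
            if not unique:
                continue
            term, (d,) = unique[0]
            others = sorted(set(all_annotated) - {term})
            if not others:
                continue
            query = set(rng.choice(others, size=min(3, len(others)), replace=False))
            before = ranker.rank(query).rank_of[d]
            after = ranker.rank(query | {term}).rank_of[d]
            assert after <= before
            checked += 1
        assert checked >= 10


class TestOracleAgreement:
    def test_normalized_scores_match_naive_scorer(self):
        rng = np.random.default_rng(41)
        from glycorank import compute_ic

        for _ in range(25):
            graph, corpus = random_small_corpus(rng)
            ic = compute_ic(graph, corpus)
            ranker = Ranker(graph, ic, corpus)
            non_root = sorted(set(graph.terms) - graph.roots)
            query = set(
                rng.choice(non_root, size=min(4, len(non_root)), replace=False)
            )
            ic_map = {t: ic[t] for t in graph.terms}
            oracle = naive_ranking(
                graph.parents,
                ic_map,
                sorted(query),
                {d: set(corpus.direct_terms(d)) for d in corpus.diseases},
            )
            result = ranker.rank(query)
            for d, (o_rank, o_score) in oracle.items():
                got = ranker.profile_match(query, d).normalized
                assert got == pytest.approx(o_score, abs=1e-9)
                assert result.rank_of[d] == o_rank


def compute_ic_for(graph, corpus):
    from glycorank import compute_ic

    return compute_ic(graph, corpus)
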