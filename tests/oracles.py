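"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: ancestor sets by repeated parent
expansion with no caching, profile scores by direct recomputation of every
pairwise term score, and the exact test by integer enumeration of all
admissible tables. None of it shares code with the package paths it
checks.
"""

import math
from math import comb


def naive_ancestors(parents, term):
    """Reflexive transitive closure by repeated parent expansion."""
    closure = {term}
    while True:
        grown = set(closure)
        for t in closure:
            grown |= set(parents[t])
        if grown == closure:
            return closure
        closure = grown


def naive_ic(parents, disease_terms):
    """IC table from a {disease: set(term)} mapping, by materializing every
    disease's propagated set."""
    n = len(disease_terms)
    counts = {}
    for terms in disease_terms.values():
        propagated = set()
        for t in terms:
            propagated |= naive_ancestors(parents, t)
        for t in propagated:
            counts[t] = counts.get(t, 0) + 1
    all_terms = set(parents)
    return {
        t: -math.log(counts[t] / n) if t in counts else math.log(n + 1)
        for t in all_terms
    }


def naive_term_score(parents, ic, t1, t2):
    a1 = naive_ancestors(parents, t1)
    a2 = naive_ancestors(parents, t2)
    common = a1 & a2
    if not common:
        return 0.0
    jacc = len(common) / len(a1 | a2)
    mica = max(ic[a] for a in common)
    return math.sqrt(jacc * mica)


def naive_profile_score(parents, ic, query, disease_terms, symmetric=True):
    """Normalized 0-100 profile score against one disease's direct terms."""
    dterms = sorted(disease_terms)
    bq = [max(naive_term_score(parents, ic, q, d) for d in dterms) for q in query]
    best = list(bq)
    if symmetric:
        best += [max(naive_term_score(parents, ic, d, q) for q in query) for d in dterms]
    diag = [naive_term_score(parents, ic, d, d) for d in dterms]
    opt_max, opt_avg = max(diag), sum(diag) / len(diag)
    raw_max, raw_avg = max(best), sum(best) / len(best)
    score = 100.0 * (raw_max / opt_max + raw_avg / opt_avg) / 2.0
    return min(100.0, max(0.0, score))


def naive_ranking(parents, ic, query, corpus_terms, symmetric=True):
    """{disease: (rank, score)} with ties sharing the best rank."""
    scores = {
        d: naive_profile_score(parents, ic, query, terms, symmetric)
        for d, terms in corpus_terms.items()
    }
    return {
        d: (1 + sum(1 for other in scores.values() if other > s), s)
        for d, s in scores.items()
    }


def enumerate_fisher(table):
    """Two-sided Fisher exact p by exact integer enumeration.

    All tables sharing the observed margins have hypergeometric
    probabilities with the common denominator C(n, c1), so the
    probability-ordering comparison can be done on integer numerators —
    no floating point, ties exact.
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    obs = comb(r1, a) * comb(r2, c1 - a)
    total = 0
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        num = comb(r1, k) * comb(r2, c1 - k)
        if num <= obs:
            total += num
    return total / comb(n, c1)
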