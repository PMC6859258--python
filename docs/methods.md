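# Methods

## The question the package operationalizes

Rare-disease diagnosis by phenotype matching encodes a patient as a set of
ontology terms and ranks candidate diseases by semantic similarity between
the patient profile and each disease's curated phenotype annotations.
Molecular phenotypes such as glycan abnormalities (oligosacchariduria,
decreased fucosidase activity, …) are observable, highly disease-specific,
and sparsely represented in clinical phenotype vocabularies. The package
implements a controlled simulation that quantifies their diagnostic value:
draw many simulated patients from a target disease's pool of common
phenotypes, swap a few pool terms for distinctive molecular markers in a
paired second arm, rank every profile against the whole disease corpus,
and compare the two arms' rank-1 frequencies with an exact test.

## Similarity model

Term-to-term similarity is the geometric mean of two standard ingredients
computed over reflexive `is_a` ancestor closures:

    score(t1, t2) = sqrt( simJ(t1, t2) · IC(MICA(t1, t2)) )

where `simJ` is the Jaccard index of the ancestor sets and `MICA` is the
common ancestor with maximal information content. IC is corpus-based:
`IC(t) = −ln(d(t)/N)` with `d(t)` the number of diseases whose propagated
annotation set contains `t` and `N` the corpus size. Only `is_a` edges
contribute; other OBO relationship types are ignored because profile
matching here is purely subclass-based. Reflexive closures make a term's
self-similarity `sqrt(IC(t))` and its self-MICA itself.

A profile is matched to a disease by symmetric best-match aggregation:
each query term keeps its best score against the disease's *direct*
annotations and vice versa (direct, not propagated, on the disease side —
propagation already acts inside the term scores, and propagating the
annotation side too would double-count shallow terms). The maximum and
mean of the concatenated best-match vectors are each normalized by the
disease's self-match optimum (its diagonal scores `sqrt(IC)`), averaged,
scaled to 0–100 and clipped. A query identical to the disease's direct
annotation set scores exactly 100. A query-directional aggregation
(query-side vector only) is available behind the `aggregation` flag; any
experiment applies one setting to both arms, so the comparison is fair
either way.

Ranking sorts normalized scores descending with ties broken
deterministically by disease id for presentation; the reported rank is
`1 + #{strictly better diseases}`, so tied diseases share the best rank
and a tied-first target counts as rank 1 in both arms.

### Numerical choices

- Terms never annotated (even after propagation) receive the additive
  smoothing ceiling `−ln(1/(N+1))` instead of infinite IC, so arbitrary
  query terms always produce finite scores.
- A disease whose every annotation has zero IC (e.g. only the root) has a
  zero self-match optimum and is rejected as unrankable rather than
  silently scored.
- Two terms with no common ancestor (possible with multiple roots) score
  0 by definition; no artificial super-root is added.

## Exact test

The two arms' rank-1 counts form a 2×2 table compared with a two-sided
Fisher exact test under the probability-ordering definition: the p-value
sums hypergeometric probabilities of all tables with the observed margins
whose probability does not exceed the observed one. Probabilities are
evaluated in log space (`lgamma`), so margins in the thousands are exact;
ties are detected with a relative tolerance of 1e-12 on the log
probability, wide enough to absorb floating-point noise between exactly
tied tables and far below the gap between genuinely distinct ones. Tests
cross-check against full-margin integer enumeration (exact arithmetic)
and against an independent library implementation.

## Simulation design

Profiles are unweighted term sets, matching the motivating study: no
phenotype frequency, onset or severity modeling. Defaults mirror that
study's fucosidosis setting: n=1000 profiles per arm, each a uniform
without-replacement draw of k=10 from a P=16-term pool, with m=2
substitutions. (The study's figure caption mentions 18 listed phenotypes
while its text samples 10 of 16; the package follows the text and leaves
P configurable.) The substituted arm is paired: the same base profiles
with m uniformly chosen members replaced by the marker terms, so the two
arms differ in exactly m members per profile. An unpaired mode (fresh
independent bases) exists behind a flag.

Randomness flows from a single master seed through NumPy PCG64 with
per-profile substreams keyed `(seed, stream, profile_index)`: profile i
is identical no matter how many profiles are requested, and runs are
bit-identical across platforms. Outputs record the generator name and
seed path.

## Synthetic corpus generator

The generator emulates the statistical structure of the real HPO + Monarch
setting at a size that regenerates in milliseconds: a depth-4,
branching-3 rooted tree (121 terms) with a 10% rate of cross-edges to
strictly shallower terms (keeping a rooted DAG whose ancestor sets remain
hand-checkable), and 50 diseases with 10 annotations each. The target
disease carries P=16 mid-level pool terms plus 2 deep leaf markers;
`marker_exclusivity` controls the fraction of other diseases sharing each
marker (0 → unique to the target, IC = ln N). Other diseases draw
annotations weighted 3 : 2 : 1 (pool : other internal : leaf).

The weights were chosen so the shipped corpus reproduces the *geometry*
of the published fucosidosis experiment: pool terms are shared by roughly
a third of the corpus (IC ≈ 1 nat) while markers sit at the IC ceiling
(ln 50 ≈ 3.9), leaving the target genuinely contested at baseline
(rank-1 ≈ 0.5–0.6) and near ceiling after substitution — the same
mid-range-to-high movement the published analysis reports (53% → 82%),
though the absolute numbers on this 50-disease synthetic corpus are not
comparable to the real 7000-disease corpus and are not treated as such.

What the generator does not emulate: real HPO term labels or depth
distribution, realistic disease-disease phenotype correlation, annotation
noise, or glycan chemistry. Passing tests therefore demonstrate that the
pipeline recovers a designed effect under the assumed structure, not that
it reproduces the published percentages on real data.

### Exchangeable null mode

For calibration, `exchangeable=True` builds a corpus in which the
"substitutes" are constructed exactly like pool terms: P+m common terms
are drawn from the same mid-depth stratum, all are annotated to the
target, all enter the other diseases' weighted draws at the same weight,
and the m terms labeled substitutes are an arbitrary subset. Substitution
then swaps interchangeable terms and neither arm holds a systematic
advantage; across seeds the arm difference is ~0 and the exact test is
(conservatively) calibrated.

One property of this construction is worth stating plainly: because the
target's annotations are exactly the common terms, with no rare markers
penalizing its self-match optimum, the target sits at or near the rank-1
ceiling in both arms. The null check therefore verifies that the pipeline
introduces no spurious arm difference under exchangeability; it is not a
power analysis. Contested-baseline null designs were examined and
rejected: whenever the ranking is sensitive to *which* common terms are
substituted, the finitely realized corpus leaves the fixed substitute
pair with idiosyncratic co-occurrence advantages, and the arms differ
systematically even though the construction is exchangeable in
distribution — a real effect of the realized corpus, not a test
miscalibration.

## Problem sizes used in the shipped checks

Oracle-agreement checks run 200 random corpora of ≤ 20 diseases and ≤ 50
terms against naive brute-force scorers (1e-9 agreement) and 1000 random
2×2 tables with totals ≤ 200 against exact enumeration (1e-10). The
effect-direction check runs 20 master seeds at n=1000 on the shipped
corpus; the specificity check (markers vs their parents) runs 20 seeds at
n=300; the null calibration runs 20 seeds at n=200 with the corpus
regenerated per seed. These sizes make the full suite complete in a few
minutes on one CPU while keeping every binomial standard error far
smaller than the effects asserted.

## Reproducing the published numbers

The published values (rank-1 82% with vs 53% without glycophenotypes,
Fisher exact p = 8.5e-47) depend on a specific, unversioned HPO release
and Monarch annotation snapshot. Reproducing them requires downloading
`hp.obo` and a Monarch disease–phenotype annotation export, converting
the latter to the three-column TSV this package reads, configuring
fucosidosis (MONDO:0009254) as the target with its 16 most frequent
phenotypes as the pool and two annotated glycophenotypes as substitutes,
and running `glycorank experiment`. The package asserts the direction and
statistical machinery of that result, never the snapshot-dependent
percentages.

## Known limitations

- Only `is_a` semantics; no OWL reasoning, cross-ontology bridging, or
  logical definitions.
- Similarity formula variants (Resnik-only, Lin, asymmetric OWLSim
  configurations) are out of scope except for the query-directional
  aggregation flag.
- The ranking engine materializes ancestor incidence against the corpus
  term universe; it is sized for corpora of up to a few thousand
  annotation terms, not for all-vs-all similarity over a full 17k-term
  ontology.
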