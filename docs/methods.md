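# Methods

## Model and procedure

The pipeline asks, for one genetic classification at a time: within each
histological tumor type, are the protein-expression profiles of cases in
different genetic classes distinguishable, which proteins distinguish
them, and is the same effect present with the same direction in another
histotype?

Stages, in order:

1. **Batch screen** (optional): per histotype, remove batches until the
   Dispersion Separability Criterion is below threshold.
2. **Classification**: assign each case a class label (three-gene scheme,
   binary actionable-variant filter, nearest mutational neighbor, or an
   externally supplied table).
3. **Discriminability**: for every unordered class pair within every
   histotype where both groups have ≥ `min_group` cases, compute the
   energy distance, a Monte-Carlo permutation p-value, and BH-adjusted
   significance across all subtests of the classification.
4. **Characteristic proteins**: per-protein contribution decomposition
   with a dynamic noise threshold, for significant subtests.
5. **Cross-cancer effects**: directional characteristic-protein overlap
   between same-class-pair subtests in different histotypes, hypergeometric
   upper-tail test, BH across candidates.
6. **Scores**: classification effectivity score (percent significant
   subtests) globally, per class and per histotype.

## Energy distance and its null behavior

The two-group statistic is the raw pair-sum form

    de = Σ within-A distances + Σ within-B distances − 2 Σ cross distances,

with Euclidean distance in protein space. Note the term counts:
C(i,2) + C(j,2) within-pairs versus i·j cross-pairs, so under the null
E[de] = ((i−j)² − 2ij − (i+j))/2 · E[d], which is far from zero for
realistic group sizes. This is harmless for the permutation test — random
re-splits preserve (i, j), so the bias cancels — and the reported
`s_dis = de/(i·j)` is simply a size-normalized convention (the original
study reports normalized scores without defining the normalization; raw
`de` is always reported alongside).

The Monte-Carlo p-value is the frequency of permuted splits with
`de_perm ≤ de_obs` (ties count; an optional `(r+1)/(n+1)` estimator is
available behind the `pseudocount` flag, the default reports the raw
frequency and can print p = 0). Splits are drawn uniformly from a
per-subtest generator seeded by (master seed, subtest index), so any
subtest is reproducible in isolation. The default permutation count is
10⁶; tests and examples scale this down (10³–10⁴) since p-value
resolution, not correctness, is what changes.

## Contribution centering (a deliberate deviation)

Per-protein contributions evaluate the same sum with the 1-D distance
|x_k − y_k|. Applied literally, the size bias above makes every
contribution negative whenever ((i−j)² − 2ij − (i+j)) < 0 — i.e. for
essentially all realistic group sizes — so the dynamic threshold ("largest
positive contribution") would be zero and nearly the whole panel would be
called characteristic. That contradicts the intended semantics of the
threshold as a noise-floor estimate, and small published characteristic
sets demonstrate the intended behavior is a roughly zero-centered noise
distribution.

`protein_contributions` therefore centers each contribution at its exact
permutation expectation, which has the closed form

    E_perm[c_k] = ((i−j)² − 2ij − (i+j))/2 · mean pooled pairwise |Δx_k|,

before applying the threshold rule (`center="permutation-mean"`, the
default; `center="none"` gives the literal reading). Raw and centered
values are both reported. The centered null is still left-skewed (an
energy-type statistic can be arbitrarily negative when a random split
happens to separate the values, but only mildly positive), so near exact
group balance the max-positive threshold admits a small number of false
characteristic calls (~10 of 115 null proteins at i = j = 30 in
simulation); planted effects of 3σ are recovered with perfect
direction-matched recall. Directions are assigned by group-mean
comparison; a protein with exactly equal group means is excluded from
both direction sets and logged.

## Cross-cancer overlap test

With direction-matched intersection count `ni` and characteristic-set
sizes `n_A`, `n_B` over a panel of `N` proteins, the p-value is
P(X ≥ ni) for X hypergeometric (population N, n_A marked, n_B drawn) —
the one-tailed Fisher probability of the corresponding 2×2 table. The
universe defaults to the panel width actually present in the data rather
than a hard-coded 120. Candidates require BH-significance of both member
subtests; candidates with `ni = 0` stay in the BH family with p = 1 so
the family size is deterministic; an effect is reported when adjusted
p < α and `ni ≥ 1`.

## Batch screen

DSC = S_b/S_w with S_b = √(Σ_k (n_k/N)‖μ_k−μ‖²) and
S_w = √(Σ_k (n_k/N)(1/n_k)Σ_{i∈k}‖x_i−μ_k‖²); a single batch yields
DSC = 0 with p = 1, and zero within-batch dispersion is an error. The
permutation p is the fraction of label shuffles with DSC ≥ observed
(default 1000 shuffles). The greedy screen removes, per round, the batch
whose removal minimizes the remainder's DSC. The published stopping
condition is the conjunction "DSC < 0.3 and p < 0.05"; read literally it
keeps removing while batch structure is *non*-significant, which is
arguably inverted (a low p flags a strong batch effect). The literal
conjunction is the default (`stop_rule="literal"`); the disjunctive
reading — stop when DSC < 0.3 or when p ≥ 0.05 — is available as
`stop_rule="lenient"`, and the report records which condition fired.
Batches are removed, never corrected.

## Classifications

- **Three-gene complexity reduction**: class = 4·[TP53 mutated] +
  2·[TTN mutated] + [BRAF mutated], classes 0–7.
- **Actionable-variant filters**: one gene plus one rule — any nonsilent
  mutation, exact protein-change list, protein-change prefix (e.g. "V600"
  matches V600E/V600K after stripping the "p." prefix), or copy-number
  amplification. Binary classes mutated/wildtype.
- **Nearest mutational neighbor**: each case is labeled "to&lt;HISTOTYPE&gt;"
  of its nearest other case by Jaccard distance on binary gene vectors
  (Euclidean optional; the metric of the original neighbor analysis is not
  published, so Jaccard is this package's documented default). Exact
  distance ties resolve to the lowest case ordinal; two empty profiles are
  defined to be at distance 0 and logged.
- **Published class tables** are ingested as-is; their construction is out
  of scope.

"Nonsilent" defaults to variant classifications outside
{Silent, Intron, 3'UTR, 5'UTR, IGR, RNA} and is configurable — the
original mutation-calling filter is not public.

## Synthetic data

The generator emulates the study-scale inputs: default 30 histotypes ×
120 cases (≈3600 cases, near the 3590 analyzed), a 120-protein panel,
per-protein noise σ = 1 on normalized expression, histotype base profiles
drawn once per seed from a spherical Gaussian with scale 1 (the same
order as the noise, which in 120 dimensions already yields the strong
histotype specificity seen in real RPPA data), a 5% background mutation
rate, and drivers specified as (gene, histotypes, frequency, signed
per-protein additive effects, mutation-or-amplification, optional sign
flip per histotype). Batch structure is planted as per-batch Gaussian
mean shifts.

Effects are additive mean shifts only — the statistics under test are
location-sensitive, so this is the minimal adequate model. Not emulated:
RPPA slide/spatial noise structure, correlated protein networks beyond
the planted effect vectors, subclonality, missing data. A green test on
synthetic data therefore establishes correctness of the statistical
machinery and recoverability of planted location effects, not robustness
to real-data artifacts.

## Numerical choices

- Tie handling: permuted `de` within 1e-9·max(1, |de_obs|) of the
  observed value counts as ≤ (the event includes equality).
- BH adjustment is the standard step-up with enforced monotonicity
  (delegated to statsmodels); the family is all subtests of one
  classification by default, per-histotype behind a flag.
- Seeds: every stochastic component takes an explicit seed; subtest
  streams derive from `SeedSequence([seed, subtest_index])`.
- Alignment rejects missing expression values rather than imputing; the
  reference pan-cancer matrix is complete and the method defines no
  imputation.
- MAF-like mutation tables list mutated cases only; the pipeline treats
  the annotation case list as the mutation-assayed universe so wild-type
  cases are not dropped at alignment.

## Known limitations

- The published headline figures that depend on the full TCGA/TCPA cohort
  (45%/94% neighbor consistency, printed `s_dis`/`s_rand` magnitudes,
  per-gene discriminability calls) cannot be reproduced or certified
  here: they require the original data, the unpublished neighbor metric,
  and an unpublished score normalization.
- The dynamic-threshold rule has an intrinsic false-call floor near
  balanced group sizes (see contribution centering above).
- Monte-Carlo p-values at the default 10⁶ permutations resolve to 1e-6;
  printed "p = 0.0" means below resolution, not exactly zero.
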