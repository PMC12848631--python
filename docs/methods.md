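# Methods

## Connectivity construction and edge indexing

A subject's connectome is the Fisher z-transform (atanh) of the node-by-node
Pearson correlation matrix of parcel mean time courses. The diagonal is
stored as exactly zero and excluded everywhere. Node ids are 1-based (atlas
convention); linear edge indices are 0-based, row-major over the strict
upper triangle — stated once in `connectome.EdgeIndexMap` and used by every
module.

Numerical choices:

* |r| ≥ 1 − 1e−12 between two nodes is an **error**, not a clamp: the
  Fisher z is infinite there and a silently clamped value would hide a
  degenerate input (duplicated or constant node time courses).
* Matrices read from disk are validated as symmetric within 1e−10 and
  rejected otherwise — asymmetric inputs are never averaged into shape.
* Zero-variance nodes are an error at correlation time, named by node id.

## The CPM estimator

Per LOOCV fold the training subjects' edges are correlated with behavior,
thresholded at two-sided p < α_edge (default .01, exact t transform, never
a normal approximation), split by sign, summed into one network strength
per tail, and fitted by univariate OLS (the protocol's default model; a
two-predictor variant is deliberately out of scope). The held-out subject
is predicted from its own strength under the training mask.

* **Empty training mask** → the fold predicts the training mean of y and is
  flagged, keeping the prediction vector complete instead of dropping
  subjects.
* **Zero-variance edges** get r = 0, p = 1 (never selected) with a warning
  rather than an error, because permuted labels can create degenerate
  folds.
* **Selection frequency** uses the number of folds (= n) as denominator;
  the robust network takes frequency ≥ 0.5 *inclusive* ("50% or more").
* **Ties** in the Spearman evaluation use average ranks.

Two implementations of the fold loop coexist: the analysis path recomputes
every fold's statistics directly on the n − 1 training subjects, which
makes a held-out prediction bit-for-bit independent of that subject's own
score (the no-leakage property is exact, not just to rounding); the
permutation path downdates cohort-level sums, which is algebraically
identical and roughly an order of magnitude faster. Their equivalence is
pinned by a nested-loop reference test at 1e−10.

The permutation p uses the add-one convention (1 + #{ρ_perm ≥ ρ_obs}) /
(1 + B), which is never zero and finite-sample valid; the plain
proportion is available via `add_one=False`. Permutations are sampled
uniformly with replacement over the permutation group from a dedicated
seed stream. Under null data the LOOCV ρ is slightly left-skewed (a
training mean anti-correlates with the held-out value when masks are
empty); the permutation test is exchangeability-based and stays calibrated
regardless, which the test suite checks against the binomial band at
α = .05 over 200 null cohorts with B = 199 (scaled down from the
inference default B = 5000 to keep the run in minutes; calibration does
not depend on B beyond p-value granularity).

## Synthetic connectome cohorts

Edges are generated **directly in Fisher-z space** — not through simulated
BOLD time series — because that gives exact control of the planted effect
size; a separate helper produces node time series with a shared latent
signal so the correlation → Fisher-z path is exercised end to end. Per
subject a latent trait u ~ N(0,1) drives planted edges
(background ± γ·u + edge noise) and behavior (β·u + score noise); all
other edges are exchangeable background noise.

Defaults (the documented study conditions of the test suite): 60 subjects,
60 nodes, 15 positive + 15 negative planted edges, background Fisher z
0.3 ± 0.15 (typical resting-state magnitudes), γ = 0.1 against edge noise
0.05, β = 3 against unit score noise. These give per-edge |r| with
behavior of ≈ 0.85 on planted edges — a deliberately clear signal: the
suite checks *recovery machinery* (recall ≥ 0.8, precision ≥ 0.5, ρ ≥ 0.5),
not the detection limit. A real 268-node cohort has ~36 k edges, spatially
autocorrelated parcels and far weaker coupling; passing these tests shows
the estimator is correct, not that a real study of this size would reach
similar ρ. One global seed expands into per-purpose substreams (edge
placement, latent traits, per-subject matrices, behavior) so enlarging the
cohort never perturbs earlier draws, and fixture files are byte-identical
across runs at the same seed.

## Synthetic diary trials

Each of 2 × 60 subjects contributes 28 baseline and 28 treatment days.
Headache days are Bernoulli draws at baseline rate 7/28 per day, scaled in
treatment by a per-arm multiplicative effect — defaults 0.55 (real) and
0.80 (sham), chosen once to give an arm contrast of ≈ 1.6 migraine days,
in the range reported for effective acupuncture against sham. Headache
days carry a duration (≥ 4 h with probability 0.85, exponential excess
with mean 4 h), an ICHD-3 flag (0.95), a VAS score, and a medication class
(migraine-specific 0.5, else nonspecific 0.3). Day-level missingness
(0.02) blanks the clinical fields of a row; dropout (0.05) truncates the
treatment diary at a uniform random day and blanks the subject's score
changes. Eligibility mirrors the trial population: baselines are resampled
until they contain ≥ 2 migraine days, so a zero baseline MMD downstream is
treated as a data error. The generator does not model weekly cycles,
attack clustering (serial correlation), or informative missingness — so
the MCAR-style imputation below is exactly right for the generator and
only an approximation for real diaries.

VAS is generated per attack day; since a per-period aggregation convention
is not part of the endpoint definitions, subject-level VAS change scores
are generated directly, and both worst-attack and mean aggregations can be
derived from the diary by the user.

## Endpoint rules

* Migraine day: (headache ∧ duration ≥ 4 h ∧ ICHD-3) ∨ migraine-specific
  medication use. The 4-hour and 50%-responder boundaries are inclusive.
* A medication-only migraine day also counts toward MHD (headache days),
  an explicit assumption — MHD lacks a printed definition — which keeps
  MMD ≤ MHD invariant.
* Proration (14 ≤ observed < 28: counts × 28/observed) yields non-integer
  day counts that are carried as real values into the statistics; the
  responder ratio uses prorated values on both sides. Proration is applied
  to baseline and treatment periods separately.
* Multiple imputation draws missing endpoint changes per arm from a normal
  model with parameter uncertainty (variance from its scaled inverse-χ²
  posterior, mean from its conditional normal), m = 10 by default, pooled
  by Rubin's rules with Barnard–Rubin-style df. This is a deliberately
  simple, clearly versioned model intended to be swapped for a
  study-specific one.

## Trial statistics

* Hodges–Lehmann estimate: median of all n·m pairwise between-arm
  differences. CI by inversion of the rank-sum test — order statistics of
  the sorted pairwise differences at the Wilcoxon critical values, using
  the exact U null distribution (dynamic programming over the classic
  recurrence) for n·m ≤ 400 and the normal approximation beyond. The
  two-sided p is exact (2·min of the tail probabilities) when there are no
  ties and n·m ≤ 400, otherwise the tie-corrected asymptotic Mann–Whitney
  p with continuity correction.
* t tests default to Welch (unequal variances); single-value "groups" are
  accepted as degenerate summaries so printed per-arm means can be
  differenced, with NaN inference.
* Responder odds ratios come from a maximum-likelihood logistic fit with
  Wald CIs; complete separation raises an error directing to exact
  methods rather than returning a divergent estimate.
* Bang Blinding Index: (correct − incorrect)/total per arm with "unknown"
  answers in the denominator, Wald CI from the multinomial variance of
  p_c − p_i.
* Percentages are formatted to one decimal with ties rounded away from
  zero, matching the reporting convention of the trial literature.
* Secondary endpoints carry an `exploratory` flag: no multiplicity
  adjustment is applied.

### Sample-size helper

`power_two_sample_t` iterates n = (t_{1−α/2} + t_{1−β})²(σ₁² + σ₂²)/Δ²
with Welch df. For the published design inputs (means 2.2 vs 1.6, SDs
2.0/3.0, α = .05, power .80) it returns **285 per group**, not the 54
total reported for those inputs; the test that produced 54 is not
derivable from the stated quantities under any standard two-sample
formula, so the helper documents its own answer and makes no attempt to
match. (54 per group would correspond to a much larger standardized
effect, e.g. roughly 0.54 SD.)

## Problem sizes and determinism

Simulation-based checks run at sizes that finish in minutes on one CPU:
calibration uses 200 replicates × B = 199 at 40 subjects/60 nodes;
recovery uses the 60/60 defaults; trial sign recovery uses 100 replicates
at 60 per arm. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` substreams; every command logs its parameters
and input checksums, and identical seeds reproduce identical outputs
byte for byte (metadata timestamps aside).

## Known limitations

* No fMRI preprocessing, parcellation, or hemodynamic simulation: node
  time series / connectivity matrices are taken as given.
* LOOCV only; k-fold and split-half schemes are out of scope, as are
  covariate-adjusted or multi-behavior models.
* The imputation model conditions on arm only, not on baseline severity.
* The synthetic generators are stationarity-and-independence idealizations
  of real cohorts (no spatial autocorrelation of edges, no attack
  clustering); conclusions from passing tests are about algorithmic
  correctness, not about expected effect sizes in real data.
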