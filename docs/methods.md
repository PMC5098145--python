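# Methods

This note records the statistical model behind each layer, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical conventions that make results reproducible.

## Survival primitives

Outcomes are right-censored pairs (tᵢ, δᵢ) with tᵢ > 0 and δᵢ = 1 for
an observed death. Time units are opaque reals (days by convention);
zero or negative times are rejected rather than nudged, since a zero
survival time is a data error, not a boundary case.

**Kaplan–Meier.** The product-limit estimator Ŝ(t) = Π_{τⱼ ≤ t}
(1 − dⱼ/nⱼ) over distinct event times τⱼ; censored-only times affect
the at-risk counts only.

**Log-rank.** The standard k-sample test: per event time, observed
minus hypergeometric-expected deaths per group, with the usual
covariance Vgh = Σⱼ dⱼ (nⱼ−dⱼ)/(nⱼ−1) · pgⱼ(δgh − phⱼ); the statistic
is the quadratic form over the first k−1 groups and p comes from the
χ²(k−1) upper tail. For tiny cohorts a seeded label-permutation
p-value is available (`n_permutations=`), since the asymptotic
approximation is doubtful below a few dozen events.

**Binary Cox.** The single-binary-covariate partial likelihood is
maximized by Newton–Raphson from β₀ = 0 with |Δβ| < 1e-8 stopping and
at most 100 iterations; steps are clipped to ±5 to keep early
iterations stable. Ties use the Breslow approximation by default
because its closed form is directly verifiable against a brute-force
likelihood grid; the Efron correction is available (`ties="efron"`) and
is what the test suite compares against lifelines to 1e-6. Under
complete separation the likelihood has no interior maximum; β is then
capped at ±20 and flagged (`separation=True`) with a warning rather
than raising, so a cutoff scan can skip degenerate splits gracefully.
The Wald p-value is 2(1 − Φ(|β|/se)) with se from the observed
information at β̂.

These routines are implemented in-package rather than delegated to a
survival library because the cutoff scan and the threshold search below
perform thousands of small fits; the array-based implementation keeps a
full signature fit in seconds. lifelines serves as an independent
oracle in the tests, never as the implementation.

## Univariate cutoff classifier (1D-DDg)

Candidate cutoffs are midpoints between consecutive distinct sorted
values, restricted so each side keeps at least ⌈f·M⌉ patients. The
default `min_fraction` f = 0.05 mirrors the packaged reference
signature, whose smallest subgroup is 21/349 ≈ 6% of the cohort. The
full candidate set is scanned (not a quantile grid): exactness against
a brute-force oracle was preferred over the marginal speed of a coarser
grid.

Conventions, chosen for determinism:

- the Cox covariate is 1{value > cutoff}; the design is derived from
  the sign of β̂ (β̂ ≥ 0 → design 2), so HR ≥ 1 always refers to
  high- vs low-risk;
- values exactly at the cutoff fall on the "≤" (lower) side;
- ties on minimal p prefer the more balanced split, then the smaller
  cutoff.

Because the cutoff is selected by minimizing p over many strongly
dependent tests, the reported minimal p is anti-conservative under the
null — a pure-noise variable will often show a "significant" best
split. This is a property of the methodology, used for ranking and
weighting variables, and is deliberately not corrected here; treating
the minimal p as a calibrated significance level is the caller's error.
Feature screening and multiplicity control across variables are out of
scope.

## Weight schemes

Raw weights per variable: A constant 1; B 1/Pᵢ; C −log Pᵢ; D HRᵢ;
E and F combine −log P and HR multiplicatively and additively. For E
and F each component vector is first normalized to sum 1, then combined
(elementwise product for E, mean for F); the final vector is always
renormalized to Σw = 1. Component normalization is what gives the two
quantities a comparable scale before combination and is also what makes
every scheme invariant to the logarithm base (the base constant cancels
under normalization) — asserted in the tests by recomputing with
log₁₀. Natural log is used internally; it is immaterial. P-values of
exactly 0 arising from upstream fits are floored at 1e-300 with a
warning; P = 1 is an error since −log P and 1/P weights degenerate.

## Weighted-voting stratification (SWVg / AWR)

AWR = Σ wᵢ sᵢ with Σ wᵢ = 1, so AWR ∈ [0, 1] and 0 means every
univariate classifier voted low-risk. The three risk groups come from
an exhaustive search over ordered pairs of AWR-midpoint thresholds,
minimizing the 3-group log-rank p subject to every group holding at
least ⌈f·M⌉ patients (`min_fraction` default 0.10 for the 3-group
search; intermediate groups are typically large). Boundary values
belong to the lower class (AWR = t_high is intermediate). Ties on p
prefer the largest minimal group, then the lexicographically smaller
pair. The search is exact: groups defined by thresholds are contiguous
in AWR rank order, so the statistic for every pair is assembled from
per-event-time prefix sums — an O(J·k²) vectorized scan that returns
the same optimum as the naive per-pair loop (asserted against it).

As with the cutoff scan, the optimized 3-group p is anti-conservative,
and the recovered grouping is the most survival-significant one — which
coincides with a planted grouping only when that grouping is also the
strongest signal in the data (see the simulator notes below).

Missing variable values for a patient are an error by default; an
optional mode drops the missing variables and renormalizes the
remaining weights for that patient's AWR (`build_pbvv(..., impute=)`
covers the matching step).

## Signature-vector matching (PSVM)

Variables are ranked by descending weight (ties broken by signature
order, so the constant scheme is still deterministic); the PSV
component for variable i is bitᵢ · (n − rᵢ + 1). The reverse-rank
transform, rather than bit × weight, makes the encoding robust across
weight schemes — any two schemes with the same ordering produce
identical PSVs — and keeps components as integers in {0..n};
bit × weight is available as a sensitivity option
(`pbvv_to_psv(..., use_weights=True)`). Matching is exact Euclidean
distance on un-scaled PSVs: the rank magnitudes are the point, so
standardizing them would destroy the intended emphasis on top-ranked
variables. Distance ties take the majority class among tied references,
then the lowest-risk class.

## Ensemble

Learners consume PSVs z-scaled to zero mean and unit variance with the
*population* (divide-by-n) standard deviation, learned on the training
cohort only; constant features scale by 1 with a warning. PSVM consumes
un-scaled PSVs by design. Stratified folds shuffle within class
(seeded) and deal round-robin with a carried starting position, keeping
both per-fold class counts and fold totals within one patient of
proportional. Each fold-model trains on its own 9-fold split; a test
patient's per-learner prediction is the majority over the ten
fold-models (ties → the class more prevalent in training, then lower
risk), and the final call is the majority of the seven methods (ties →
the matcher's own prediction if among the tied classes, else the
lowest-risk tied class — the matcher is the method the vote is anchored
on).

Default hyperparameters — KNN k = 5; SVM C = 1 with RBF γ = 1/n_features;
random forest 100 trees; one hidden layer of 32 units; logistic
regression L2, C = 1 — are ordinary mid-range choices exposed through
`hyperparams=`; seeds are mandatory for the stochastic learners.
Goodman–Kruskal gamma is (C − D)/(C + D) with ties excluded; when every
pair is tied the coefficient is undefined and reported as null rather
than coerced to 0.

## Synthetic cohorts

The simulator generates exactly the structure the cutoff classifier
assumes: each variable influences survival only through a dichotomous
call at a planted cutoff, calls act multiplicatively on an exponential
baseline hazard (default 0.01 per day), and censoring is independent
exponential (default rate 0.005). Exponential event times make planted
hazard ratios exact, so recovery tests are sharp; there is deliberately
no probe-level noise model, batch structure, correlated-gene blocks or
informative censoring, so passing recovery tests demonstrates
correctness of the estimators under the model's own assumptions, not
robustness to real microarray artifacts.

The three-class mode plants a low/intermediate/high structure: each
class has a risk-call probability (its expected equal-weight AWR) and a
hazard multiplier, and a per-patient planted risk score (class center +
Gaussian noise, sd 0.04) is returned for threshold-recovery studies.
The canonical "strongly separated" condition (`three_class_spec`) uses
call probabilities 0.15/0.5/0.85, hazard ratios 1:4:16 and censoring
rate 0.002 at n = 300 with 60 variables. The separation matters: the
threshold search returns the *most significant* grouping, and under
weaker hazard contrasts (e.g. adjacent-class ratio 2) it can
legitimately trade boundary patients for a smaller p-value, dropping
planted-grouping agreement well below what the estimator's accuracy
would suggest. With adjacent-class ratio 4, agreement stays ≥ 95%
across seeds at these sizes; recovery studies in the tests use
n = 300 training / 150 held-out patients, sizes at which the full
pipeline (signature fit, threshold search, matching, 10-fold ensemble)
runs in seconds.

The packaged signature table ships as tab-separated text and
round-trips through the reader/writer byte-exactly (floats are written
in shortest-round-trip decimal form and parsed with pandas'
`round_trip` converter).

## Known limitations

- Single-covariate Cox only: no multivariate adjustment, time-dependent
  covariates or competing risks.
- Minimal-p selection is anti-conservative by construction at both the
  cutoff and threshold layers; reported p-values rank models and are
  not calibrated significance levels.
- The number of risk groups is fixed at three; variable selection for
  building a signature is out of scope.
- The exact rank-based PSV construction is one documented convention
  (reverse rank), isolated in `rank_scores` so it can be swapped.
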