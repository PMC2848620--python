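# Methods

## The statistic

For gene *g*, synchrony is the product–moment correlation
*r_g* = corr(*a_g*, *b_g*) of its expression across the *n* subjects
measured in both regions. Values are assumed already normalized and on a
log2 scale; the analysis is invariant to per-gene affine rescaling, so the
exact normalization matters only through its effect on outliers. Genes
with zero variance in either region in a given subject set are *degenerate*:
their r is recorded as NaN, counted, and excluded from distributions and
tests — never an exception in vectorized paths.

Missing values are rejected at read time rather than imputed: every
statistic here is a function of complete within-subject pairs, and
imputation would manufacture or destroy correlation silently. Gene
alignment between regions is by exact id string match (probeset-level);
collapsing probesets to genes is out of scope.

## Permutation null and the global shift test

The null hypothesis is "no within-subject coordination": scrambling which
subject's region-B column is paired with each region-A column leaves both
marginal distributions untouched but destroys the pairing. Scrambles are
**derangements** (no fixed point): with small *n*, a uniform permutation
leaves ≈1 subject self-paired on average, leaking true linkage into the
null. The cost is a small negative bias — on data with perfect synchrony
the null r has mean −1/(*n*−1), since a subject's own column is excluded —
which is negligible at the scale of the observed shift.

Two significance summaries are reported:

- `global_shift_test`: one-sided Wilcoxon rank-sum of observed genewise r
  versus the pooled null r (genes × permutations). Genes are correlated
  with one another, so this p-value is an index of separation, not an
  exact error rate; with 10⁴ genes and a large shift it underflows to 0.
- `median_shift_permutation_p`: fraction of permutations whose
  across-gene median r reaches the observed median, with the +1
  correction, floored at 1/(P+1). This respects the subject-level
  exchangeability unit and is the honest (conservative) companion: it can
  never beat its floor, 1/101 at the default P = 100.

## Percentile bootstrap

Subjects are resampled with replacement, keeping each subject's A/B pair
intact; genewise r is recomputed per resample. Point summaries are the
bootstrap median and the central percentile interval (default 95%).
Resamples in which a gene is degenerate are dropped from that gene's
percentiles (not redrawn) with a logged count — redrawing would bias the
resample distribution and complicate the resample-count interpretation.

Resampling happens in canonical (sorted-subject-id) index space, which
makes every seeded routine bitwise-invariant to the column order of the
input matrices. The raw and age-detrended bootstraps at the same seed
share the same resample indices, so raw-vs-detrended contrasts are paired.

**Known small-sample property.** At *n* = 14 the percentile bootstrap CI
for a correlation undercovers: measured coverage of the true ρ is ≈92%
at nominal 95%, confirmed independently with `scipy.stats.bootstrap`
(percentile method, same *n* and resample count). This is a documented
property of the percentile method for correlations at small *n* (a
bootstrap resample contains on average only ~8.6 distinct subjects of 14),
not an implementation artifact; the package implements the percentile
method deliberately, because it is the procedure the analysis is defined
by. Downstream difference p-values inherit a mild anti-conservatism of
the same origin (≈6–8% of null genes below p = 0.05 at *n* = 14 per
group). Users needing exact coverage at such sample sizes should treat
the CIs as approximate or increase *n*.

## Age detrending

Each gene is regressed on subject age (OLS with intercept) in each region
and replaced by its residuals; residuals have exactly zero sample
correlation with age. Because the reported estimates are bootstrapped,
detrending is performed **inside every resample on the resample's own
ages** — detrending once up front is not the same operation, as a
resample reweights subjects and hence the fitted trend. The model is
strictly linear in age; other covariates (PMI, pH, medication) are out of
scope. With constant ages the slope is undefined and the operation
degrades to mean-centering with a warning.

On full data (no resampling), detrended synchrony equals the partial
correlation of the two regions given age; the test suite checks this
closed form to 1e-10.

`age_contribution_report` summarizes age's role with (i) per-gene age
correlations before/after detrending, (ii) the across-gene correlation of
raw vs. detrended synchrony, and (iii) a baseline diagnostic correlating
each gene's age-correlation magnitude with its raw synchrony. A caveat
discovered during validation: even when *all* synchrony is age-driven,
(ii) stays well above zero at small *n*, because the raw and detrended
estimates share each gene's residual sampling noise, and that noise —
not the age signal — dominates the across-gene variance of both. The
discriminating signatures of age-driven synchrony are the collapse of the
*median* detrended r to ~0 and the compression of the age-correlation
distribution.

## Differential synchrony

Only genes with |r| ≥ 0.7 in at least one group are tested (configurable;
a `select_all` flag exists for sensitivity analysis). Selection before
testing concentrates power on genes plausibly engaged in cross-region
communication, at the price of a selection effect: a gene whose observed
|r| crossed 0.7 by chance regresses toward its true value in the other
group's estimate, so screened correlation shifts at *n* = 14 include
chance crossings. The FDR adjustment controls error for the *shift* test
among selected genes, not for the selection itself; the synthetic-truth
tests quantify the resulting precision.

Per resample, subjects are drawn independently within each group (no
cross-group pairing exists) and Δr = r_case − r_ctrl is recorded. The
two-sided p is 2·min(P(Δr ≤ 0), P(Δr ≥ 0)), floored at 1/(B+1) and capped
at 1. Each group's resample stream is keyed to its own subject-id set, so
swapping the group arguments is an exact symmetry: Δr negates, p is
unchanged, gain/loss labels swap.

Benjamini–Hochberg runs over the selected genes' p-values
(`statsmodels.multipletests`, step-up; adjusted value for rank *i* is
min_{j≥i} m·p_(j)/j). Significant genes are then banded: **loss** if
|r_ctrl| ≥ 0.7 and |r_case| ≤ 0.2, **gain** for the reverse; both
thresholds configurable. Labels follow the magnitude of correlation, so a
gene acquiring strong *negative* synchrony counts as a gain even though
its signed Δr is negative; `delta` in the results is always the signed
shift. Significant genes that stay inside the bands remain
`not_classified` but keep their p and q.

## Synthetic cohorts

The generator exists so that every inferential claim can be checked
against known truth. Per gene *g* and subject *s* with age *a_s* ~
Uniform(20, 70) by default:

    A[g,s] = μ_g + β_A[g]·a_s + σ·(√|ρ_g|·z + √(1−|ρ_g|)·e_A)
    B[g,s] = μ_g + β_B[g]·a_s + σ·(sign(ρ_g)·√|ρ_g|·z + √(1−|ρ_g|)·e_B)

with z, e_A, e_B i.i.d. standard normal. The shared factor z gives an
age-free cross-region correlation of exactly ρ_g; negative ρ flips the
shared component's sign in region B. Defaults describe a postmortem-style
design: 14 subjects per group, baselines N(8, 1.5²) on the log2 scale,
unit noise σ. Gene classes: `stable` (ρ common to both groups), `gain` /
`loss` (designed (ρ_ctrl, ρ_case) pairs, defaults (0, 0.9) and (0.9, 0)),
`age_driven` (ρ = 0, equal-sign slopes ±0.05 log2 units/year in both
regions — at the default age spread that yields population r ≈ 0.34, all
of it through age), `null` (ρ = 0).

The control-like preset draws ρ_g from Beta(2, 1.67) rescaled to
(−0.4, 0.9) — right-shifted, unimodal, median 0.3201, with a minority of
negative-synchrony genes — for 10,000 genes and 14 subjects. The draw is
stratified (one jittered draw per quantile stratum, shuffled), pinning the
empirical ρ median to the family median within O(1/n_genes) for any seed.
The family's dispersion is a free parameter: real cohorts constrain the
median of the r distribution better than its spread.

What the generator does **not** emulate: probe-level hybridization noise,
batch and array effects, heavy-tailed or skewed expression marginals,
gene–gene correlation structure (genes are independent given age), and
demographic covariates beyond age. Passing tests therefore validate the
inferential machinery under the stated model, not robustness to those
real-data features.

## Problem sizes and numerical choices

Test and example runs use 10–50 subjects, 400–10,000 genes, 200–2,000
bootstrap resamples and 20–100 permutations — sizes chosen so the full
suite runs in well under a minute while keeping Monte-Carlo error far
below every asserted tolerance; production runs would raise
`n_bootstrap` to the 20,000 default, at which point shift p-values are
stable. Bootstrap tensors are processed in gene × resample blocks capped
at ~64 MB. All r values are clipped to [−1, 1] against floating-point
overshoot. Degenerate inputs (constant genes, constant ages, empty
p-vectors) follow the rules above; every stochastic routine takes a
single integer seed and is bitwise-reproducible.
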