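# Methods

## Data model

The pipeline's central object is a balanced two-session feature table:
I subjects × 2 sessions ("test", "retest", in that order) × p features,
stored dense as an `(I, 2, p)` float array. Loading enforces balance:
subjects missing either session are dropped and counted in the log (this
mirrors how test–retest cohorts routinely lose a subject to a missing
acquisition), duplicated (subject, session, feature) entries and
non-numeric cells are hard errors. Session order matters: the test
session is the denominator of percent differences. Feature order is
preserved from the file and used by all downstream matrices. CSV output
uses 17-significant-digit formatting and CSV input uses round-trip float
parsing, so load → write → load is bit-exact.

For seed-based functional connectivity, an s-seed correlation matrix is
Fisher z-transformed (`atanh`, off-diagonal only; |r| ≥ 1 is an error
naming the offending pair) and packed into a row-major upper-triangle
vector of length s(s−1)/2 — 1,431 entries for 54 seeds. The packing is a
bijection; the inverse unpacking restores the symmetric matrix.

## Reliability estimators

**Per-feature ICC.** Computed from the explicit two-way ANOVA mean
squares (BMS, JMS, EMS, WMS) written out in `reliability.py`, vectorised
over features. All three single-measurement Shrout–Fleiss forms are
available. The default is ICC(2,1) — two-way random effects, absolute
agreement — because a test–retest study should pay for a systematic
session shift; the report always states the form used, and the
form-sensitivity is one line of config. Features with zero total
variance get NaN (logged) and are excluded from summaries. Negative
estimates are reported as computed and flagged, never truncated:
truncation at zero biases simulation summaries upward.

**Global I2C2.** Method-of-moments trace ratio. With scan vectors
`W_ij`, session-demeaned by default (`W'_ij = W_ij − mean_i W_ij`),

    trKw   = (1/2I)     Σ_i ||W'_i1 − W'_i2||²
    trKtot = (1/(2I−1)) Σ_ij ||W'_ij − W̄||²
    I2C2   = 1 − trKw / trKtot.

Demeaning is applied to numerator and denominator alike: it removes a
systematic session effect from both traces, matching the visit-mean
centering of the multivariate-reliability literature, and makes the
estimator consistent for Σσ_b²/Σ(σ_b² + σ_w²) even under a session
shift. An `demean_sessions=False` flag exists for sensitivity checks.
E[trKw] = Σσ_w² exactly; E[trKtot] underestimates Σ(σ_b² + σ_w²) by a
factor (2I−2)/(2I−1) on the σ_b² part, a bias of order 1/I (verified
below 0.01 at I = 2,000 in the acceptance suite). For p = 1 the
estimator targets the same population quantity as ICC; the suite asserts
this by simulation, not algebra. trKtot = 0 (a constant table) is an
error.

**Bootstrap CI.** Percentile interval over subject resamples (both
sessions of a resampled subject travel together), default n_boot =
1,000, deterministic given the seed. Resamples containing a single
unique subject are redrawn and counted. Bootstrap calibration is checked
at 45 subjects — the size of the larger of the two cohorts this kind of
study uses — where the empirical coverage of the 95% interval over 200
replicates is ~95%.

**Seed-level summaries.** For connectivity vectors, a seed's ICC is the
mean of the ICCs of the s−1 pairs containing it, NaN pairs excluded
pairwise.

## Fingerprint

All 2I scans are embedded jointly (never per session) in the top three
principal components. Features are z-scored first by default — regional
features span orders of magnitude and an unstandardised PCA would be a
single-feature ruler; the flag is exposed because this choice visibly
moves misclassification counts on real data. The SVD sign is fixed by
making the largest-magnitude loading entry positive, so scores are
reproducible across runs and platforms. Distances use the raw
(unwhitened) scores, the geometry a PCA scatter plot shows.

The I×I cross-session distance matrix D[i,k] (test scan i vs retest
scan k) is ranked row-wise with stable tie-breaking by subject order
(ties are logged; they have probability zero under the generative
model). Subject i is misclassified when rank(D[i,i]) ≠ 1. The primary
direction is test → retest; the reverse direction and the union count
are also reported. Limiting behaviour anchors the scale: σ_w → 0 gives
zero misclassifications, and destroying the pairing by permutation gives
the chance expectation I·(1 − 1/I) = I − 1.

## Session comparison

Per feature, a two-sided paired Wilcoxon signed-rank test: exact null
for ≤ 25 effective (non-zero-difference) pairs, normal approximation
with continuity correction above. Zero differences are dropped by
default ('wilcox' handling; 'pratt' available), counts logged; an
all-zero feature reports p = 1. BH-FDR correction is delegated to
statsmodels with NaN p-values excluded. Percent difference is
100·(test − retest)/test per cell; per-feature and overall summaries
average the *absolute* values (signed values cancel and understate
disagreement), and signed means are emitted alongside. Cells with a
zero test value are excluded with a count. Note the quantity is only
meaningful for positive-valued features; for near-zero-mean features
such as z-correlations the overall percentage is dominated by
near-zero denominators and should be ignored in favour of I2C2.

## Dice overlap

Per label l > 0: 2|A∩B| / (|A|+|B|) by direct voxel counting. Labels in
exactly one volume score 0 and are listed separately; background never
enters summaries. The summary mean is unweighted across labels (a
volume-weighted variant sits behind a flag, since big structures overlap
easily). Inputs are assumed already aligned; only shapes are enforced,
affine mismatch is a warning.

## Power

`required_n` inverts the exact two-sample t power (noncentral t with
ncp d·√(n1·n2/(n1+n2))) by doubling-plus-bisection, so the returned n
attains the target power and n − 1 does not. The Wilcoxon variant
divides the t-test n by the ARE 3/π (normal parent) before ceiling.
n beyond 10⁷ raises an overflow guard. Effect sizes between sessions are
computed in both framings — two-sample (|Δmean| over the equally
weighted pooled session SD, the default) and paired (over the SD of the
differences) — because published sample-size tables rarely state which
was used; with d values printed to two decimals the resulting n is
reproducible only to a few percent, so only the qualitative pattern
(d ≈ 0.04 → n_total above 10,000; d ≈ 0.69 → n_total below 100) is
asserted.

## Synthetic generator

`X[i,j,r] = μ_r + shift_r·1{j=retest} + b[i,r] + e[i,j,r]`, with subject
effects b of SD σ_b (optionally correlated across features through k
shared latent factors, mixing weight 0.7, which leaves the marginal
variances and hence the ICC/I2C2 truths untouched) and i.i.d. scan noise
of SD σ_w. Draw order (loadings → subject effects → noise) is fixed, so
one seed gives one table forever. Session shift defaults to 0 and is the
lever for absolute-agreement vs consistency comparisons. Monotone
modality transforms (exp for positive volumes/diffusivities, logistic
for unit-interval FA) are applied last; they change the ICC truth, which
is then estimated by a large-n Monte-Carlo oracle rather than claimed
analytically.

The modality presets freeze what the generator treats as the study
conditions: 20 subjects; 226 volume features with log-normal means and
per-region ICC drawn in 0.97–0.995; 97 FA regions (ICC 0.70–0.93);
97 MD regions (ICC 0.55–0.90); 1,431 seed-pair z-values from 54 seeds
(ICC 0.25–0.55). These reproduce the canonical reliability ordering
volumes > FA > MD ≫ rsfMRI. What the generator does *not* emulate:
spatially structured noise, motion artifacts, scanner drift, non-Gaussian
tails, or inter-regional correlation structure estimated from real
brains — so passing recovery tests demonstrate estimator correctness
under the stated model, not pipeline performance on real scans.

Synthetic label volumes are axis-aligned cubes (default edge 10 in a
48³ grid) whose pair partner is a translated copy, giving analytic truth
Dice `Π max(0, edge − |d_axis|) / edge³`.

## Problem sizes and numerical choices

The test suite uses I = 2,000 (p = 50) for point-estimate recovery
(±0.02 bands), 200 replicates × n_boot = 500 at I = 45 for bootstrap
coverage (accepted band 90–99%), 1,000 permutations at I = 20 for the
fingerprint chance check, and 200 null replicates for type-I control;
the full suite runs in well under a minute of CPU except the coverage
block (~5 s). Symmetry tolerance for seed matrices is 1e-8 absolute;
ICC degeneracy is detected against float eps scaled by the data
magnitude; all tie-breaks are stable and logged.

## Limitations

Exactly two sessions — no multi-site or multi-scanner variance
components, no identification statistics over longer session sequences.
No registration: Dice assumes pre-aligned volumes. The percent
difference is undefined for zero test values and unstable near zero.
The published-data reproduction tests require the originating study's
deposited supplementary tables, which must be obtained separately and
placed under `data/supplementary/`; they are not distributed here.
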