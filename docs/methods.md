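# Methods

## Model and statistic

The package treats a cohort of multivariate recordings (regions × time, one
matrix per subject, z-scored per region within subject) as realizations of
a first-order vector autoregression. Two models are fitted to the
subject-concatenated series by ordinary least squares, with no intercept
(inputs are centred by z-scoring) and with transition pairs that straddle a
subject junction excluded:

* forward: x_t regressed on x_{t−1};
* backward: x_t regressed on x_{t+1}.

The regional arrow-of-time strength is
τ_i = (K(ε_f,i) − 3)² − (K(ε_b,i) − 3)², where K is the population
kurtosis (fourth standardized central moment, no bias correction, no
excess offset) of region i's residuals and 3 is the analytic kurtosis of a
standard normal.

The statistic rests on a result from linear non-Gaussian causal inference:
if the data really follow the forward model with independent, non-Gaussian
innovations, the forward residuals recover those innovations, while the
residuals of the reversed regression are linear mixtures of many
innovations and are therefore closer to Gaussian. Three consequences shape
interpretation:

* τ_i ≥ 0 asymptotically for *every* region of a fully observed linear VAR
  with i.i.d. innovations — backward residuals are mixtures, and a
  mixture's |excess kurtosis| cannot exceed that of its most extreme
  component. Positive τ therefore marks regions receiving directed input
  (sinks), with magnitude growing with the innovation's non-Gaussianity.
* Negative τ_i requires an asymmetry in the innovation structure itself:
  the region's own drive must be closer to Gaussian than the backward
  mixture it inherits from its targets. A causal source driven by Gaussian
  noise while its targets carry kurtotic innovations is the canonical
  example; unobserved variables or region-dependent response delays act
  similarly. Negative values should be read as "source-like asymmetry",
  not as a guaranteed source label.
* A Gaussian linear process is time-reversible: τ carries no signal and
  fluctuates around zero. This is the pipeline's built-in negative
  control.

## Group estimation

Kurtosis is an outlier-driven moment, so single-concatenation estimates are
unstable. The group estimator draws, per fold, a random permutation of the
subjects, concatenates in that order, truncates to the first `n_samples`
time points (a subject cut mid-way stays in as a partial block; a 1-sample
stub simply contributes no transition pair), fits both directions and
evaluates τ. The per-region **median across folds** is the estimate; its
mean over regions is the whole-system summary τ̄. Defaults are
`n_samples=8000`, `n_folds=100`, both freely reducible. All randomness
flows from a single `numpy` seed; identical seeds give bit-identical
results.

Truncating to a fixed budget makes fold-to-fold variation reflect subject
selection, and makes estimates comparable across conditions with different
recording lengths. With mid-block truncation the exact time-reversal
antisymmetry of τ (reversing every subject's series negates every fold's
τ) holds only up to the truncated block's asymmetry; with a budget equal
to a whole number of subjects, or the full pooled length, it is exact to
machine precision and is tested at that precision.

## Surrogate null and significance

The null hypothesis is "no temporal asymmetry, everything else equal".
Amplitude-adjusted phase randomization (AAFT) builds surrogates whose
sorted values equal the original's exactly and whose power spectrum is
approximately preserved: a Gaussian companion series is rank-matched to
the data, phase-randomized, and the data's sorted values are re-mapped
onto the companion's ranks. One phase draw is shared across regions
(multivariate phase randomization), so cross-correlations — not just
autocorrelations — survive into the null. This matters: with independent
per-region phases the null's *joint* cross-region distribution is wrong
even though every per-region marginal is calibrated, and family-wise error
on Gaussian VAR cohorts stayed near 0.3 regardless of threshold rule; with
shared phases it drops to the nominal level (measured 0.033 at α=0.05).
Surrogates are generated per subject, independently across subjects and
null realizations, preserving the block structure the fold scheme uses.
An iterated spectrum-matching variant (`method="iaaft"`) is available; it
re-fits spectra per region and is kept for univariate-style use.

Each of `n_null` (default 100) realizations surrogates every subject and
reruns the full fold estimator; the per-region medians form the null
ensemble, whose mean and sd are recorded per region.

Thresholds: the default (`maxstat`) standardizes each null realization by
the per-region null mean/sd, takes the maximum |z| over regions per
realization, and uses the (1−α) quantile of those maxima as a common
standardized threshold M*; per-region limits are mean ± M*·sd. This
controls the family-wise rate by construction, needs only a ~95th
percentile from the ensemble, and makes no tail assumption. The
alternative `gaussian` method reads Bonferroni-corrected quantiles
((α/2)/R per tail) off a Gaussian fitted to the null mean/sd; it is
provided for comparison but is markedly anti-conservative here, because
the null τ is a difference of squared kurtosis deviations and is strongly
leptokurtic (measured excess kurtosis ≈ 2.7 of the standardized null;
Gaussian thresholds inflated family-wise error to ≈ 0.4 in the same
experiment). `empirical` raw percentiles are included for completeness but
cannot resolve Bonferroni tails from ~100 draws.

## Task-epoch masking

Binarized paradigms (0 = rest, 1 = task) are convolved with a canonical
double-gamma haemodynamic response function — response peak 6 s,
undershoot peak 16 s, undershoot ratio 1/6, kernel length 32 s, sampled at
the series' period and peak-normalized to 1 so the threshold is on the
kernel's own scale. Samples with convolved value > 0.5 are task; ties at
exactly 0.5 count as rest. Filtering a cohort to task (or rest) samples
splits each subject at removed gaps into sub-blocks, so no transition pair
is ever formed across a gap; retained runs shorter than 2 samples are
dropped with a warning.

## Sliding-window dynamics

For window width W (default 20) and stride 1, three measures share one
window grid indexed by window start:

* **aot** — the W-sample window at start t is taken from every subject and
  pooled (each window its own block); forward and backward VAR(1) fits on
  the pooled pairs give τ per region. Pooling across subjects is what
  keeps an R-region fit identified when W−1 per-subject pairs would not
  be; it assumes subjects are paradigm-locked.
* **activity** — the cross-subject mean time course smoothed with a
  length-W moving average.
* **connectivity** — per window, Pearson correlations on samples pooled
  over subjects after per-subject demeaning (so between-subject offsets do
  not masquerade as coupling), summed over all partners per region.

## Network aggregation

Regions are assigned to networks by majority vote over region × label
overlap counts; ties break deterministically by label order and are
logged. Signed contributions sum positive τ and |negative τ| separately
per network over *all* member regions (significance is not a filter); the
per-label sums partition the cohort's signed τ mass exactly.

## Synthetic cohorts

The generator simulates x_t = A x_{t−1} + ε_t per subject independently,
discards a 200-sample burn-in, applies an optional modulation window
(multiplicative gain on selected couplings, in post-burn-in time), and
z-scores each subject. Innovation families — gaussian, laplace,
student_t(df > 4), generalized_gaussian(shape) — are standardized to unit
variance so kurtosis is the only family difference. Stability (spectral
radius < 1) is checked for the base and the modulated coefficient matrix.

`make_chain_system` builds a causal chain with roles derived from the edge
set. By default the designated source regions are driven by Gaussian
innovations and downstream regions by the requested non-Gaussian family.
This is a deliberate design: with homogeneous innovations all regions come
out τ ≥ 0 (sources included — verified numerically and implied by the
mixture argument above), so sources would not be sign-separable and the
generator could not serve as ground truth for the sign convention. The
heterogeneous default realizes the sink-positive / source-negative reading
within a fully observed linear system. Default coupling 1.2 and
self-coupling 0.3 give a source τ near −0.7 and sink τ near +9 at the
default cohort size (10 subjects × 1000 points), comfortably separated
from the surrogate null.

What the generator emulates: linear first-order dynamics, non-Gaussian
drive, subject concatenation structure, paradigm-locked coupling changes.
What it does not: haemodynamic convolution and its regional delay
variation, measurement noise, spatially correlated noise, motion
artifacts, nonstationarity beyond the modulation window, nonlinearity.
Passing tests therefore demonstrate correctness of the estimator under its
own model class, not robustness to real-fMRI confounds.

## Numerical choices

* OLS via economy QR with a triangular solve; a rank-deficient predictor
  matrix raises (no silent pseudo-inverse). Underdetermined fits (pairs ≤
  regions) raise with the counts.
* z-scoring uses the unbiased (n−1) sd; zero-variance regions raise with
  the region id.
* Kurtosis requires ≥ 4 samples and nonzero variance.
* The KL-divergence variant measures non-Gaussianity per residual row as
  KL(empirical ‖ moment-matched Gaussian) = ½log(2πe·var) − Ĥ, with Ĥ a
  Vasicek spacing entropy estimate, and reports forward minus backward. It
  is exactly zero for identical rows and negates under argument swap.
* Zero-variance regions inside a connectivity window get correlations 0
  with a warning; mask-filter runs shorter than 2 samples are dropped with
  a warning count.
* Test and acceptance problem sizes (e.g. 10 subjects × 800–1000 points,
  20 regions for the negative control, 20 folds, 50 nulls, 50 Monte-Carlo
  repetitions) were chosen as the smallest cohorts at which the measured
  properties are stable; all scale up through the public parameters.

## Limitations

* Interpretation of τ inherits all linear non-Gaussian causal-inference
  assumptions: fully observed state, i.i.d. innovations, first-order
  linear dynamics. Negative τ is evidence of asymmetry, not a certificate
  of a source.
* The surrogate test is conditional on the realized amplitudes and
  spectra; its calibration was verified on Gaussian VAR cohorts at R = 20
  and may degrade for very short series.
* The sliding-window fit assumes paradigm-locked subjects; windows
  containing a coupling switch are transiently misspecified, which is
  precisely what makes the excursions visible but means within-window
  values there should not be read as stationary τ estimates.
* Fold truncation keeps partial subject blocks; alternative sample
  selection schemes (e.g. whole-subject budgets) would change fold
  dispersion slightly.
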