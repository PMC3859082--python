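# Methods

## Signal model and envelope extraction

A deflation-phase cuff recording is modelled as

    CP(t) = B(t) + A(B(t)) · s(t) + ε(t),

where `B(t)` is the slowly decreasing cuff baseline, `A(·)` is a unimodal
amplitude envelope as a function of cuff pressure that peaks at the mean
arterial pressure, `s(t)` is the cardiac oscillation (unit-amplitude,
heart-rate periodic), and `ε` is sensor noise.

The baseline is estimated with a **twice-applied centered moving average**
(implemented as a polyorder-1 Savitzky–Golay filter with least-squares edge
fitting, window 3 s by default). A single moving average leaks a sinc-shaped
fraction of the cardiac component into the baseline — about 8% of the
oscillation amplitude at 72 bpm with a 3 s window — which would bias the
extracted envelope beyond the 5% recovery tolerance this package tests
itself against. Applying the same filter twice squares that attenuation
(< 1% leakage) while still passing linear deflation ramps exactly, ends
included. The oscillometric waveform (OMW) is the residual `CP − B`; the
pulse derivative waveform is the first difference of CP per unit time and
is carried as an auxiliary signal.

Because the leaked fraction is multiplicative and constant across a
recording, it cancels exactly in every amplitude *ratio*; it only matters
for the absolute amplitude `m`, which is why the residual < 1% bias is
acceptable.

**Pulse peaks** are strict local maxima of the OMW. The cardiac fundamental
is first estimated as the dominant discrete-Fourier peak of the OMW inside
the plausible heart-rate band (40–180 bpm by default); peaks must then be
separated by at least 0.6 of that period (never less than the 60/`hr_max`
bound) and exceed a prominence of 5% of the median absolute oscillation,
with an absolute floor of 10⁻³ mmHg. The period-based separation matters:
with only the `hr_max` bound, sensor noise can inject a spurious
low-amplitude "peak" between two genuine beats, and one such point is
enough to make the envelope spline oscillate violently.

The **envelope** takes one point per peak — amplitude = OMW value,
pressure = baseline value at the peak time — and is smoothed by a natural
cubic spline in peak time, evaluated on a 200-point uniform grid, with
deflation pressure interpolated linearly onto the same grid. The maximum
`m` and its pressure (the mean-arterial-pressure estimate) are read off
the dense grid; ties resolve to the earliest grid sample, and a maximum on
the grid boundary flags the envelope degenerate. Local pressure inversions
across peaks up to 2 mmHg (sensor ripple) are tolerated with a warning;
larger ones are an error. Smoothing precedes every amplitude lookup, so
reference amplitudes and back-mapped pressures are always read from the
same smoothed curve as `m`.

Branch convention: during deflation the *systolic* branch is everything
before the envelope maximum (higher cuff pressures) and the *diastolic*
branch everything after. When a noisy branch crosses a target amplitude
more than once, the crossing farthest from the apex is used — the outer
intersection, which corresponds to the clinically meaningful one.

## Estimators

**MAA.** Target amplitudes `m·r_s` and `m·r_d` with fixed ratios, default
(0.70, 0.45); pressures by inverse interpolation on each branch. Ratios are
validated to (0, 1] with a warning outside [0.3, 0.99]; the degenerate pair
(1, 1) collapses both estimates onto the apex pressure and exists for the
identity test only.

**Bayesian MAP ratios (MAABG / MAABL).** Candidate grids are uniform with
exact endpoints — systolic 0.65–0.95, diastolic 0.30–0.60, step 0.01,
`K = 31`. The prior is uniform (`1/K ≈ 0.032`) unless the caller supplies
another. The reference ratio `ŷ` is the smoothed envelope amplitude at the
averaged nurse pressure, over `m`. Likelihoods share one standard deviation
`σ`:

* Gaussian: `f(ŷ|c) = (2πσ²)^(-1/2) exp(−(ŷ−c)²/(2σ²))`
* Laplacian: `f(ŷ|c) = (√2 σ)^(-1) exp(−(√2/σ)|ŷ−c|)` (variance σ²)

Posteriors are computed in log space and normalized by log-sum-exp, so the
result is a proper probability vector even when every density underflows
(small σ, far-out ŷ). The MAP candidate is the posterior argmax; ties
within a relative tolerance of 10⁻⁹ (e.g. ŷ exactly midway between
adjacent candidates) resolve deterministically to the smaller ratio. A
reference ratio outside the grid needs no clipping — the boundary candidate
wins through the posterior itself. Pressures then follow by exactly the
MAA back-mapping with the MAP ratios, the only mechanism that converts a
ratio into mmHg.

Under a uniform prior both likelihood families are strictly decreasing in
`|ŷ − c|`, so the MAP is the nearest grid candidate for *any* σ: MAABG and
MAABL coincide exactly, and σ does not move the argmax. Both facts are
asserted property-wise against a brute-force oracle. Non-uniform priors
break the equivalence, which is what distinguishes the Bayesian machinery
from plain quantization; a point-mass prior returns its candidate
regardless of data.

`σ` defaults to 0.10, the midpoint of the validated 0.02–0.20 range; since
the uniform-prior argmax is σ-invariant, the default is inert for the
shipped estimators and matters only for posterior *shapes* and non-uniform
priors.

Each measurement yields one (systolic, diastolic) ratio pair; there is no
pooling across a subject's measurements — the per-measurement ratios are
modelled as conditionally independent given the subject's physiological
state.

## Bootstrap

With `m` observed ratios per subject (five in the emulated study design),
`B` resamples of size `m` are drawn with replacement (default `B = 1000`)
and the resample means form the pseudo-ratio distribution. Normality of
that distribution is checked with the Anderson–Darling statistic; scipy
supplies the statistic and the p-value uses the standard small-sample
adjustment `A*² = A²(1 + 0.75/n + 2.25/n²)` with the piecewise-exponential
null approximation (Stephens). Shapiro–Wilk and D'Agostino–Pearson are
selectable alternatives. Constant input is flagged degenerate (non-normal,
p = 0) rather than erroring.

## Agreement evaluation

Differences are oriented estimate − reference; MD is their mean, SD their
sample standard deviation (n − 1). The AAMI SP10 pass rule is implemented
inclusively: `|MD| ≤ 5` and `SD ≤ 8` mmHg, tested at exact equality.
Bland–Altman points are `((est+ref)/2, est−ref)` with limits of agreement
`MD ± 2·SD`. The per-measurement summary table reports, for each
measurement index and method, the mean estimate (SD across subjects) and
MD (SD of differences); the `avg` row is the arithmetic mean of the five
per-measurement MDs/SDs, and a `pooled` row (all differences pooled) is
reported alongside because the two conventions differ slightly and the
choice between them is not canonical.

## Synthetic data

The generator emulates a two-nurse auscultatory validation study:

* **Deflation**: linear ramp at 2.5 mmHg/s (clinically typical). The ramp
  starts at `SBP + 30` mmHg, or higher when needed so the envelope has
  already fallen to 0.60 of its peak (below the 0.65 grid floor) at the
  start, and ends at `DBP − 20` mmHg or wherever the envelope reaches 0.25
  of peak — guaranteeing every candidate ratio and the classical (0.70,
  0.45) pair have a crossing. Duration follows from the span, clipped into
  the study's observed 31–95 s range (the rate adapts if clipping binds).
* **Envelope**: a two-sided Gaussian bell in cuff pressure centered at the
  true mean pressure. The branch widths are *solved* from the ratio
  constraints `A(SBP) = r_s·peak` and `A(DBP) = r_d·peak`, so the true
  ratios are exact by construction; any unimodal shape satisfying those two
  constraints would do, and the bell is the two-parameter closed form.
  Peak oscillation amplitude 2 mmHg.
* **Oscillation**: a sinusoid at the subject's heart rate with random
  phase; sensor noise is additive white Gaussian, SD 0.05 mmHg by default.
* **Cohort structure**: subject-level SBP/DBP from truncated normals on
  the study's observed ranges (SBP 78–147, mean 110 (13); DBP 42–99, mean
  67 (10), pulse pressure ≥ 25 mmHg), mean pressure at DBP + PP/3.
  Subject-level true ratios from truncated normals matching the reported
  per-measurement ratio averages — systolic mean 0.80, SD 0.11 on
  [0.65, 0.95]; diastolic mean 0.42, SD 0.11 on [0.30, 0.60] — with
  per-measurement jitter of SD 0.03 (clipped to the ranges) and pressure
  jitter of SD 2 mmHg. Heart rate 72 (8) bpm on [50, 100].
* **Nurse readings**: two readings per pressure whose half-difference is
  uniform on [0, 1] mmHg (so the pair is at most 2 mmHg apart, matching
  the study's stability criterion) and whose average is the true pressure
  plus a Gaussian reading error, SD 1 mmHg by default. Downstream code
  always uses the average.
* `snap_ratios_to_grid` quantizes the true ratios to the 0.01 candidate
  grid, used by recovery tests where "the truth is on the grid" is part of
  the claim being tested.

One master seed drives cohort generation; each recording receives a child
seed recorded in the truth manifest, so any single measurement can be
regenerated in isolation.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: motion and arrhythmia artifacts, non-sinusoidal
pulse morphology and heart-rate variability within a measurement,
envelope shapes that are skewed or multi-modal rather than bell-shaped,
inflation-phase data, device quantization, and any systematic (rather than
random) disagreement between auscultatory readings and the oscillometric
ground truth. In particular, on real data the reference ratios inherit
auscultation bias, which no amount of synthetic validation can bound.

## Problem sizes and numerical choices

The shipped tests use cohorts of 40 subjects × 5 measurements (200
recordings) for the equivalence and recovery checks, twenty 8 × 5 cohorts
for the fixed-vs-Bayesian comparison, and the acceptance script runs the
full 85 × 5 study structure; at 100 Hz sampling these sizes keep the whole
suite in a few seconds while leaving the statistics stable. Other
numerical defaults: 200-point dense envelope grid; natural spline boundary
conditions; posterior tie tolerance 10⁻⁹ relative; prior sums validated to
10⁻¹², posteriors to 10⁻¹⁰; grid bounds must be commensurate with the step
to 10⁻⁹.

## Known limitations

* The envelope apex is a biased estimator of mean arterial pressure when
  the envelope is asymmetric (here it is asymmetric by construction), but
  only ratios and branch crossings matter for the estimators, so the bias
  is second-order for SBP/DBP.
* The Bayesian estimator requires a per-measurement auscultatory
  reference; it individualizes ratios, it does not remove the need for a
  reference the way a free-standing monitor must. Cohorts are evaluated
  against the same references the estimator consumed, which is the
  intended use (characterizing ratio variability), not an independent
  accuracy claim.
* With a uniform prior the MAP estimator reduces to nearest-candidate
  quantization of the reference ratio; its added value over quantization
  appears only with informative priors, which the API supports but no
  shipped estimator uses.
* The fixed 2 mmHg inversion tolerance and the 5% prominence rule are
  heuristics tuned to the synthetic noise model; heavily artifacted real
  recordings would need dedicated artifact rejection (out of scope).
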