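# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `dcequant`, in the spirit of a methods appendix: what is
computed, under which assumptions, and what the tests do and do not
demonstrate.

## Acquisition model

All processing assumes a spoiled-gradient-echo (SPGR/FLASH) dynamic
acquisition. Defaults in `AcquisitionSpec` describe a 3 T dual-gradient-echo
protocol: 128×128 matrix, 20 slices, 60 dynamic frames at 6 s temporal
resolution (6 min total), TR 6.8 ms, TE 2.61/3.89 ms, dynamic flip angle
10°, contrast bolus 52 s after the start of the dynamic scan, and a
four-angle (2°, 5°, 10°, 15°) variable-flip-angle series at TR 7.3 ms for
pre-contrast T1 mapping. Frame k is timestamped t = k·dt; time grids are in
seconds, relaxation times in ms, and rate constants in min⁻¹ at every
public interface (converted internally).

Inputs are assumed co-registered: flip-angle volumes, the dynamic series,
and masks share one voxel grid. Registration is out of scope; the synthetic
generator emits aligned volumes by construction.

## T1 mapping (relaxometry)

The SPGR steady-state signal S = M0 sinα (1−E)/(1−E cosα), E = exp(−TR/T1),
is linear in S/tanα vs S/sinα. Per voxel we solve that regression and, by
default, refine (T1, M0) with bounded nonlinear least squares. On noiseless
data the linear step is already exact; refinement matters only for noisy
data. Fits outside a physical window (1 ms – 10 s) or from degenerate input
(all-zero, non-finite) are flagged invalid — values are retained, never
silently clipped — and flagged voxels are excluded downstream.

The between-baseline QC metric is the T10 histogram shift
(P1 − P2)/P1, where P is the mode of a fixed-bin histogram (100 bins over
0–5000 ms; bin width is a parameter pinned by the tests). The histogram is
taken over the whole volume above a small intensity floor, since a curated
brain mask is not assumed to exist. |shift| > 20% flags a subject as a QC
outlier (large apparent B1/T10 instability); outliers are annotated in the
cohort report, not excluded. B1 correction is out of scope.

## Concentration conversion

With A = (S(t)/S(0))·(1−E10)/(1−E10 cosα) and E10 = exp(−TR/T10),

    1/T1(t) = −(1/TR) ln((1−A)/(1−A cosα)),
    C(t) = (1/r1) (1/T1(t) − 1/T10).

S(0) is the mean of the pre-bolus frames: all frames strictly before bolus
arrival minus one guard frame (7 frames at the defaults). This conversion
is the exact algebraic inverse of SPGR signal generation, which the tests
exploit as a round-trip identity (< 1e−9 relative error, noiseless).

A is the saturation fraction of the SPGR signal; A outside [0, 1) has no
physical solution, and any voxel whose log argument leaves (0, ∞), whose
baseline signal is non-positive, or whose T10 fit is invalid is flagged and
set to NaN — flagged voxels are counted, logged and excluded from fitting,
never clamped to the valid range.

r1 defaults to 3.7 s⁻¹mM⁻¹ (a gadolinium chelate at 3 T) and is a
configuration parameter. No hematocrit correction is applied; Cp is used on
the (possibly normalized) scale it is supplied on.

## Vascular input function

Two extraction routes operate on signal curves:

* **automatic**: keep voxels whose (peak time − bolus arrival) < 10 s and
  whose temporal-maximum intensity is ≥ the 90th percentile of per-voxel
  maxima over the whole image (ties at the threshold are kept); average the
  survivors into a composite profile and record their mean T10. An empty
  selection raises an explicit error rather than returning an empty curve.
* **manual**: average over a drawn venous-sinus ROI.

Bolus arrival is detected per curve as the first frame exceeding
(baseline mean + 3·SD) for ≥ 2 consecutive frames, computed over the
pre-bolus window; the detector is the package's own design, as is the
interpretation of "90th percentile" as the percentile of per-voxel temporal
maxima (it matches the maximum-intensity wording of the selection rule).

When the sequence is dual-echo, the composite VIF signal is extrapolated to
TE = 0 assuming mono-exponential T2* decay between the echoes
(R2* = ln(S1/S2)/(TE2−TE1)) before conversion. The VIF is converted to
concentration with the contributing voxels' mean T10, then the (auto,
manual) pair is rescaled by **one shared factor** so the larger curve peaks
at exactly 2. The shared factor (rather than per-curve normalization) keeps
auto-vs-manual parameter differences meaningful; per-curve mode is
available behind a flag. Because of this relative scaling, fitted vp, ve
and Ktrans are relative to the supplied Cp scale — fitting against c·Cp
yields vp/c, ve/c, Ktrans/c with an unchanged model curve, a covariance the
tests assert explicitly. Absolute-scale runs can disable normalization.

## Kinetic fitting

The eTM convolution is evaluated with an exponential-kernel recursion that
is exact when Cp is piecewise linear on the frame grid, and numerically
stable for arbitrarily large kep (no growing exponentials). At 6 s sampling
with only 60 frames this is substantially more accurate than FFT
quadrature; the tests compare it against adaptive quadrature of the same
piecewise-linear input. The LTKM adds λtr times the trapezoidal cumulative
integral of Cp and reduces to the eTM exactly at λtr = 0. Pre-bolus frames
carry Cp = 0, so the integrals effectively start at bolus arrival.

Voxelwise fitting minimizes the residual sum of squares with bounded
damped least squares (`scipy.optimize.least_squares`, trust-region
reflective — the bound-aware member of the Levenberg–Marquardt family).
Defaults: initial values vp = 0.02, ve = 0.1, Ktrans = 0.05 min⁻¹,
λtr = 0.001 min⁻¹; box bounds vp ∈ [0,1], ve ∈ (0,1], Ktrans, λtr ∈ [0,10]
min⁻¹. λtr is constrained non-negative (the leakage compartment only
fills). A degenerate λtr bound (0, 0) freezes the leakage term, making the
LTKM fit bit-identical to the eTM path — used to verify model nesting.
Optional multi-start (jittered initial values, best cost wins) is off by
default so fits are deterministic. Degenerate curves (constant or
non-finite) and optimizer failures are flagged with NaN parameters; a map
fit never raises on a single bad voxel.

Goodness of fit is R² = 1 − SSerr/SStot; constant data leave R² undefined
(flagged). Voxels with R² ≤ 0.5 are treated as poor fits (typically
necrotic, low-enhancement tissue); the ROI summary is the untrimmed mean
over voxels with R² strictly greater than 0.5, and the count of such voxels
doubles as the tumor-volume estimate.

## Repeatability statistics

Given per-subject parameter summaries at two baselines, the package
computes d = ln(B2/B1) per subject, Bland–Altman bias and limits of
agreement on the distribution of d (mean ± 1.96 × sample SD, n−1 divisor
throughout), the within-subject CV, %RC = 1.96·√2·wCV·100, and the mean
per-subject CoV. Bias is the mean of per-subject log-ratios (not the
difference of means; the two differ only by Jensen effects). Subjects with
non-positive summaries are dropped from that cohort with a logged warning.
Bland–Altman analysis is performed on log-ratios only; a raw-difference
mode is deliberately not provided, since the downstream %RC is a relative
threshold.

## Synthetic data

The generator provides three layers, all driven by one integer seed:

* **Plasma curve**: a gamma-variate first pass (unit peak ~5 s after
  arrival) plus a slower recirculation/washout shoulder; zero before bolus
  arrival, non-negative, single early global maximum. The functional form
  is the package's own choice of a smooth curve satisfying the automatic
  selection criteria; the absolute amplitude (default 6 mM at peak) is
  arbitrary because downstream parameters are relative to the Cp scale.
* **Reference object**: one slice of rectangular patches sweeping
  Ktrans ∈ {0.01, 0.02, 0.05, 0.1, 0.2, 0.35} min⁻¹ ×
  ve ∈ {0.01, 0.05, 0.1, 0.2, 0.5} at fixed vp = 0.05 (8×8 voxels per
  patch, 1920 tissue voxels), plus an 8-row vessel strip carrying the pure
  plasma curve (vp = 1, ve = Ktrans = 0, blood T10 1660 ms; tissue T10
  1400 ms). Tissue signals are the exact SPGR transform of the model
  concentration curves; the second echo applies a static T2* decay
  (R2* = 20 s⁻¹), so dual-echo correction is exact by construction.
* **Double baselines**: each baseline's parameter maps are the shared
  truth multiplied by independent log-normal factors exp(N(0, σ²)) — σ is
  the per-scan, within-subject log-SD, applied globally or voxelwise — with
  independent Gaussian (optionally Rician) signal noise expressed as a
  fraction of each voxel's pre-bolus baseline. In this model the noise-free
  expected %RC is 1.96·√2·σ·100 (e.g. 27.7% at σ = 0.1), which the
  pipeline recovers within Monte-Carlo error; a summary-level simulator
  (`simulate_summary_cohort`) uses the same perturbation model for fast
  cohort-scale studies (n = 200 runs in milliseconds).

What the phantoms deliberately do **not** emulate: anatomy, motion,
B1 inhomogeneity, flow/inflow enhancement, partial-volume mixing at vessel
boundaries, or concentration-dependent T2*. Passing tests therefore
demonstrate correctness of the estimators and statistics under the stated
signal model — not robustness to those real-data effects, several of which
are known drivers of between-baseline variation in vivo.

## Numerical and design notes

* The ~18% median Ktrans error observed on the reference object at 5%
  signal noise (SNR 20, noisy VFA included) reflects the genuine
  sensitivity of Ktrans estimation to noise at 6 s sampling; the regression
  test bounds it at 20%.
* Problem sizes in the test suite and acceptance script (compact phantom
  grids, 200-subject summary cohorts, 100 random cohorts for the statistic
  oracles) were chosen so the full validation runs in about a minute on one
  CPU while keeping Monte-Carlo error well inside the asserted tolerances.
* Determinism: fixed seeds make every generator bit-reproducible; fits are
  deterministic given initial values (multi-start off by default); cohort
  outputs are byte-identical across reruns.
* The convolution's k·dt → 0 branch switches to the trapezoid limit below
  1e−12 to avoid catastrophic cancellation.
* DICOM ingestion, population VIF models, water-exchange and bookend T1
  corrections, spatial regularization and model selection among nested
  variants are out of scope.
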