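# dcequant

Quantitative analysis of dynamic contrast-enhanced MRI (DCE-MRI) for brain
tumors, with a focus on **test–retest repeatability** of perfusion kinetic
parameters. The package implements the full voxelwise pipeline — variable
flip angle T1 mapping, signal-to-concentration conversion, automatic and
manual vascular input function (VIF) extraction, extended Tofts and leaky
tracer-kinetic model fitting — plus the double-baseline repeatability
statistics (Bland–Altman, within-subject CV, repeatability coefficient)
that turn paired scans into a change-detection threshold. A synthetic
phantom generator with known ground truth makes every stage testable at
desk scale.

Intended users: imaging scientists and analysts who process dynamic
T1-weighted acquisitions into parameter maps (vp, ve, Ktrans, λtr) and need
to know how large a change must be before it exceeds measurement noise.

## Models

Tissue contrast-agent concentration C(t) is driven by the plasma
concentration Cp(t) (the VIF). The **extended Tofts model (eTM)** is

    C(t) = vp Cp(t) + Ktrans ∫₀ᵗ Cp(τ) exp(−(Ktrans/ve)(t−τ)) dτ

with plasma volume fraction vp, extravascular-extracellular volume fraction
ve, and transfer constant Ktrans (min⁻¹). The **leaky tracer-kinetic model
(LTKM)** adds an irreversible accumulation compartment filling at rate λtr:

    C(t) = eTM(t) + λtr ∫₀ᵗ Cp(τ) dτ

Concentration comes from the spoiled-gradient-echo (SPGR) signal equation
via the pre-contrast T1 (T10, mapped with the variable-flip-angle method)
and the relaxivity r1:

    C(t) = (1/r1) (1/T1(t) − 1/T10)

Repeatability of a parameter P over paired baselines (x_j1, x_j2) is
summarized by the log-change d_j = ln(x_j2/x_j1), Bland–Altman limits of
agreement d̄ ± 1.96σ, the within-subject coefficient of variation

    wCV = sqrt( (1/n) Σⱼ ((x_j1 − x_j2)²/2) / x̄ⱼ² )

and the percent repeatability coefficient %RC = 1.96·√2·wCV·100 — the
smallest relative change distinguishable from measurement error at 95%
confidence.

## Worked example

```python
import numpy as np
from dcequant import (
    AcquisitionSpec, PairedCohort, fit_voxel, etm_forward,
    generate_vif, percent_rc, wcv, bland_altman,
)
from dcequant.synthetic import simulate_summary_cohort

spec = AcquisitionSpec()              # 128x128x20, 60 frames at 6 s, bolus at 52 s
cp = generate_vif(spec)               # synthetic plasma curve Cp(t)

# forward-model a tissue curve and fit it back
curve = etm_forward(vp=0.05, ve=0.2, ktrans=0.1, cp=cp.values, t_s=spec.times_s)
params = fit_voxel(curve, cp, model="etm")
print(f"vp={params.vp:.4f}  ve={params.ve:.4f}  "
      f"Ktrans={params.ktrans:.4f} /min  R2={params.r2:.4f}")

# a 29-subject test-retest cohort with 10% per-scan log-normal variation
b1, b2 = simulate_summary_cohort(29, sigma=0.10, seed=7)
cohort = PairedCohort(b1=b1, b2=b2, parameter="ktrans")
bias, (lo, hi) = bland_altman(cohort.d)
print(f"bias={bias:+.3f}  LoA=({lo:+.3f}, {hi:+.3f})  "
      f"%RC={percent_rc(wcv(cohort)):.1f}%")
```

Output:

```
vp=0.0500  ve=0.2000  Ktrans=0.1000 /min  R2=1.0000
bias=-0.006  LoA=(-0.224, +0.212)  %RC=21.4%
```

The first line shows exact recovery of the generating parameters from a
noiseless curve (R² = 1). The second line reads: between the two baselines
the mean log-change in Ktrans is −0.006 (no systematic drift), 95% of
subjects fall within log-limits (−0.224, +0.212), and a change must exceed
about 21% before it is distinguishable from scan-to-scan variation — close
to the analytic value 1.96·√2·0.10·100 ≈ 27.7% once the finite-sample
spread of a 29-subject cohort is accounted for.

## Command line

```bash
dcequant simulate --out cohort/ --subjects 4 --sigma 0.1 --seed 1
dcequant report --config cohort/config.yaml       # full repeatability table
dcequant fit --config cohort/config.yaml --subject sub01 --baseline 1
dcequant validate-dro --model etm                 # phantom recovery check
```

`report` writes `summaries.csv` (per subject/baseline/model/VIF-method ROI
summaries), `repeatability_report.csv` (bias, limits of agreement, %RC,
%CoV per parameter), `qc_t10_shift.csv` (between-baseline T10 histogram
shift, flagging |shift| > 20%), and `exclusions.csv`.

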