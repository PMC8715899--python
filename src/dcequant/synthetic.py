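"""Synthetic DCE-MRI phantoms with known ground truth.

Everything downstream of acquisition is exercisable at desk scale through
three generators:

* :func:`generate_vif` — an analytic plasma input: gamma-variate first pass
  plus a slower recirculation/washout shoulder;
* :func:`generate_dro_phantom` — a digital-reference-object style slice of
  rectangular patches, each a constant (Ktrans, ve) pair at fixed vp, plus a
  vessel strip carrying the pure plasma curve; tissue signals are the exact
  SPGR transform of the kinetic-model concentration curves, so signal
  generation and concentration conversion are mutual inverses on noiseless
  data;
* :func:`generate_double_baseline` — a test-retest pair in which each
  baseline's parameters are independently perturbed from shared truth by a
  multiplicative log-normal factor (sigma is the per-scan within-subject
  log-SD) with independent signal noise per study.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import AcquisitionSpec, DynamicSeries, VIFCurve
from .concentration import DEFAULT_R1
from .pkfit import PARAM_NAMES, etm_forward, ltkm_forward
from .relaxometry import spgr_signal

__all__ = [
    "GroundTruth",
    "VariationModel",
    "SyntheticStudy",
    "DROGrid",
    "generate_vif",
    "concentration_to_signal",
    "generate_dro_phantom",
    "generate_vessel_detection_phantom",
    "generate_double_baseline",
    "simulate_summary_cohort",
]

BLOOD_T10_MS = 1660.0
TISSUE_T10_MS = 1400.0
DEFAULT_M0 = 1000.0
STATIC_R2STAR_PER_MS = 0.02  # baseline T2* decay used for the dual-echo signals


@dataclass
class GroundTruth:
    """Voxelwise true kinetic and relaxometric parameters."""

    vp: np.ndarray
    ve: np.ndarray
    ktrans: np.ndarray  # min^-1
    lambda_tr: np.ndarray  # min^-1
    t10_ms: np.ndarray
    m0: np.ndarray
    vessel_mask: np.ndarray
    tumor_mask: np.ndarray

    def __post_init__(self):
        arrs = [self.vp, self.ve, self.ktrans, self.lambda_tr, self.t10_ms, self.m0]
        shape = arrs[0].shape
        for a in arrs + [self.vessel_mask, self.tumor_mask]:
            if a.shape != shape:
                raise ValueError("all ground-truth arrays must share one shape")
        if np.any(self.vp < 0) or np.any(self.vp > 1):
            raise ValueError("vp must lie in [0, 1]")
        if np.any(self.ve < 0) or np.any(self.ve > 1):
            raise ValueError("ve must lie in [0, 1]")
        if np.any(self.vp + self.ve > 1 + 1e-12):
            raise ValueError("vp + ve must not exceed 1")
        if np.any(self.ktrans < 0) or np.any(self.lambda_tr < 0):
            raise ValueError("rate constants must be non-negative")
        if np.any(self.t10_ms <= 0):
            raise ValueError("T10 must be positive")
        if np.any(self.vessel_mask & self.tumor_mask):
            raise ValueError("vessel and tumor masks must be disjoint")

    @property
    def shape(self) -> tuple:
        return self.vp.shape

    def params(self) -> dict:
        return {
            "vp": self.vp, "ve": self.ve,
            "ktrans": self.ktrans, "lambda_tr": self.lambda_tr,
        }


@dataclass
class VariationModel:
    """Between-baseline variation: log-normal parameter perturbation + noise.

    ``param_sigma`` maps parameter names (vp, ve, ktrans, lambda_tr, t10) to
    the per-scan log-SD of a multiplicative log-normal factor; ``mode``
    selects one factor per study ("global") or one per voxel ("voxelwise").
    ``signal_noise_sd`` is the additive noise SD as a fraction of each
    voxel's pre-bolus baseline signal.
    """

    param_sigma: dict = field(default_factory=dict)
    signal_noise_sd: float = 0.0
    noise: str = "gaussian"
    mode: str = "global"
    seed: int = 0

    def __post_init__(self):
        if any(s < 0 for s in self.param_sigma.values()) or self.signal_noise_sd < 0:
            raise ValueError("variation sigmas must be non-negative")
        if self.noise not in ("gaussian", "rician"):
            raise ValueError("noise must be 'gaussian' or 'rician'")
        if self.mode not in ("global", "voxelwise"):
            raise ValueError("mode must be 'global' or 'voxelwise'")


@dataclass
class SyntheticStudy:
    """One simulated scan session: VFA stack + dynamic series + truth."""

    spec: AcquisitionSpec
    vfa: dict  # flip angle (deg) -> 3D volume
    series: DynamicSeries
    truth: GroundTruth
    vif: VIFCurve  # the true plasma curve, concentration units
    meta: dict = field(default_factory=dict)


def generate_vif(
    spec: AcquisitionSpec,
    amplitude: float = 6.0,
    bolus_width_s: float = 5.0,
    washout_fraction: float = 0.35,
    sharpness: float = 2.0,
    recirc_rise_s: float = 30.0,
    recirc_decay_s: float = 300.0,
    t_s: np.ndarray | None = None,
) -> VIFCurve:
    """Analytic plasma input on the dynamic time grid.

    Gamma-variate bolus ``A (s/tp)^a exp(a (1 - s/tp))`` (unit peak at
    ``s = tp`` after arrival) plus a recirculation shoulder
    ``A w (1 - e^{-s/rise}) e^{-s/decay}``; zero before bolus arrival.
    ``amplitude`` is in mM but the absolute scale is arbitrary — fitted
    vp/ve/Ktrans are relative to the Cp scale supplied to the fit.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if bolus_width_s <= 0 or sharpness <= 0:
        raise ValueError("bolus width and sharpness must be positive")
    if not 0 <= washout_fraction:
        raise ValueError("washout fraction must be non-negative")
    t = spec.times_s if t_s is None else np.asarray(t_s, dtype=float)
    s = np.maximum(t - spec.bolus_arrival_s, 0.0)
    with np.errstate(invalid="ignore"):
        bolus = np.where(
            s > 0,
            (s / bolus_width_s) ** sharpness
            * np.exp(sharpness * (1.0 - s / bolus_width_s)),
            0.0,
        )
    recirc = washout_fraction * (1.0 - np.exp(-s / recirc_rise_s)) * np.exp(
        -s / recirc_decay_s
    )
    cp = amplitude * (bolus + np.where(s > 0, recirc, 0.0))
    return VIFCurve(t_s=t, values=cp, method="synthetic")


def concentration_to_signal(
    c_mM: np.ndarray,
    t10_ms,
    m0,
    tr_ms: float,
    flip_deg: float,
    r1: float = DEFAULT_R1,
) -> np.ndarray:
    """SPGR signal (TE = 0) for a concentration time course.

    1/T1(t) = 1/T10 + r1 C(t); the exact forward of the conversion used in
    analysis, so the round trip is lossless on noiseless data.
    """
    c = np.asarray(c_mM, dtype=float)
    r1_t = 1000.0 / np.asarray(t10_ms, dtype=float) + r1 * c  # s^-1
    t1_ms = 1000.0 / r1_t
    return spgr_signal(m0, t1_ms, tr_ms, flip_deg)


@dataclass(frozen=True)
class DROGrid:
    """Patch layout of the reference-object phantom."""

    ktrans_values: tuple = (0.01, 0.02, 0.05, 0.1, 0.2, 0.35)  # min^-1
    ve_values: tuple = (0.01, 0.05, 0.1, 0.2, 0.5)
    vp: float = 0.05
    lambda_tr: float = 0.0  # min^-1; > 0 makes the tissue follow the leaky model
    patch_shape: tuple = (8, 8)
    vessel_rows: int = 8

    def __post_init__(self):
        if any(self.vp + ve > 1 for ve in self.ve_values):
            raise ValueError("grid has patches with vp + ve > 1")
        if any(k < 0 for k in self.ktrans_values) or self.lambda_tr < 0:
            raise ValueError("rate constants must be non-negative")


def generate_dro_phantom(
    spec: AcquisitionSpec | None = None,
    grid: DROGrid | None = None,
    variation: VariationModel | None = None,
    r1: float = DEFAULT_R1,
) -> SyntheticStudy:
    """Single-slice reference-object phantom with known (Ktrans, ve) patches.

    Columns sweep Ktrans, rows sweep ve; a vessel strip along the top rows
    carries the pure plasma curve (vp = 1, ve = Ktrans = 0). The acquisition
    timing comes from ``spec`` (its matrix size is replaced by the grid
    geometry); signals are noiseless unless a :class:`VariationModel` with
    ``signal_noise_sd > 0`` is supplied.
    """
    spec = spec or AcquisitionSpec()
    grid = grid or DROGrid()
    ph, pw = grid.patch_shape
    nx = pw * len(grid.ktrans_values)
    ny = ph * len(grid.ve_values) + grid.vessel_rows
    spec = spec.with_matrix(nx, ny, 1)
    shape = spec.shape

    vp = np.zeros(shape)
    ve = np.zeros(shape)
    kt = np.zeros(shape)
    lam = np.zeros(shape)
    t10 = np.full(shape, TISSUE_T10_MS)
    m0 = np.full(shape, DEFAULT_M0)
    vessel = np.zeros(shape, dtype=bool)
    tumor = np.zeros(shape, dtype=bool)

    vessel[:, :grid.vessel_rows, 0] = True
    vp[vessel] = 1.0
    t10[vessel] = BLOOD_T10_MS
    for j, ve_val in enumerate(grid.ve_values):
        y0 = grid.vessel_rows + j * ph
        for i, kt_val in enumerate(grid.ktrans_values):
            x0 = i * pw
            sl = (slice(x0, x0 + pw), slice(y0, y0 + ph), 0)
            vp[sl] = grid.vp
            ve[sl] = ve_val
            kt[sl] = kt_val
            lam[sl] = grid.lambda_tr
            tumor[sl] = True

    truth = GroundTruth(
        vp=vp, ve=ve, ktrans=kt, lambda_tr=lam, t10_ms=t10, m0=m0,
        vessel_mask=vessel, tumor_mask=tumor,
    )
    vif = generate_vif(spec)
    study = _render_study(spec, truth, vif, r1=r1)
    if variation is not None and variation.signal_noise_sd > 0:
        rng = np.random.default_rng(variation.seed)
        study = _add_noise(study, variation, rng)
    return study


def _render_study(
    spec: AcquisitionSpec,
    truth: GroundTruth,
    vif: VIFCurve,
    r1: float = DEFAULT_R1,
    meta: dict | None = None,
) -> SyntheticStudy:
    """Forward-model VFA volumes and the dynamic series from ground truth."""
    t = spec.times_s
    cp = vif.values
    shape = truth.shape
    conc = np.zeros(shape + (spec.n_frames,))

    # tissue curves share kinetics within a patch; cache by parameter tuple
    cache: dict = {}
    flat = np.stack(
        [truth.vp.ravel(), truth.ve.ravel(), truth.ktrans.ravel(),
         truth.lambda_tr.ravel()], axis=1,
    )
    conc_flat = conc.reshape(-1, spec.n_frames)
    for i, row in enumerate(flat):
        key = tuple(row)
        if key not in cache:
            vp_i, ve_i, kt_i, lam_i = row
            cache[key] = ltkm_forward(vp_i, ve_i, kt_i, lam_i, cp, t) if lam_i > 0 \
                else etm_forward(vp_i, ve_i, kt_i, cp, t)
        conc_flat[i] = cache[key]

    sig0 = concentration_to_signal(
        conc, truth.t10_ms[..., None], truth.m0[..., None],
        spec.tr_ms, spec.flip_deg, r1=r1,
    )
    e1 = sig0 * np.exp(-spec.te1_ms * STATIC_R2STAR_PER_MS)
    e2 = sig0 * np.exp(-spec.te2_ms * STATIC_R2STAR_PER_MS)
    series = DynamicSeries(data=e1, spec=spec, data2=e2)
    vfa = {
        a: spgr_signal(truth.m0, truth.t10_ms, spec.vfa_tr_ms, a)
        for a in spec.vfa_angles_deg
    }
    return SyntheticStudy(
        spec=spec, vfa=vfa, series=series, truth=truth, vif=vif,
        meta=dict(meta or {}, r1=r1),
    )


def _add_noise(study: SyntheticStudy, variation: VariationModel, rng) -> SyntheticStudy:
    sd_frac = variation.signal_noise_sd
    base = study.series.data[..., : study.spec.baseline_frames].mean(axis=-1)
    sd = sd_frac * base[..., None]

    def noisy(arr, sd_arr):
        if variation.noise == "rician":
            n1 = rng.normal(0.0, 1.0, arr.shape) * sd_arr
            n2 = rng.normal(0.0, 1.0, arr.shape) * sd_arr
            return np.sqrt((arr + n1) ** 2 + n2**2)
        return arr + rng.normal(0.0, 1.0, arr.shape) * sd_arr

    e1 = noisy(study.series.data, sd)
    e2 = noisy(study.series.data2, sd) if study.series.data2 is not None else None
    vfa = {a: noisy(v, sd_frac * v.mean()) for a, v in study.vfa.items()}
    return SyntheticStudy(
        spec=study.spec,
        vfa=vfa,
        series=DynamicSeries(data=e1, spec=study.spec, data2=e2),
        truth=study.truth,
        vif=study.vif,
        meta=dict(study.meta, noise_sd=sd_frac, noise_model=variation.noise),
    )


def _perturb_factors(rng, sigma: float, shape, mode: str) -> np.ndarray:
    """Multiplicative log-normal factors exp(N(0, sigma^2))."""
    if sigma == 0:
        return np.ones(shape)
    if mode == "global":
        return np.full(shape, np.exp(rng.normal(0.0, sigma)))
    return np.exp(rng.normal(0.0, sigma, shape))


def _perturbed_truth(truth: GroundTruth, variation: VariationModel, rng) -> GroundTruth:
    sig = variation.param_sigma
    new = {}
    for name in PARAM_NAMES:
        arr = getattr(truth, name)
        new[name] = arr * _perturb_factors(rng, sig.get(name, 0.0), arr.shape, variation.mode)
    t10 = truth.t10_ms * _perturb_factors(rng, sig.get("t10", 0.0), truth.shape, variation.mode)
    # keep fractions physical after perturbation
    new["vp"] = np.clip(new["vp"], 0.0, 1.0)
    new["ve"] = np.clip(new["ve"], 0.0, 1.0 - new["vp"])
    return GroundTruth(
        vp=new["vp"], ve=new["ve"], ktrans=new["ktrans"], lambda_tr=new["lambda_tr"],
        t10_ms=t10, m0=truth.m0.copy(),
        vessel_mask=truth.vessel_mask.copy(), tumor_mask=truth.tumor_mask.copy(),
    )


def generate_double_baseline(
    spec: AcquisitionSpec,
    truth: GroundTruth,
    variation: VariationModel,
    r1: float = DEFAULT_R1,
) -> tuple:
    """Simulate a test-retest pair (baseline 1, baseline 2).

    Each baseline's kinetic parameters are the shared truth times an
    independent log-normal factor exp(N(0, sigma^2)) — sigma is the
    per-scan, within-subject log-SD — and each study receives independent
    signal noise. With all sigmas zero the two studies are bit-identical.
    The seeds used for each study are recorded in the output metadata.
    """
    root = np.random.SeedSequence(variation.seed)
    children = root.spawn(2)
    studies = []
    for b, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        truth_b = _perturbed_truth(truth, variation, rng)
        study = _render_study(
            spec, truth_b, generate_vif(spec), r1=r1,
            meta={"baseline": b, "spawn_key": list(child.spawn_key),
                  "seed": variation.seed},
        )
        if variation.signal_noise_sd > 0:
            study = _add_noise(study, variation, rng)
        studies.append(study)
    return tuple(studies)


def generate_vessel_detection_phantom(
    spec: AcquisitionSpec | None = None,
    n_vessel: int = 50,
    shape: tuple = (20, 20, 2),
    baseline_signal: float = 100.0,
    vessel_amplitude: float = 400.0,
    include_boundary_voxels: bool = False,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple:
    """Signal-domain phantom for exercising automatic VIF voxel selection.

    Plants ``n_vessel`` voxels with rapid enhancement (peak 6-8 s after
    arrival, amplitude far above the whole-image 90th percentile of
    temporal maxima) in a sea of slowly, monotonically enhancing tissue
    (time-to-peak of minutes). With ``include_boundary_voxels`` two
    threshold-case voxels are added: one peaking exactly 12 s after arrival
    and one with a fast shape at half the selection amplitude — both must be
    rejected. Returns ``(DynamicSeries, planted_indices)``.
    """
    spec = (spec or AcquisitionSpec()).with_matrix(*shape)
    t = spec.times_s
    t0 = spec.bolus_arrival_s
    s = np.maximum(t - t0, 0.0)
    rng = np.random.default_rng(seed)

    n_vox = int(np.prod(shape))
    if n_vessel + 2 >= n_vox:
        raise ValueError("phantom too small for the requested vessel count")

    # slow tissue: monotone saturating enhancement, peak at the final frame
    data = np.empty(shape + (spec.n_frames,))
    flat = data.reshape(n_vox, -1)
    amps = 20.0 + 40.0 * (np.arange(n_vox) % 17) / 16.0  # heterogeneous, deterministic
    flat[:] = baseline_signal + amps[:, None] * (1.0 - np.exp(-s / 120.0))[None, :]

    # fast vessel shape: sharp rise, peak ~6 s after arrival, partial washout
    g = np.where(s > 0, (s / 6.0) ** 2 * np.exp(2.0 * (1.0 - s / 6.0)), 0.0)
    g = g + np.where(s > 0, 0.3 * (1.0 - np.exp(-s / 30.0)), 0.0)
    g /= g.max()

    order = rng.permutation(n_vox)
    vessel_flat = np.sort(order[:n_vessel])
    flat[vessel_flat] = baseline_signal + vessel_amplitude * g[None, :]

    extras = []
    if include_boundary_voxels:
        slow_peak, half_amp = order[n_vessel], order[n_vessel + 1]
        # peak exactly 12 s after its detected arrival frame
        arrival_frame = int(np.searchsorted(t, t0, side="right"))
        y = np.full(spec.n_frames, baseline_signal)
        y[arrival_frame] = baseline_signal + 0.4 * vessel_amplitude
        y[arrival_frame + 1] = baseline_signal + 0.7 * vessel_amplitude
        y[arrival_frame + 2] = baseline_signal + vessel_amplitude  # +12 s
        y[arrival_frame + 3:] = baseline_signal + 0.3 * vessel_amplitude
        flat[slow_peak] = y
        # fast shape at half the selection threshold: below the whole-image
        # 90th percentile of per-voxel maxima, so amplitude alone rejects it
        threshold = np.percentile(flat.max(axis=1), 90.0)
        flat[half_amp] = baseline_signal + 0.5 * (threshold - baseline_signal) * g
        extras = [int(slow_peak), int(half_amp)]

    if noise_sd > 0:
        flat += rng.normal(0.0, noise_sd * baseline_signal, flat.shape)

    planted = [tuple(int(q) for q in np.unravel_index(i, shape)) for i in vessel_flat]
    series = DynamicSeries(data=data, spec=spec)
    series_meta = {"planted": planted, "boundary": extras}
    series.meta = series_meta
    return series, planted


def simulate_summary_cohort(
    n_subjects: int,
    sigma: float,
    seed: int = 0,
    population_median: float = 0.1,
    population_log_sd: float = 0.5,
) -> tuple:
    """Paired per-subject parameter summaries for repeatability studies.

    Subject truths are log-normal across the population; each baseline
    observes truth times an independent exp(N(0, sigma^2)) factor — the same
    per-scan variation model used by :func:`generate_double_baseline`, so in
    the noise-free limit the expected %RC is 1.96 * sqrt(2) * sigma * 100.
    Returns ``(b1, b2)`` arrays of length ``n_subjects``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    truth = population_median * np.exp(rng.normal(0.0, population_log_sd, n_subjects))
    b1 = truth * _perturb_factors(rng, sigma, n_subjects, "voxelwise")
    b2 = truth * _perturb_factors(rng, sigma, n_subjects, "voxelwise")
    return b1, b2
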