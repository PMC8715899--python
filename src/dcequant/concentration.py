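"""Signal-to-concentration conversion and dual-echo T2* correction.

A dynamic SPGR signal time course is converted to contrast-agent
concentration through the longitudinal relaxation rate:

    C(t) = (1/r1) * (1/T1(t) - 1/T10),
    1/T1(t) = -(1/TR) * ln((1 - A) / (1 - A cos(a))),
    A = (S(t)/S(0)) * (1 - E10) / (1 - E10 cos(a)),   E10 = exp(-TR/T10),

with S(0) the mean of the designated pre-bolus frames. On noiseless SPGR
data this is the exact algebraic inverse of signal generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AcquisitionSpec, DynamicSeries, VIFCurve
from .relaxometry import T1Map

__all__ = [
    "ConcentrationSeries",
    "dual_echo_correct",
    "signal_to_concentration",
    "concentration_scalar",
    "vif_signal_to_concentration",
    "DEFAULT_R1",
]

# longitudinal relaxivity of a gadolinium chelate at 3 T, s^-1 mM^-1
DEFAULT_R1 = 3.7

#: sentinel written into voxels whose conversion is undefined
SENTINEL = np.nan


@dataclass
class ConcentrationSeries:
    """Voxelwise contrast-agent concentration C(t), mM."""

    data: np.ndarray  # (x, y, z, t)
    t_s: np.ndarray
    r1: float
    baseline_frames: int
    flagged: np.ndarray = field(default=None)  # True where conversion failed

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.t_s = np.asarray(self.t_s, dtype=float)
        if self.data.shape[-1] != self.t_s.size:
            raise ValueError("time grid does not match frame count")
        if self.flagged is None:
            self.flagged = np.zeros(self.data.shape[:-1], dtype=bool)
        self.flagged = np.asarray(self.flagged, dtype=bool)

    @property
    def shape(self) -> tuple:
        return self.data.shape[:-1]


def dual_echo_correct(S1, S2, te1_ms: float, te2_ms: float):
    """Extrapolate a dual-echo signal pair to TE = 0.

    Assumes mono-exponential T2* decay between the echoes:
    R2* = ln(S1/S2) / (TE2 - TE1) and S0 = S1 * exp(TE1 * R2*).
    """
    if not 0 < te1_ms < te2_ms:
        raise ValueError("need 0 < TE1 < TE2")
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    if np.any(S1 <= 0) or np.any(S2 <= 0):
        raise ValueError("dual-echo correction requires strictly positive signals")
    r2star = np.log(S1 / S2) / (te2_ms - te1_ms)  # ms^-1
    return S1 * np.exp(te1_ms * r2star)


def concentration_scalar(t1_t_ms, t10_ms, r1: float = DEFAULT_R1):
    """C in mM from instantaneous T1 and pre-contrast T10 (both ms)."""
    r1_t = 1000.0 / np.asarray(t1_t_ms, dtype=float)  # s^-1
    r10 = 1000.0 / np.asarray(t10_ms, dtype=float)
    return (r1_t - r10) / r1


def _signal_ratio_to_concentration(ratio, t10_ms, tr_ms, alpha_deg, r1):
    """Core of Eqs. relating S(t)/S(0) to C(t); vectorised, NaN where invalid."""
    cos_a = np.cos(np.deg2rad(alpha_deg))
    e10 = np.exp(-tr_ms / t10_ms)
    a_fac = (1.0 - e10) / (1.0 - e10 * cos_a)
    A = ratio * a_fac
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = (1.0 - A) / (1.0 - A * cos_a)
        # A is the saturation fraction; values outside [0, 1) have no SPGR
        # solution (signal above the T1 -> 0 limit) and are flagged
        bad = ~np.isfinite(arg) | (arg <= 0) | (A >= 1.0) | (A < 0)
        r1_t = np.where(bad, np.nan, -np.log(np.where(bad, 1.0, arg)) / tr_ms)  # ms^-1
    r10 = 1.0 / t10_ms
    c = 1000.0 * (r1_t - r10) / r1  # ms^-1 -> s^-1, then / r1
    return c, bad


def signal_to_concentration(
    series: DynamicSeries,
    t1map: T1Map,
    r1: float = DEFAULT_R1,
    baseline_frames: int | None = None,
) -> ConcentrationSeries:
    """Convert a dynamic series to concentration using a voxelwise T10 map.

    Voxels with invalid T10, non-positive baseline signal, or a log argument
    outside (0, inf) at any frame are flagged and set to NaN — never clamped.
    """
    spec = series.spec
    if baseline_frames is None:
        baseline_frames = spec.baseline_frames
    if baseline_frames < 1:
        raise ValueError("need at least one baseline frame")
    if t1map.t10_ms.shape != series.shape:
        raise ValueError("T1 map geometry does not match the dynamic series")

    S = series.data
    s0 = S[..., :baseline_frames].mean(axis=-1)
    voxel_bad = ~t1map.valid | ~(s0 > 0) | ~np.isfinite(s0)

    t10 = np.where(voxel_bad, 1000.0, t1map.t10_ms)  # placeholder on bad voxels
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = S / s0[..., None]
    c, frame_bad = _signal_ratio_to_concentration(
        ratio, t10[..., None], spec.tr_ms, spec.flip_deg, r1
    )
    flagged = voxel_bad | frame_bad.any(axis=-1)
    c = np.where(flagged[..., None], SENTINEL, c)
    return ConcentrationSeries(
        data=c,
        t_s=spec.times_s,
        r1=r1,
        baseline_frames=baseline_frames,
        flagged=flagged,
    )


def vif_signal_to_concentration(
    vif: VIFCurve,
    spec: AcquisitionSpec,
    r1: float = DEFAULT_R1,
    baseline_frames: int | None = None,
    t10_ms: float | None = None,
) -> VIFCurve:
    """Convert a signal-domain VIF to plasma concentration Cp(t).

    Uses the mean pre-contrast T1 of the contributing voxels (stored on the
    curve, or passed explicitly). Dual-echo correction, when applicable, is
    done upstream on the per-echo signals before averaging.
    """
    t10 = t10_ms if t10_ms is not None else vif.mean_t10_ms
    if t10 is None or not np.isfinite(t10) or t10 <= 0:
        raise ValueError("a positive mean T10 is required to convert the VIF")
    if baseline_frames is None:
        baseline_frames = spec.baseline_frames
    s0 = float(np.mean(vif.values[:baseline_frames]))
    if s0 <= 0:
        raise ValueError("non-positive pre-bolus VIF signal")
    c, bad = _signal_ratio_to_concentration(
        vif.values / s0, float(t10), spec.tr_ms, spec.flip_deg, r1
    )
    if np.any(bad):
        raise ValueError("VIF signal leaves the valid SPGR range; cannot convert")
    return VIFCurve(
        t_s=vif.t_s.copy(),
        values=c,
        method=vif.method,
        voxel_indices=list(vif.voxel_indices),
        mean_t10_ms=float(t10),
        normalization=vif.normalization,
    )
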