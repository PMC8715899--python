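"""Variable-flip-angle (VFA) T1 mapping and T10 histogram-shift QC.

The spoiled gradient-recalled echo (SPGR) steady-state signal is

    S = M0 * sin(a) * (1 - E) / (1 - E cos(a)),   E = exp(-TR / T1),

which is linear in ``S/tan(a)`` versus ``S/sin(a)``; T1 and M0 are estimated
per voxel by that linear regression followed by an optional nonlinear
refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "T1Map",
    "spgr_signal",
    "VFAT1Mapper",
    "fit_t10_vfa",
    "histogram_peak",
    "t10_shift",
    "t10_shift_maps",
    "T10_SHIFT_OUTLIER_THRESHOLD",
]

# |T10 shift| above this fraction flags a between-baseline QC outlier
# (typically large B1-field inhomogeneity).
T10_SHIFT_OUTLIER_THRESHOLD = 0.20

# physically plausible window for brain T1 at 3 T; fits outside are flagged
T1_FLOOR_MS = 1.0
T1_CEIL_MS = 10_000.0


@dataclass
class T1Map:
    """Voxelwise pre-contrast T1 (T10, ms) and equilibrium signal M0."""

    t10_ms: np.ndarray
    m0: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.t10_ms = np.asarray(self.t10_ms, dtype=float)
        self.m0 = np.asarray(self.m0, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.t10_ms.shape == self.m0.shape == self.valid.shape):
            raise ValueError("T1Map fields must share one shape")


def spgr_signal(m0, t1_ms, tr_ms, alpha_deg):
    """SPGR steady-state signal (TE = 0 amplitude).

    Parameters may be scalars or broadcastable arrays; T1 and TR in ms,
    flip angle in degrees.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    if np.any(np.asarray(tr_ms, dtype=float) <= 0):
        raise ValueError("TR must be positive")
    a = np.deg2rad(alpha_deg)
    if np.any((np.asarray(alpha_deg) <= 0) | (np.asarray(alpha_deg) >= 180)):
        raise ValueError("flip angle must be in (0, 180) degrees")
    e = np.exp(-np.asarray(tr_ms, dtype=float) / t1)
    return np.asarray(m0, dtype=float) * np.sin(a) * (1.0 - e) / (1.0 - e * np.cos(a))


class VFAT1Mapper:
    """Estimator mapping multi-angle SPGR signals to (T10, M0) per voxel.

    Parameters
    ----------
    angles_deg : sequence of float
        Flip angles of the acquired volumes (>= 2 distinct values).
    tr_ms : float
        Repetition time of the VFA sequence, ms.
    refine : bool
        Run a per-voxel nonlinear least-squares refinement after the
        linearized fit. On noiseless data the linear fit is already exact;
        refinement mostly matters for noisy, low-angle-count data.

    Attributes (after :meth:`fit`)
    ------------------------------
    t10_ms_, m0_ : ndarray, one value per input sample
    valid_ : boolean ndarray, False where the voxel was degenerate or the
        fit left the physical window (value retained, not clipped).
    """

    def __init__(self, angles_deg, tr_ms, refine: bool = True):
        self.angles_deg = tuple(float(a) for a in angles_deg)
        self.tr_ms = float(tr_ms)
        self.refine = refine

    # sklearn-style parameter plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {"angles_deg": self.angles_deg, "tr_ms": self.tr_ms, "refine": self.refine}

    def set_params(self, **params) -> "VFAT1Mapper":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, S: np.ndarray, y=None) -> "VFAT1Mapper":
        """Fit every row of ``S`` (shape ``(n_voxels, n_angles)``)."""
        S = np.atleast_2d(np.asarray(S, dtype=float))
        angles = np.asarray(self.angles_deg, dtype=float)
        if len(np.unique(angles)) < 2:
            raise ValueError("VFA fitting needs at least 2 distinct flip angles")
        if S.shape[1] != angles.size:
            raise ValueError("signal columns must match the number of flip angles")
        if np.any(S[np.isfinite(S)] < 0):
            raise ValueError("VFA signals must be non-negative")

        a = np.deg2rad(angles)
        sin_a, tan_a = np.sin(a), np.tan(a)

        n = S.shape[0]
        t10 = np.full(n, np.nan)
        m0 = np.full(n, np.nan)
        valid = np.zeros(n, dtype=bool)

        finite = np.all(np.isfinite(S), axis=1)
        nonzero = np.any(S > 0, axis=1)
        usable = finite & nonzero

        y_lin = S[usable] / sin_a  # (m, k)
        x_lin = S[usable] / tan_a
        xm = x_lin.mean(axis=1, keepdims=True)
        ym = y_lin.mean(axis=1, keepdims=True)
        sxx = np.sum((x_lin - xm) ** 2, axis=1)
        sxy = np.sum((x_lin - xm) * (y_lin - ym), axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(sxx > 0, sxy / sxx, np.nan)
            intercept = ym[:, 0] - slope * xm[:, 0]
            ok = (slope > 0) & (slope < 1)
            t1_est = np.where(ok, -self.tr_ms / np.log(np.where(ok, slope, 0.5)), np.nan)
            m0_est = np.where(ok, intercept / (1.0 - slope), np.nan)

        if self.refine:
            idx_ok = np.flatnonzero(ok)
            for i in idx_ok:
                t1_est[i], m0_est[i] = self._refine_voxel(
                    S[usable][i], angles, t1_est[i], m0_est[i]
                )

        t10[usable] = t1_est
        m0[usable] = m0_est
        in_window = (
            np.isfinite(t10)
            & np.isfinite(m0)
            & (t10 >= T1_FLOOR_MS)
            & (t10 <= T1_CEIL_MS)
        )
        valid[:] = in_window
        self.t10_ms_ = t10
        self.m0_ = m0
        self.valid_ = valid
        self.n_features_in_ = angles.size
        return self

    def _refine_voxel(self, s, angles, t1_0, m0_0):
        def resid(p):
            return spgr_signal(p[1], p[0], self.tr_ms, angles) - s

        try:
            res = least_squares(
                resid,
                x0=[t1_0, m0_0],
                bounds=([T1_FLOOR_MS, 0.0], [T1_CEIL_MS, np.inf]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=200,
            )
            return res.x[0], res.x[1]
        except Exception:  # pragma: no cover - defensive
            return t1_0, m0_0

    def predict(self, angles_deg=None) -> np.ndarray:
        """Forward-model signals at ``angles_deg`` from the fitted maps."""
        if not hasattr(self, "t10_ms_"):
            raise RuntimeError("call fit() first")
        angles = np.asarray(self.angles_deg if angles_deg is None else angles_deg)
        return spgr_signal(
            self.m0_[:, None], self.t10_ms_[:, None], self.tr_ms, angles[None, :]
        )


def fit_t10_vfa(vfa_signals: np.ndarray, angles_deg, tr_ms: float, refine: bool = True) -> T1Map:
    """Fit a T1Map from a stack of SPGR volumes.

    ``vfa_signals`` has the flip angle on the last axis; any leading shape
    (a flat voxel list or a 3D volume) is preserved in the output maps.
    Degenerate voxels (all-zero or non-finite) are flagged invalid and never
    abort the fit of the rest of the volume.
    """
    sig = np.asarray(vfa_signals, dtype=float)
    lead = sig.shape[:-1]
    mapper = VFAT1Mapper(angles_deg, tr_ms, refine=refine).fit(sig.reshape(-1, sig.shape[-1]))
    return T1Map(
        t10_ms=mapper.t10_ms_.reshape(lead),
        m0=mapper.m0_.reshape(lead),
        valid=mapper.valid_.reshape(lead),
    )


def histogram_peak(
    values: np.ndarray,
    mask: np.ndarray | None = None,
    bins: int = 100,
    range_ms: tuple = (0.0, 5000.0),
    intensity_floor: float = 0.0,
) -> float:
    """Mode of a fixed-bin histogram: center of the most populated bin.

    Used on whole-volume T10 maps; ``intensity_floor`` drops background
    voxels when no explicit mask is available.
    """
    v = np.asarray(values, dtype=float).ravel()
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        if not m.any():
            raise ValueError("mask selects no voxels")
        v = v[m]
    v = v[np.isfinite(v) & (v > intensity_floor)]
    if v.size == 0:
        raise ValueError("no voxels available for the histogram")
    counts, edges = np.histogram(v, bins=bins, range=range_ms)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def t10_shift(p1: float, p2: float) -> tuple:
    """Signed fractional shift between two histogram peaks.

    Shift = (P1 - P2) / P1. Returns ``(shift, is_outlier)`` where the
    outlier flag marks |shift| above 20%.
    """
    if p1 == 0:
        raise ValueError("baseline-1 histogram peak is zero; shift undefined")
    shift = (p1 - p2) / p1
    return float(shift), bool(abs(shift) > T10_SHIFT_OUTLIER_THRESHOLD)


def t10_shift_maps(
    map_b1: T1Map,
    map_b2: T1Map,
    mask: np.ndarray | None = None,
    bins: int = 100,
    range_ms: tuple = (0.0, 5000.0),
) -> tuple:
    """T10 histogram shift between two baseline maps over a shared mask."""
    if map_b1.t10_ms.shape != map_b2.t10_ms.shape:
        raise ValueError("maps must share geometry")
    p1 = histogram_peak(map_b1.t10_ms, mask=mask, bins=bins, range_ms=range_ms)
    p2 = histogram_peak(map_b2.t10_ms, mask=mask, bins=bins, range_ms=range_ms)
    return t10_shift(p1, p2)
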