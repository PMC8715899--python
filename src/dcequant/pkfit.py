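"""Tracer-kinetic forward models and voxelwise nonlinear fitting.

Two nested compartment models describe the tissue concentration C(t) driven
by the plasma input Cp(t):

extended Tofts (eTM)
    C(t) = vp Cp(t) + Ktrans \\int_0^t Cp(u) exp(-(Ktrans/ve)(t-u)) du

leaky tracer-kinetic model (LTKM)
    eTM + lambda_tr \\int_0^t Cp(u) du

with plasma volume fraction vp, interstitial volume fraction ve, transfer
constant Ktrans (min^-1) and irreversible leakage rate lambda_tr (min^-1).
The convolution uses an exponential-kernel recursion that is exact for a
piecewise-linear Cp, which is accurate at coarse (several-second) temporal
sampling where FFT quadrature is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .concentration import ConcentrationSeries
from .core import VIFCurve

__all__ = [
    "PKParams",
    "ParamMap",
    "exp_convolve",
    "cumulative_integral",
    "etm_forward",
    "ltkm_forward",
    "r_squared",
    "good_fit_mask",
    "TracerKineticModel",
    "fit_voxel",
    "fit_roi",
    "R2_GOOD_FIT",
    "PARAM_NAMES",
]

R2_GOOD_FIT = 0.5  # voxels with R^2 <= 0.5 are poor fits (typically necrotic)
PARAM_NAMES = ("vp", "ve", "ktrans", "lambda_tr")

DEFAULT_INIT = {"vp": 0.02, "ve": 0.1, "ktrans": 0.05, "lambda_tr": 0.001}
DEFAULT_BOUNDS = {
    "vp": (0.0, 1.0),
    "ve": (1e-6, 1.0),
    "ktrans": (0.0, 10.0),
    "lambda_tr": (0.0, 10.0),
}


@dataclass
class PKParams:
    """One voxel's kinetic parameters and fit quality."""

    vp: float
    ve: float
    ktrans: float  # min^-1
    lambda_tr: float = 0.0  # min^-1, LTKM only
    r2: float = np.nan
    flagged: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.vp, self.ve, self.ktrans, self.lambda_tr])


def exp_convolve(t_s: np.ndarray, cp: np.ndarray, kep_per_min: float) -> np.ndarray:
    """``I(t_n) = int_0^{t_n} cp(u) exp(-kep (t_n - u)) du`` (t in s, kep in min^-1).

    Recursive evaluation, exact when cp is piecewise linear on the grid;
    numerically stable for arbitrarily large kep (no growing exponentials).
    Returns the integral in (cp units) * seconds.
    """
    t = np.asarray(t_s, dtype=float)
    c = np.asarray(cp, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError("time grid and cp must be equal-length 1D arrays")
    k = kep_per_min / 60.0  # s^-1
    out = np.zeros_like(c)
    if k < 0:
        raise ValueError("kep must be non-negative")
    for i in range(1, t.size):
        dt = t[i] - t[i - 1]
        if dt <= 0:
            raise ValueError("time grid must be strictly increasing")
        a, b = c[i - 1], c[i]
        if k * dt < 1e-12:
            seg = 0.5 * (a + b) * dt  # trapezoid limit of the exact kernel
            decay = 1.0 - k * dt
        else:
            decay = np.exp(-k * dt)
            m = (b - a) / dt
            # int_0^dt (b - m u) e^{-k u} du
            seg = b * (1.0 - decay) / k - m * (1.0 - decay * (1.0 + k * dt)) / (k * k)
        out[i] = out[i - 1] * decay + seg
    return out


def cumulative_integral(t_s: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """Trapezoidal ``int_0^t cp du`` in (cp units) * seconds."""
    t = np.asarray(t_s, dtype=float)
    c = np.asarray(cp, dtype=float)
    out = np.zeros_like(c)
    np.cumsum(0.5 * (c[1:] + c[:-1]) * np.diff(t), out=out[1:])
    return out


def _check_rate_params(ktrans: float, ve: float):
    if ktrans < 0:
        raise ValueError("Ktrans must be non-negative")
    if ktrans > 0 and ve <= 0:
        raise ValueError("ve must be positive when Ktrans > 0")


def etm_forward(
    vp: float, ve: float, ktrans: float, cp: np.ndarray, t_s: np.ndarray
) -> np.ndarray:
    """Extended Tofts tissue concentration on the grid of ``cp``."""
    _check_rate_params(ktrans, ve)
    cp = np.asarray(cp, dtype=float)
    out = vp * cp
    if ktrans > 0:
        kep = ktrans / ve
        out = out + (ktrans / 60.0) * exp_convolve(t_s, cp, kep)
    return out


def ltkm_forward(
    vp: float,
    ve: float,
    ktrans: float,
    lambda_tr: float,
    cp: np.ndarray,
    t_s: np.ndarray,
) -> np.ndarray:
    """Leaky tracer-kinetic model: eTM plus an irreversible leakage term."""
    if lambda_tr < 0:
        raise ValueError("lambda_tr must be non-negative")
    out = etm_forward(vp, ve, ktrans, cp, t_s)
    if lambda_tr != 0:
        out = out + (lambda_tr / 60.0) * cumulative_integral(t_s, cp)
    return out


def r_squared(data: np.ndarray, model: np.ndarray) -> float:
    """Coefficient of determination R^2 = 1 - SSerr/SStot.

    Returns NaN when the data are constant (SStot = 0, undefined); values
    below 0 indicate a fit worse than the data mean.
    """
    d = np.asarray(data, dtype=float)
    m = np.asarray(model, dtype=float)
    if d.size < 3:
        raise ValueError("R^2 needs at least 3 points")
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    if ss_tot == 0:
        return np.nan
    ss_err = float(np.sum((d - m) ** 2))
    return 1.0 - ss_err / ss_tot


def good_fit_mask(r2_values: np.ndarray, threshold: float = R2_GOOD_FIT) -> np.ndarray:
    """Strict R^2 > threshold filter (NaN never passes)."""
    r2 = np.asarray(r2_values, dtype=float)
    with np.errstate(invalid="ignore"):
        return r2 > threshold


class TracerKineticModel:
    """Estimator fitting eTM or LTKM parameters to concentration curves.

    Parameters
    ----------
    t_s, cp : arrays
        Shared time grid (s) and plasma input Cp(t) for every voxel.
    model : {"etm", "ltkm"}
    x0, bounds : dict, optional
        Per-parameter initial values / (lo, hi) box bounds; defaults are
        vp=0.02, ve=0.1, Ktrans=0.05 min^-1, lambda_tr=0.001 min^-1 inside
        [0,1] x (0,1] x [0,10] x [0,10].
    multistart : int
        Extra jittered restarts (best SSerr wins); 0 keeps the fit fully
        deterministic and is the default.

    Attributes (after :meth:`fit`)
    ------------------------------
    params_ : (n_voxels, 4) array of (vp, ve, ktrans, lambda_tr)
    r_squared_ : (n_voxels,) array
    flagged_ : boolean array, True where the voxel was degenerate (constant
        or non-finite curve) or the optimizer failed; such voxels carry NaN
        parameters rather than raising.
    """

    def __init__(
        self,
        t_s=None,
        cp=None,
        model: str = "etm",
        x0: dict | None = None,
        bounds: dict | None = None,
        multistart: int = 0,
        random_state: int | None = None,
    ):
        self.t_s = t_s
        self.cp = cp
        self.model = model
        self.x0 = x0
        self.bounds = bounds
        self.multistart = multistart
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "t_s": self.t_s,
            "cp": self.cp,
            "model": self.model,
            "x0": self.x0,
            "bounds": self.bounds,
            "multistart": self.multistart,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "TracerKineticModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals ---------------------------------------------------------
    def _setup(self):
        if self.model not in ("etm", "ltkm"):
            raise ValueError("model must be 'etm' or 'ltkm'")
        if self.t_s is None or self.cp is None:
            raise ValueError("t_s and cp must be set before fitting")
        t = np.asarray(self.t_s, dtype=float)
        cp = np.asarray(self.cp, dtype=float)
        if t.shape != cp.shape:
            raise ValueError("t_s and cp must share one grid")
        names = PARAM_NAMES if self.model == "ltkm" else PARAM_NAMES[:3]
        x0 = dict(DEFAULT_INIT)
        if self.x0:
            x0.update(self.x0)
        bounds = {k: tuple(v) for k, v in DEFAULT_BOUNDS.items()}
        if self.bounds:
            bounds.update({k: tuple(v) for k, v in self.bounds.items()})
        if self.model == "ltkm" and bounds["lambda_tr"][0] == bounds["lambda_tr"][1]:
            # degenerate bound freezes the leakage term; lambda_tr is dropped
            # from the optimisation and reported at its fixed value
            if bounds["lambda_tr"][0] != 0.0:
                raise ValueError("lambda_tr can only be frozen at 0")
            names = PARAM_NAMES[:3]
        return t, cp, names, x0, bounds

    def _forward(self, x, names, cp, t):
        p = dict(zip(names, x))
        if self.model == "ltkm":
            return ltkm_forward(
                p["vp"], p["ve"], p["ktrans"], p.get("lambda_tr", 0.0), cp, t
            )
        return etm_forward(p["vp"], p["ve"], p["ktrans"], cp, t)

    def _fit_one(self, y, t, cp, names, x0_vec, lo, hi, rng):
        def resid(x):
            return self._forward(x, names, cp, t) - y

        starts = [x0_vec]
        for _ in range(self.multistart):
            jitter = rng.uniform(0.5, 1.5, size=x0_vec.size)
            starts.append(np.clip(x0_vec * jitter, lo + 1e-12, hi))
        best = None
        for s in starts:
            try:
                res = least_squares(
                    resid, s, bounds=(lo, hi), method="trf",
                    xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        return best

    def fit(self, X: np.ndarray, y=None) -> "TracerKineticModel":
        """Fit every row of ``X`` (shape ``(n_voxels, n_frames)``)."""
        t, cp, names, x0, bounds = self._setup()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != t.size:
            raise ValueError("curve length does not match the time grid")
        lo = np.array([bounds[k][0] for k in names])
        hi = np.array([bounds[k][1] for k in names])
        x0_vec = np.clip(np.array([x0[k] for k in names]), lo, hi)
        rng = np.random.default_rng(self.random_state)

        n = X.shape[0]
        params = np.full((n, 4), np.nan)
        r2 = np.full(n, np.nan)
        flagged = np.zeros(n, dtype=bool)
        for i in range(n):
            yv = X[i]
            if not np.all(np.isfinite(yv)) or np.ptp(yv) == 0:
                flagged[i] = True
                continue
            res = self._fit_one(yv, t, cp, names, x0_vec, lo, hi, rng)
            if res is None:
                flagged[i] = True
                continue
            full = dict.fromkeys(PARAM_NAMES, 0.0)
            full.update(dict(zip(names, res.x)))
            params[i] = [full[k] for k in PARAM_NAMES]
            r2[i] = r_squared(yv, self._forward(res.x, names, cp, t))
        self.params_ = params
        self.r_squared_ = r2
        self.flagged_ = flagged
        self.n_features_in_ = t.size
        return self

    def predict(self, X=None) -> np.ndarray:
        """Model curves for the fitted voxels."""
        if not hasattr(self, "params_"):
            raise RuntimeError("call fit() first")
        t, cp, names, _, _ = self._setup()
        out = np.full((self.params_.shape[0], t.size), np.nan)
        for i, row in enumerate(self.params_):
            if self.flagged_[i]:
                continue
            x = [row[PARAM_NAMES.index(k)] for k in names]
            out[i] = self._forward(x, names, cp, t)
        return out


def fit_voxel(
    curve: np.ndarray,
    vif: VIFCurve,
    model: str = "etm",
    x0: dict | None = None,
    bounds: dict | None = None,
) -> PKParams:
    """Fit one voxel's concentration curve; degenerate input flags, never raises."""
    est = TracerKineticModel(
        t_s=vif.t_s, cp=vif.values, model=model, x0=x0, bounds=bounds
    ).fit(np.asarray(curve, dtype=float)[None, :])
    vp, ve, kt, lam = est.params_[0]
    return PKParams(
        vp=vp, ve=ve, ktrans=kt, lambda_tr=lam,
        r2=float(est.r_squared_[0]), flagged=bool(est.flagged_[0]),
    )


@dataclass
class ParamMap:
    """Voxelwise kinetic-parameter maps for one (model, VIF method) fit."""

    shape: tuple
    model: str
    vif_method: str
    maps: dict  # name -> 3D array (vp, ve, ktrans, lambda_tr, r2)
    roi_mask: np.ndarray
    fitted_mask: np.ndarray = None
    summary: dict | None = None
    status: str = "ok"
    threshold: float = R2_GOOD_FIT
    _good: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.fitted_mask is None:
            self.fitted_mask = np.zeros(self.shape, dtype=bool)

    @property
    def good_fit(self) -> np.ndarray:
        if self._good is None:
            self._good = good_fit_mask(self.maps["r2"], self.threshold) & np.asarray(
                self.roi_mask, dtype=bool
            )
        return self._good

    @property
    def tumor_volume_voxels(self) -> int:
        """Count of ROI voxels with a confident fit (strict R^2 > 0.5)."""
        return int(self.good_fit.sum())

    def summarize(self) -> dict | None:
        good = self.good_fit
        if not good.any():
            self.summary = None
            self.status = "undefined: no voxel exceeded the goodness-of-fit threshold"
            return None
        self.summary = {k: float(self.maps[k][good].mean()) for k in PARAM_NAMES}
        self.summary["r2"] = float(self.maps["r2"][good].mean())
        self.summary["tumor_volume_voxels"] = self.tumor_volume_voxels
        self.status = "ok"
        return self.summary


def fit_roi(
    conc: ConcentrationSeries,
    roi_mask: np.ndarray,
    vif: VIFCurve,
    model: str = "etm",
    x0: dict | None = None,
    bounds: dict | None = None,
) -> ParamMap:
    """Voxelwise fit over an ROI with goodness-of-fit filtering.

    Voxels flagged during concentration conversion, or with flat/degenerate
    curves, are skipped (flagged) rather than fitted. The ROI summary is the
    untrimmed mean over voxels with R^2 strictly above 0.5, and the good-fit
    voxel count doubles as the tumor-volume estimate.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != conc.shape:
        raise ValueError("ROI mask geometry does not match the series")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    fit_sel = mask & ~conc.flagged
    voxels = np.argwhere(fit_sel)
    shape = conc.shape
    maps = {k: np.full(shape, np.nan) for k in (*PARAM_NAMES, "r2")}
    fitted = np.zeros(shape, dtype=bool)

    if len(voxels):
        curves = conc.data[fit_sel]
        est = TracerKineticModel(
            t_s=conc.t_s, cp=vif.values, model=model, x0=x0, bounds=bounds
        ).fit(curves)
        ok = ~est.flagged_
        for j, v in enumerate(voxels):
            v = tuple(v)
            if not ok[j]:
                continue
            fitted[v] = True
            for ki, k in enumerate(PARAM_NAMES):
                maps[k][v] = est.params_[j, ki]
            maps["r2"][v] = est.r_squared_[j]

    pm = ParamMap(
        shape=shape,
        model=model,
        vif_method=vif.method,
        maps=maps,
        roi_mask=mask,
        fitted_mask=fitted,
    )
    pm.summarize()
    return pm
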