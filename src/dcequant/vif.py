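"""Vascular input function (VIF) extraction.

Two routes to a per-scan VIF:

* **automatic** — keep voxels whose signal enhances rapidly (time from bolus
  arrival to peak under 10 s) and whose temporal-maximum intensity reaches
  the 90th percentile of per-voxel maxima over the whole image, then average
  the survivors into a composite profile;
* **manual** — average the signal over a drawn venous-sinus ROI.

For comparability the pair is normalized with one shared factor so the
larger curve peaks at exactly 2 (relative, not absolute, concentration).
"""

from __future__ import annotations

import numpy as np

from .core import DynamicSeries, VIFCurve
from .relaxometry import T1Map

__all__ = [
    "detect_bolus_arrival",
    "auto_vif",
    "manual_vif",
    "normalize_vif_pair",
    "NoVIFError",
]

TTP_MAX_S = 10.0  # strict upper bound on time-to-peak for "rapid" voxels
MAX_INTENSITY_PERCENTILE = 90.0


class NoVIFError(RuntimeError):
    """Raised when the automatic selection keeps no voxel."""


def detect_bolus_arrival(
    curve: np.ndarray,
    baseline_window: int,
    k: float = 3.0,
    persistence: int = 2,
) -> int | None:
    """First frame where a curve rises persistently above its baseline.

    Arrival is the first frame whose value exceeds
    ``baseline mean + k * baseline SD`` for at least ``persistence``
    consecutive frames. Returns ``None`` for curves that never rise
    (e.g. flat, non-enhancing voxels).
    """
    y = np.asarray(curve, dtype=float)
    if baseline_window < 3:
        raise ValueError("baseline_window must cover at least 3 frames")
    if y.size <= baseline_window:
        raise ValueError("curve shorter than the baseline window")
    base = y[:baseline_window]
    mean, sd = float(base.mean()), float(base.std(ddof=0))
    scale = float(np.max(np.abs(y))) or 1.0
    thresh = mean + k * sd + 1e-12 * scale  # epsilon guards exact-equality noise
    above = y > thresh
    run = 0
    for i in range(y.size):
        run = run + 1 if above[i] else 0
        if run >= persistence:
            return i - persistence + 1
    return None


def _composite(series: DynamicSeries, voxels: list, t1map: T1Map | None) -> VIFCurve:
    curves = np.stack([series.data[v] for v in voxels])
    mean_t10 = None
    if t1map is not None:
        t10s = np.array([t1map.t10_ms[v] for v in voxels], dtype=float)
        t10s = t10s[np.isfinite(t10s)]
        if t10s.size:
            mean_t10 = float(t10s.mean())
    return VIFCurve(
        t_s=series.times_s,
        values=curves.mean(axis=0),
        method="auto",
        voxel_indices=voxels,
        mean_t10_ms=mean_t10,
    )


def auto_vif(
    series: DynamicSeries,
    t1map: T1Map | None = None,
    ttp_max_s: float = TTP_MAX_S,
    percentile: float = MAX_INTENSITY_PERCENTILE,
    baseline_window: int | None = None,
    k: float = 3.0,
) -> VIFCurve:
    """Automatic VIF voxel selection and composite-profile averaging.

    A voxel survives when (peak time - bolus arrival) < ``ttp_max_s`` AND its
    maximum signal is >= the ``percentile``-th percentile of per-voxel
    temporal maxima over the whole image (ties at the threshold are kept).
    """
    if baseline_window is None:
        baseline_window = max(series.spec.baseline_frames, 3)
    data = series.data
    t = series.times_s
    maxima = data.max(axis=-1)
    threshold = float(np.percentile(maxima, percentile))
    candidates = np.argwhere(maxima >= threshold)

    kept: list = []
    for idx in map(tuple, candidates):
        y = data[idx]
        arrival = detect_bolus_arrival(y, baseline_window, k=k)
        if arrival is None:
            continue
        ttp = t[int(np.argmax(y))] - t[arrival]
        if ttp < ttp_max_s:
            kept.append(idx)
    if not kept:
        raise NoVIFError(
            "automatic VIF selection found no voxel with rapid enhancement "
            "above the intensity percentile"
        )
    kept.sort()
    return _composite(series, kept, t1map)


def manual_vif(
    series: DynamicSeries,
    sinus_mask: np.ndarray,
    t1map: T1Map | None = None,
) -> VIFCurve:
    """Average the signal over a manually drawn venous-sinus ROI."""
    mask = np.asarray(sinus_mask, dtype=bool)
    if mask.shape != series.shape:
        raise ValueError("sinus mask geometry does not match the series")
    voxels = [tuple(v) for v in np.argwhere(mask)]
    if not voxels:
        raise ValueError("sinus mask is empty")
    out = _composite(series, voxels, t1map)
    out.method = "manual"
    return out


def normalize_vif_pair(
    auto: VIFCurve,
    manual: VIFCurve,
    target_max: float = 2.0,
    shared_scale: bool = True,
) -> tuple:
    """Scale a (auto, manual) VIF pair so the peak equals ``target_max``.

    With ``shared_scale`` (default) one factor
    ``s = target_max / max(max(auto), max(manual))`` is applied to both
    curves, so between-method parameter differences stay meaningful; with
    ``shared_scale=False`` each curve is normalized to the target
    independently.
    """
    if auto.t_s.shape != manual.t_s.shape or not np.allclose(auto.t_s, manual.t_s):
        raise ValueError("curves must share one time grid")
    ma, mm = float(np.max(auto.values)), float(np.max(manual.values))
    if ma <= 0 or mm <= 0:
        raise ValueError("VIF maxima must be positive for normalization")
    if shared_scale:
        s = target_max / max(ma, mm)
        return auto.scaled(s), manual.scaled(s)
    return auto.scaled(target_max / ma), manual.scaled(target_max / mm)
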