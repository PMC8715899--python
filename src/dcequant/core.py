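"""Shared containers for DCE-MRI acquisitions.

Conventions used throughout the package:

* time grids are in **seconds**, frame ``k`` acquired at ``t = k * dt``;
* relaxation times (T1, T10) and sequence timings (TR, TE) are in **ms**;
* kinetic rate constants (Ktrans, kep, lambda_tr) are in **min^-1** at every
  public interface and converted internally where needed;
* contrast-agent relaxivity r1 is in s^-1 mM^-1, concentrations in mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["AcquisitionSpec", "DynamicSeries", "VIFCurve"]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Geometry and timing of a dynamic contrast-enhanced acquisition.

    Defaults describe a 3 T dual-gradient-echo FLASH protocol:
    128 x 128 matrix, 20 slices, 60 dynamic frames at 6 s resolution with a
    contrast bolus injected 52 s after the start of the dynamic scan, and a
    four-angle (2/5/10/15 degree) variable-flip-angle series for pre-contrast
    T1 mapping.
    """

    nx: int = 128
    ny: int = 128
    nslices: int = 20
    n_frames: int = 60
    dt_s: float = 6.0
    tr_ms: float = 6.8
    te1_ms: float = 2.61
    te2_ms: float = 3.89
    flip_deg: float = 10.0
    vfa_angles_deg: tuple = (2.0, 5.0, 10.0, 15.0)
    vfa_tr_ms: float = 7.3
    bolus_arrival_s: float = 52.0

    def __post_init__(self):
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 dynamic frames")
        angles = (self.flip_deg, *self.vfa_angles_deg)
        if any(not 0 < a < 90 for a in angles):
            raise ValueError("flip angles must lie strictly between 0 and 90 degrees")
        if not self.bolus_arrival_s < self.n_frames * self.dt_s:
            raise ValueError("bolus_arrival_s must fall inside the scan window")
        if min(self.nx, self.ny, self.nslices) < 1:
            raise ValueError("matrix dimensions must be positive")
        if self.tr_ms <= 0 or self.vfa_tr_ms <= 0:
            raise ValueError("TR must be positive")
        if not 0 < self.te1_ms < self.te2_ms:
            raise ValueError("need 0 < TE1 < TE2")

    @property
    def shape(self) -> tuple:
        return (self.nx, self.ny, self.nslices)

    @property
    def times_s(self) -> np.ndarray:
        """Frame acquisition times, seconds."""
        return np.arange(self.n_frames) * self.dt_s

    @property
    def baseline_frames(self) -> int:
        """Number of leading frames used for the pre-contrast signal S(0).

        All frames acquired strictly before bolus arrival, minus one frame of
        guard band (7 frames with the default 52 s arrival and 6 s spacing).
        """
        n = int(np.floor(self.bolus_arrival_s / self.dt_s)) - 1
        return max(n, 1)

    def with_matrix(self, nx: int, ny: int, nslices: int) -> "AcquisitionSpec":
        return replace(self, nx=nx, ny=ny, nslices=nslices)


@dataclass
class DynamicSeries:
    """A 4D dynamic acquisition: ``data[x, y, z, t]`` signal intensities.

    ``data2`` optionally holds the second-echo signal of a dual-echo
    sequence (same grid, acquired at ``spec.te2_ms``).
    """

    data: np.ndarray
    spec: AcquisitionSpec
    data2: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DynamicSeries.data must be 4D (x, y, z, t)")
        if self.data.shape[-1] != self.spec.n_frames:
            raise ValueError("frame count does not match AcquisitionSpec")
        if self.data2 is not None:
            self.data2 = np.asarray(self.data2, dtype=float)
            if self.data2.shape != self.data.shape:
                raise ValueError("second echo must match first echo in shape")

    @property
    def times_s(self) -> np.ndarray:
        return self.spec.times_s

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]


@dataclass
class VIFCurve:
    """A vascular input function sampled on the dynamic time grid.

    ``values`` is either a signal-intensity profile (before conversion) or a
    plasma concentration profile Cp(t); ``method`` records provenance
    ("auto", "manual" or "synthetic").
    """

    t_s: np.ndarray
    values: np.ndarray
    method: str = "synthetic"
    voxel_indices: Sequence[tuple] = field(default_factory=list)
    mean_t10_ms: float | None = None
    normalization: float | None = None

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t_s.shape != self.values.shape:
            raise ValueError("time grid and values must have equal length")
        if self.t_s.ndim != 1:
            raise ValueError("VIF must be one-dimensional")

    def scaled(self, factor: float) -> "VIFCurve":
        return VIFCurve(
            t_s=self.t_s.copy(),
            values=self.values * factor,
            method=self.method,
            voxel_indices=list(self.voxel_indices),
            mean_t10_ms=self.mean_t10_ms,
            normalization=factor,
        )

    @property
    def peak_time_s(self) -> float:
        return float(self.t_s[int(np.argmax(self.values))])
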