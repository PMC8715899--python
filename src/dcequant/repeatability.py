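"""Double-baseline repeatability statistics.

For each subject j with parameter summaries x_j1, x_j2 at baselines 1 and 2:

* relative change        d_j = ln(x_j2 / x_j1)
* Bland-Altman           bias = mean(d),  LoA = bias +/- 1.96 * SD(d)
* within-subject CV      wCV = sqrt( (1/n) sum_j [ ((x_j1 - x_j2)^2 / 2) / xbar_j^2 ] )
* repeatability coeff    %RC = 1.96 * sqrt(2) * wCV * 100
* coefficient of var.    %CoV = 100 * (1/n) sum_j s_j / xbar_j,
                         s_j = |x_j1 - x_j2| / sqrt(2)

%RC is the smallest relative change distinguishable from measurement error
at 95% confidence. The sample SD (n-1 divisor) is used throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PairedCohort",
    "relative_change",
    "bland_altman",
    "wcv",
    "percent_rc",
    "cov_mean_diff",
    "build_report",
]

logger = logging.getLogger(__name__)

Z_95 = 1.96


@dataclass
class PairedCohort:
    """Per-subject baseline-1/baseline-2 summaries of one parameter."""

    b1: np.ndarray
    b2: np.ndarray
    parameter: str = ""
    model: str = ""
    vif_method: str = ""
    subjects: list = field(default_factory=list)

    def __post_init__(self):
        self.b1 = np.asarray(self.b1, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        if self.b1.shape != self.b2.shape or self.b1.ndim != 1:
            raise ValueError("b1 and b2 must be equal-length 1D arrays")
        if not self.subjects:
            self.subjects = list(range(len(self.b1)))
        bad = ~((self.b1 > 0) & (self.b2 > 0) & np.isfinite(self.b1) & np.isfinite(self.b2))
        if bad.any():
            dropped = [self.subjects[i] for i in np.flatnonzero(bad)]
            logger.warning(
                "dropping %d subject(s) with non-positive %s summaries: %s",
                bad.sum(), self.parameter or "parameter", dropped,
            )
            keep = ~bad
            self.b1, self.b2 = self.b1[keep], self.b2[keep]
            self.subjects = [s for s, k in zip(self.subjects, keep) if k]

    @property
    def n(self) -> int:
        return len(self.b1)

    @property
    def d(self) -> np.ndarray:
        """Per-subject log-ratios ln(B2/B1)."""
        return np.log(self.b2 / self.b1)


def relative_change(p_b1: float, p_b2: float, subject=None) -> float:
    """d = ln(P_B2 / P_B1); antisymmetric under baseline swap."""
    if p_b1 <= 0 or p_b2 <= 0:
        raise ValueError(
            f"relative change undefined for non-positive values"
            f"{f' (subject {subject})' if subject is not None else ''}:"
            f" ({p_b1}, {p_b2})"
        )
    return float(np.log(p_b2 / p_b1))


def bland_altman(d: np.ndarray) -> tuple:
    """Bias and 95% limits of agreement of a difference distribution.

    Returns ``(bias, (lower, upper))`` with bias = mean(d) and limits
    bias +/- 1.96 * sample SD (n-1 divisor).
    """
    d = np.asarray(d, dtype=float)
    if d.size < 2:
        raise ValueError("Bland-Altman needs at least 2 observations")
    bias = float(d.mean())
    half = Z_95 * float(d.std(ddof=1))
    return bias, (bias - half, bias + half)


def wcv(cohort: PairedCohort) -> float:
    """Within-subject coefficient of variation over test-retest pairs."""
    if cohort.n < 1:
        raise ValueError("empty cohort")
    xbar = 0.5 * (cohort.b1 + cohort.b2)
    if np.any(xbar == 0):
        raise ValueError("zero pair mean; wCV undefined")
    terms = ((cohort.b1 - cohort.b2) ** 2 / 2.0) / xbar**2
    return float(np.sqrt(terms.mean()))


def percent_rc(wcv_value: float) -> float:
    """%RC = 1.96 * sqrt(2) * wCV * 100."""
    if wcv_value < 0:
        raise ValueError("wCV must be non-negative")
    return Z_95 * np.sqrt(2.0) * wcv_value * 100.0


def cov_mean_diff(cohort: PairedCohort) -> float:
    """%CoV of the mean difference: mean over subjects of s_j / xbar_j (x100).

    s_j is the sample SD of the two measurements, |x_j1 - x_j2| / sqrt(2).
    """
    if cohort.n < 1:
        raise ValueError("empty cohort")
    xbar = 0.5 * (cohort.b1 + cohort.b2)
    if np.any(xbar == 0):
        raise ValueError("zero pair mean; CoV undefined")
    s = np.abs(cohort.b1 - cohort.b2) / np.sqrt(2.0)
    return float(100.0 * (s / xbar).mean())


def build_report(
    cohorts: list,
    qc_outliers: dict | None = None,
) -> pd.DataFrame:
    """Assemble the per-(parameter, model, VIF-method) repeatability table.

    One row per cohort with bias, limits of agreement (log units), %RC,
    %CoV and n. ``qc_outliers`` maps subject id -> T10 shift for subjects
    whose between-baseline T10 histogram shift exceeded 20%; they are
    annotated, not excluded.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    qc_outliers = qc_outliers or {}
    rows = []
    for c in cohorts:
        bias, (lb, ub) = bland_altman(c.d)
        flagged = sorted(str(s) for s in c.subjects if s in qc_outliers)
        rows.append(
            {
                "parameter": c.parameter,
                "model": c.model,
                "vif_method": c.vif_method,
                "n": c.n,
                "bias": bias,
                "loa_lower": lb,
                "loa_upper": ub,
                "pct_rc": percent_rc(wcv(c)),
                "pct_cov": cov_mean_diff(c),
                "qc_outlier_subjects": ";".join(flagged),
            }
        )
    return pd.DataFrame(rows)


def bland_altman_plot_data(cohort: PairedCohort) -> pd.DataFrame:
    """Mean-vs-difference columns for a Bland-Altman plot of log values."""
    return pd.DataFrame(
        {
            "subject": cohort.subjects,
            "mean_log": 0.5 * (np.log(cohort.b1) + np.log(cohort.b2)),
            "difference_log": cohort.d,
        }
    )
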