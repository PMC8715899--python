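"""Study orchestration: per-subject processing and cohort repeatability.

Per subject and baseline: VFA T1 mapping -> dual-echo-corrected VIF
extraction (automatic and/or manual) -> signal-to-concentration conversion
-> voxelwise kinetic fits over the tumor ROI, emitting one summary record
per (model, VIF method). Per cohort: T10-shift QC, exclusion accounting for
incomplete pairs, and the repeatability table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concentration import (
    DEFAULT_R1,
    dual_echo_correct,
    signal_to_concentration,
    vif_signal_to_concentration,
)
from .core import VIFCurve
from .io import load_study, save_t1map, save_vif_csv, save_volume
from .pkfit import PARAM_NAMES, fit_roi
from .relaxometry import fit_t10_vfa, histogram_peak, t10_shift
from .repeatability import PairedCohort, build_report
from .vif import auto_vif, manual_vif, normalize_vif_pair

__all__ = [
    "StudyConfig",
    "StudyValidationError",
    "run_subject",
    "run_cohort",
]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "subject", "baseline", "model", "vif_method",
    *PARAM_NAMES, "r2", "tumor_volume_voxels", "status", "t10_peak_ms",
]


class StudyValidationError(ValueError):
    """Configuration or input files failed validation."""


@dataclasses.dataclass
class StudyConfig:
    """Plain-text study description.

    ``subjects`` maps subject id -> {baseline label ("1"/"2") -> study
    directory in the sidecar layout written by :func:`dcequant.io.save_study`}.
    """

    subjects: dict
    output_dir: str
    r1: float = DEFAULT_R1
    models: tuple = ("etm", "ltkm")
    vif_methods: tuple = ("auto", "manual")
    seed: int = 0
    save_maps: bool = True
    normalize_vif: bool = True  # peak-2 convention; off for absolute-scale runs

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            subjects={str(k): {str(b): str(p) for b, p in v.items()}
                      for k, v in raw["subjects"].items()},
            output_dir=str(raw["output_dir"]),
            r1=float(raw.get("r1", DEFAULT_R1)),
            models=tuple(raw.get("models", ("etm", "ltkm"))),
            vif_methods=tuple(raw.get("vif_methods", ("auto", "manual"))),
            seed=int(raw.get("seed", 0)),
            save_maps=bool(raw.get("save_maps", True)),
            normalize_vif=bool(raw.get("normalize_vif", True)),
        )

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    def validate(self):
        for model in self.models:
            if model not in ("etm", "ltkm"):
                raise StudyValidationError(f"unknown model {model!r}")
        for vm in self.vif_methods:
            if vm not in ("auto", "manual"):
                raise StudyValidationError(f"unknown VIF method {vm!r}")
        for subject, baselines in self.subjects.items():
            for label, directory in baselines.items():
                if label not in ("1", "2"):
                    raise StudyValidationError(
                        f"subject {subject}: baseline label must be '1' or '2'"
                    )
                d = Path(directory)
                if not (d / "study.json").exists():
                    raise StudyValidationError(
                        f"subject {subject} baseline {label}: missing study at {d}"
                    )
                paths = json.loads((d / "study.json").read_text())["paths"]
                for key, p in paths.items():
                    if not (d / p).exists():
                        raise StudyValidationError(
                            f"subject {subject} baseline {label}: missing file {p} ({key})"
                        )

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _extract_vifs(study, t1map, methods) -> dict:
    """Signal-domain VIFs per method, dual-echo corrected when available."""
    series = study.series
    out = {}
    if "auto" in methods:
        curve = auto_vif(series, t1map=t1map)
        out["auto"] = _correct_curve(curve, series)
    if "manual" in methods:
        sinus = study.truth.vessel_mask
        curve = manual_vif(series, sinus, t1map=t1map)
        out["manual"] = _correct_curve(curve, series)
    return out


def _correct_curve(curve: VIFCurve, series) -> VIFCurve:
    if series.data2 is None:
        return curve
    e2 = np.stack([series.data2[v] for v in curve.voxel_indices]).mean(axis=0)
    corrected = dual_echo_correct(
        curve.values, e2, series.spec.te1_ms, series.spec.te2_ms
    )
    return VIFCurve(
        t_s=curve.t_s, values=corrected, method=curve.method,
        voxel_indices=list(curve.voxel_indices), mean_t10_ms=curve.mean_t10_ms,
    )


def run_subject(config: StudyConfig, subject: str, baseline: str) -> list:
    """Process one (subject, baseline): maps, VIFs, fits, summary records."""
    t_start = time.time()
    directory = Path(config.subjects[subject][baseline])
    study = load_study(directory)
    spec = study.spec
    out_dir = Path(config.output_dir) / subject / f"baseline_{baseline}"
    out_dir.mkdir(parents=True, exist_ok=True)

    vfa_stack = np.stack([study.vfa[a] for a in spec.vfa_angles_deg], axis=-1)
    t1map = fit_t10_vfa(vfa_stack, spec.vfa_angles_deg, spec.vfa_tr_ms)
    t10_peak = histogram_peak(t1map.t10_ms, intensity_floor=1.0)
    if config.save_maps:
        save_t1map(out_dir, t1map)

    conc = signal_to_concentration(study.series, t1map, r1=config.r1)
    logger.info(
        "%s b%s: %d voxels, %d flagged in conversion",
        subject, baseline, int(np.prod(conc.shape)), int(conc.flagged.sum()),
    )

    signal_vifs = _extract_vifs(study, t1map, config.vif_methods)
    conc_vifs = {
        m: vif_signal_to_concentration(v, spec, r1=config.r1)
        for m, v in signal_vifs.items()
    }
    if config.normalize_vif:
        if set(conc_vifs) == {"auto", "manual"}:
            conc_vifs["auto"], conc_vifs["manual"] = normalize_vif_pair(
                conc_vifs["auto"], conc_vifs["manual"]
            )
        else:  # single-method runs still use the peak-2 convention
            for m, v in conc_vifs.items():
                conc_vifs[m] = v.scaled(2.0 / float(np.max(v.values)))
    for m, v in conc_vifs.items():
        save_vif_csv(out_dir / f"vif_{m}.csv", v)

    records = []
    roi = study.truth.tumor_mask
    for vm, cp in conc_vifs.items():
        for model in config.models:
            pm = fit_roi(conc, roi, cp, model=model)
            if config.save_maps:
                for name, arr in pm.maps.items():
                    save_volume(out_dir / f"{model}_{vm}_{name}.nii", arr)
                save_volume(out_dir / f"{model}_{vm}_goodfit.nii", pm.good_fit)
            rec = {
                "subject": subject,
                "baseline": baseline,
                "model": model,
                "vif_method": vm,
                "tumor_volume_voxels": pm.tumor_volume_voxels,
                "status": pm.status,
                "t10_peak_ms": t10_peak,
            }
            summary = pm.summary or {}
            for k in (*PARAM_NAMES, "r2"):
                rec[k] = summary.get(k, np.nan)
            records.append(rec)
            logger.info(
                "%s b%s %s/%s: %d/%d good-fit voxels",
                subject, baseline, model, vm,
                pm.tumor_volume_voxels, int(roi.sum()),
            )
    logger.info("%s b%s done in %.1f s", subject, baseline, time.time() - t_start)
    return records


def _provenance(config: StudyConfig) -> dict:
    return {
        "config_digest": config.digest(),
        "seed": config.seed,
        "software": {"name": "dcequant", "version": __version__},
    }


def run_cohort(config: StudyConfig) -> dict:
    """Run every complete double-baseline pair and build the repeatability table.

    Writes ``summaries.csv`` (long format), ``repeatability_report.csv``,
    ``qc_t10_shift.csv``, ``exclusions.csv`` and a provenance JSON under the
    configured output directory; returns the paths.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    complete, exclusions = [], []
    for subject, baselines in sorted(config.subjects.items()):
        missing = [b for b in ("1", "2") if b not in baselines]
        if missing:
            exclusions.append(
                {"subject": subject,
                 "reason": f"missing baseline {' and '.join(missing)}"}
            )
        else:
            complete.append(subject)
    if len(complete) < 2:
        raise StudyValidationError("need at least 2 complete double-baseline pairs")

    records = []
    for subject in complete:
        for baseline in ("1", "2"):
            try:
                records.extend(run_subject(config, subject, baseline))
            except Exception as exc:
                exclusions.append(
                    {"subject": subject, "reason": f"baseline {baseline} failed: {exc}"}
                )
                records = [r for r in records if r["subject"] != subject]
                logger.error("subject %s failed: %s", subject, exc)
                break

    summaries = pd.DataFrame(records, columns=SUMMARY_COLUMNS)
    summaries_path = out_dir / "summaries.csv"
    summaries.to_csv(summaries_path, index=False)

    # T10-shift QC per subject
    qc_rows, qc_outliers = [], {}
    for subject in sorted(summaries["subject"].unique()):
        sub = summaries[summaries["subject"] == subject]
        p1 = float(sub[sub["baseline"] == "1"]["t10_peak_ms"].iloc[0])
        p2 = float(sub[sub["baseline"] == "2"]["t10_peak_ms"].iloc[0])
        shift, outlier = t10_shift(p1, p2)
        qc_rows.append(
            {"subject": subject, "t10_peak_b1_ms": p1, "t10_peak_b2_ms": p2,
             "t10_shift": shift, "outlier": outlier}
        )
        if outlier:
            qc_outliers[subject] = shift
    qc = pd.DataFrame(qc_rows)
    qc_path = out_dir / "qc_t10_shift.csv"
    qc.to_csv(qc_path, index=False)

    cohorts = []
    for model in config.models:
        params = PARAM_NAMES if model == "ltkm" else PARAM_NAMES[:3]
        for vm in config.vif_methods:
            for param in (*params, "tumor_volume_voxels"):
                sel = summaries[
                    (summaries["model"] == model) & (summaries["vif_method"] == vm)
                ]
                piv = sel.pivot_table(
                    index="subject", columns="baseline", values=param, aggfunc="first"
                )
                piv = piv.dropna()
                if len(piv) < 2 or "1" not in piv or "2" not in piv:
                    continue
                cohorts.append(
                    PairedCohort(
                        b1=piv["1"].to_numpy(), b2=piv["2"].to_numpy(),
                        parameter=param, model=model, vif_method=vm,
                        subjects=list(piv.index),
                    )
                )
    report = build_report(cohorts, qc_outliers=qc_outliers)
    report_path = out_dir / "repeatability_report.csv"
    report.to_csv(report_path, index=False)

    excl = pd.DataFrame(exclusions, columns=["subject", "reason"])
    excl_path = out_dir / "exclusions.csv"
    excl.to_csv(excl_path, index=False)

    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(_provenance(config), indent=2, sort_keys=True))

    return {
        "summaries": str(summaries_path),
        "report": str(report_path),
        "qc": str(qc_path),
        "exclusions": str(excl_path),
        "provenance": str(prov_path),
    }
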