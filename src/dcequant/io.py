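"""NIfTI and sidecar I/O for synthetic studies and pipeline inputs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import AcquisitionSpec, DynamicSeries, VIFCurve
from .relaxometry import T1Map
from .synthetic import GroundTruth, SyntheticStudy

__all__ = [
    "save_volume",
    "load_volume",
    "save_study",
    "load_study",
    "save_t1map",
    "save_vif_csv",
]

_IDENTITY = np.eye(4)


def save_volume(path, data: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), _IDENTITY), str(path))
    return path


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def _spec_to_dict(spec: AcquisitionSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["vfa_angles_deg"] = list(d["vfa_angles_deg"])
    return d


def spec_from_dict(d: dict) -> AcquisitionSpec:
    d = dict(d)
    d["vfa_angles_deg"] = tuple(d["vfa_angles_deg"])
    return AcquisitionSpec(**d)


def save_study(directory, study: SyntheticStudy) -> dict:
    """Write one study as NIfTI volumes plus a JSON sidecar.

    Layout: ``dce_e1.nii`` / ``dce_e2.nii`` (4D), ``vfa_<angle>.nii`` (3D),
    ``mask_tumor.nii`` / ``mask_vessel.nii``, per-parameter ground-truth
    maps, and ``study.json`` holding the acquisition spec, seeds and the
    true plasma curve. Returns the path map.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # sidecar paths are relative to the study directory, so a study can be
    # moved or copied as a unit
    save_volume(directory / "dce_e1.nii", study.series.data)
    paths = {"dce": "dce_e1.nii"}
    if study.series.data2 is not None:
        save_volume(directory / "dce_e2.nii", study.series.data2)
        paths["dce_e2"] = "dce_e2.nii"
    for angle, vol in study.vfa.items():
        key = f"vfa_{angle:g}"
        save_volume(directory / f"{key}.nii", vol)
        paths[key] = f"{key}.nii"
    truth = study.truth
    save_volume(directory / "mask_tumor.nii", truth.tumor_mask)
    paths["mask_tumor"] = "mask_tumor.nii"
    save_volume(directory / "mask_vessel.nii", truth.vessel_mask)
    paths["mask_vessel"] = "mask_vessel.nii"
    for name in ("vp", "ve", "ktrans", "lambda_tr", "t10_ms", "m0"):
        save_volume(directory / f"truth_{name}.nii", getattr(truth, name))
        paths[f"truth_{name}"] = f"truth_{name}.nii"
    sidecar = {
        "spec": _spec_to_dict(study.spec),
        "meta": study.meta,
        "vif_t_s": study.vif.t_s.tolist(),
        "vif_cp": study.vif.values.tolist(),
        "paths": paths,
    }
    (directory / "study.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return paths


def load_study(directory) -> SyntheticStudy:
    directory = Path(directory)
    sidecar = json.loads((directory / "study.json").read_text())
    spec = spec_from_dict(sidecar["spec"])
    data = load_volume(directory / "dce_e1.nii")
    data2_path = directory / "dce_e2.nii"
    data2 = load_volume(data2_path) if data2_path.exists() else None
    series = DynamicSeries(data=data, spec=spec, data2=data2)
    vfa = {
        a: load_volume(directory / f"vfa_{a:g}.nii") for a in spec.vfa_angles_deg
    }
    truth = GroundTruth(
        vp=load_volume(directory / "truth_vp.nii"),
        ve=load_volume(directory / "truth_ve.nii"),
        ktrans=load_volume(directory / "truth_ktrans.nii"),
        lambda_tr=load_volume(directory / "truth_lambda_tr.nii"),
        t10_ms=load_volume(directory / "truth_t10_ms.nii"),
        m0=load_volume(directory / "truth_m0.nii"),
        vessel_mask=load_volume(directory / "mask_vessel.nii") > 0.5,
        tumor_mask=load_volume(directory / "mask_tumor.nii") > 0.5,
    )
    vif = VIFCurve(
        t_s=np.array(sidecar["vif_t_s"]),
        values=np.array(sidecar["vif_cp"]),
        method="synthetic",
    )
    return SyntheticStudy(
        spec=spec, vfa=vfa, series=series, truth=truth, vif=vif, meta=sidecar["meta"]
    )


def save_t1map(directory, t1map: T1Map, prefix: str = "t10") -> dict:
    directory = Path(directory)
    return {
        "t10": str(save_volume(directory / f"{prefix}_ms.nii", t1map.t10_ms)),
        "m0": str(save_volume(directory / f"{prefix}_m0.nii", t1map.m0)),
        "valid": str(save_volume(directory / f"{prefix}_valid.nii", t1map.valid)),
    }


def save_vif_csv(path, vif: VIFCurve) -> Path:
    """Two-column CSV (time s, Cp) plus a JSON record of provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.column_stack([vif.t_s, vif.values])
    np.savetxt(path, arr, delimiter=",", header="time_s,cp", comments="")
    record = {
        "method": vif.method,
        "n_voxels": len(vif.voxel_indices),
        "voxel_indices": [list(map(int, v)) for v in vif.voxel_indices],
        "mean_t10_ms": vif.mean_t10_ms,
        "normalization": vif.normalization,
    }
    path.with_suffix(".json").write_text(json.dumps(record, indent=2))
    return path
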