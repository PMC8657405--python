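"""Readers and writers for on-disk study artifacts.

Velocity fields are stored as one 4-D NIfTI per component (``vx.nii`` /
``vy.nii`` / ``vz.nii``, spatial dims x frames) or, flag-selected, a single
5-D file, with a JSON sidecar carrying VENC, spacing, frame duration and
frame count; masks as NIfTI; valve planes, ground truth and offset models
as JSON. World coordinates are RAS mm with voxel centres at
``(index + 0.5) * spacing``. Cohort tables travel as CSV with the column
dictionary in :data:`COHORT_COLUMNS`.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .anatomy import PhaseMap, ValvePlane
from .field import VelocityField4D
from .phantom import GroundTruth, PhantomBundle
from .preprocess import OffsetModel

__all__ = [
    "write_bundle",
    "read_field_bundle",
    "write_offset_model",
    "read_offset_model",
    "read_cohort_csv",
    "COHORT_COLUMNS",
    "BundleValidationError",
]

SIDECAR_NAME = "sidecar.json"

#: column dictionary for cohort CSV files
COHORT_COLUMNS = {
    "subject_id": "unique subject identifier",
    "group": "study group (e.g. control | PAF)",
    "age_years": "age in years",
    "sex": "F | M",
    "height_m": "height in metres",
    "weight_kg": "weight in kilograms",
    "bsa_m2": "body-surface area (Du Bois), m^2",
    "df_pct": "direct flow, % of mapped end-diastolic volume",
    "ri_pct": "retained inflow, %",
    "de_pct": "delayed ejection, %",
    "rv_pct": "residual volume, %",
    "df_ml": "direct flow volume, ml",
    "ri_ml": "retained inflow volume, ml",
    "de_ml": "delayed ejection volume, ml",
    "rv_ml": "residual volume, ml",
}


class BundleValidationError(ValueError):
    """On-disk bundle is inconsistent; the message names file and field."""


def _affine(spacing_mm: np.ndarray) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = 0.5 * spacing_mm  # voxel centres at (index + 0.5) * spacing
    return aff


def _plane_to_json(plane: ValvePlane) -> dict:
    d = {
        "label": plane.label,
        "origin_mm": np.asarray(plane.origin_mm).tolist(),
        "normal": np.asarray(plane.normal).tolist(),
    }
    if plane.orifice_radius_mm is not None:
        d["orifice"] = {"disc_radius_mm": plane.orifice_radius_mm}
    else:
        d["orifice"] = {"polygon_mm": np.asarray(plane.orifice_polygon_mm).tolist()}
    return d


def _plane_from_json(d: dict) -> ValvePlane:
    orif = d["orifice"]
    return ValvePlane(
        label=d["label"],
        origin_mm=np.asarray(d["origin_mm"]),
        normal=np.asarray(d["normal"]),
        orifice_radius_mm=orif.get("disc_radius_mm"),
        orifice_polygon_mm=(
            np.asarray(orif["polygon_mm"]) if "polygon_mm" in orif else None
        ),
    )


def write_bundle(bundle: PhantomBundle, directory, single_file: bool = False) -> Path:
    """Write a phantom/study bundle to a directory; returns the path."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    field = bundle.field
    aff = _affine(field.spacing_mm)
    # velocity: (frames, nx, ny, nz, 3) -> spatial-major for NIfTI
    vol = np.moveaxis(field.values, 0, 3)  # (nx, ny, nz, frames, 3)
    if single_file:
        nib.save(nib.Nifti1Image(vol, aff), out / "velocity.nii")
    else:
        for c, name in enumerate(("vx", "vy", "vz")):
            nib.save(nib.Nifti1Image(np.ascontiguousarray(vol[..., c]), aff), out / f"{name}.nii")
    nib.save(
        nib.Nifti1Image(np.moveaxis(bundle.lv_mask, 0, 3).astype(np.uint8), aff),
        out / "lv_mask.nii",
    )
    nib.save(
        nib.Nifti1Image(bundle.static_mask.astype(np.uint8), aff), out / "static_mask.nii"
    )
    sidecar = {
        "venc_cm_s": field.venc_cm_s,
        "spacing_mm": field.spacing_mm.tolist(),
        "frame_ms": field.frame_ms,
        "n_frames": field.n_frames,
        "cyclic": field.cyclic,
        "single_file": single_file,
        "meta": _jsonable(bundle.meta),
    }
    (out / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))
    planes = {
        "mitral": _plane_to_json(bundle.mitral),
        "aortic": _plane_to_json(bundle.aortic),
    }
    (out / "valve_planes.json").write_text(json.dumps(planes, indent=2))
    (out / "phases.json").write_text(
        json.dumps(
            {
                "t_ivr": bundle.phases.t_ivr,
                "t_ed": bundle.phases.t_ed,
                "t_es": bundle.phases.t_es,
                "n_frames": bundle.phases.n_frames,
            },
            indent=2,
        )
    )
    (out / "ground_truth.json").write_text(json.dumps(asdict(bundle.truth), indent=2))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def read_field_bundle(directory) -> PhantomBundle:
    """Load and validate a bundle directory written by :func:`write_bundle`."""
    src = Path(directory)
    sidecar_path = src / SIDECAR_NAME
    if not sidecar_path.exists():
        raise BundleValidationError(f"{sidecar_path}: sidecar missing")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("venc_cm_s", "spacing_mm", "frame_ms", "n_frames"):
        if key not in sidecar:
            raise BundleValidationError(f"{sidecar_path}: {key} required")

    if sidecar.get("single_file"):
        vol = np.asarray(nib.load(src / "velocity.nii").dataobj)
    else:
        comps = [np.asarray(nib.load(src / f"{n}.nii").dataobj) for n in ("vx", "vy", "vz")]
        vol = np.stack(comps, axis=-1)
    values = np.moveaxis(vol, 3, 0)  # back to (frames, nx, ny, nz, 3)
    if values.shape[0] != sidecar["n_frames"]:
        raise BundleValidationError(
            f"velocity frames {values.shape[0]} != sidecar n_frames {sidecar['n_frames']}"
        )
    field = VelocityField4D(
        values,
        sidecar["spacing_mm"],
        sidecar["frame_ms"],
        sidecar["venc_cm_s"],
        cyclic=sidecar.get("cyclic", True),
        meta=sidecar.get("meta", {}),
    )
    lv_mask = np.moveaxis(np.asarray(nib.load(src / "lv_mask.nii").dataobj), 3, 0).astype(bool)
    static = np.asarray(nib.load(src / "static_mask.nii").dataobj).astype(bool)
    if lv_mask.shape[0] != field.n_frames:
        raise BundleValidationError(
            f"lv_mask.nii: frame count {lv_mask.shape[0]} != field frames {field.n_frames}"
        )
    if lv_mask.shape[1:] != field.grid_shape:
        raise BundleValidationError("lv_mask.nii: grid shape mismatch")

    planes = json.loads((src / "valve_planes.json").read_text())
    mitral = _plane_from_json(planes["mitral"])
    aortic = _plane_from_json(planes["aortic"])
    ph = json.loads((src / "phases.json").read_text())
    phases = PhaseMap(**ph)

    truth_path = src / "ground_truth.json"
    if truth_path.exists():
        truth = GroundTruth(**json.loads(truth_path.read_text()))
    else:  # acquired data: no analytic truth; placeholder of all-residual
        total = float(lv_mask[phases.t_ed].sum()) * field.voxel_volume_ml()
        truth = GroundTruth(0, 0, 0, 100.0, 0, 0, 0, total, total, "analytic")
    return PhantomBundle(field, lv_mask, static, mitral, aortic, truth, phases,
                         meta=sidecar.get("meta", {}))


def write_offset_model(model: OffsetModel, path) -> None:
    d = {
        "order": model.order,
        "coeffs_cm_s_per_mm_k": model.coeffs.tolist(),
        "fit_rms_cm_s": np.asarray(model.fit_rms).tolist(),
        "grid_shape": list(model.grid_shape),
        "spacing_mm": model.spacing_mm.tolist(),
    }
    Path(path).write_text(json.dumps(d, indent=2))


def read_offset_model(path) -> OffsetModel:
    d = json.loads(Path(path).read_text())
    return OffsetModel(
        order=d["order"],
        coeffs=np.asarray(d["coeffs_cm_s_per_mm_k"]),
        fit_rms=np.asarray(d["fit_rms_cm_s"]),
        grid_shape=tuple(d["grid_shape"]),
        spacing_mm=np.asarray(d["spacing_mm"]),
    )


def read_cohort_csv(path, require_fractions: bool = True) -> pd.DataFrame:
    """Load a cohort table, validating the documented column dictionary."""
    df = pd.read_csv(path)
    required = ["subject_id", "group"]
    if require_fractions:
        required += ["df_pct", "ri_pct", "de_pct", "rv_pct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise BundleValidationError(f"{path}: missing cohort columns {missing}")
    if require_fractions:
        sums = df[["df_pct", "ri_pct", "de_pct", "rv_pct"]].sum(axis=1)
        bad = np.nonzero(np.abs(sums.to_numpy() - 100.0) > 1e-6)[0]
        if bad.size:
            raise BundleValidationError(
                f"{path}: fractions do not sum to 100 for rows {bad.tolist()[:5]}"
            )
    return df
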