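"""Readers and writers: NIfTI image stacks, JSON contour sets and ground
truth, CSV cohort tables, and JSON reports.

All writers round-trip: reading a written file reproduces integer values
exactly and floating-point values to full IEEE precision (JSON) or at
least 1e-9 relative (NIfTI stores float32 optionally; we keep float64).
Contour coordinates are millimetres in the image plane (x rightward,
y downward, origin at the image corner).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import ContourSet, GroundTruth, ImageStack, RegionMasks, SliceContours
from .simulate import COHORT_COLUMNS


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------


def write_image_nifti(stack: ImageStack, path: str | Path) -> None:
    """Write the stack as NIfTI with spacing in the header.

    Data are stored (x=col, y=row, z=slice); in-plane spacing and the
    effective slice spacing go in ``pixdim``, and the thickness/gap split
    is kept in the free-text ``descrip`` field.
    """
    data = np.transpose(stack.voxels, (2, 1, 0)).astype(np.float64)
    affine = np.diag([stack.pixel_spacing, stack.pixel_spacing, stack.slice_spacing, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((stack.pixel_spacing, stack.pixel_spacing, stack.slice_spacing))
    img.header["descrip"] = f"thk={stack.slice_thickness};gap={stack.slice_gap}".encode()
    nib.save(img, str(path))


def read_image_nifti(path: str | Path) -> ImageStack:
    """Read a NIfTI volume into an ImageStack, spacing from the header."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="replace")
    thickness, gap = float(zooms[2]), 0.0
    try:
        fields = dict(item.split("=") for item in descrip.split(";") if "=" in item)
        if "thk" in fields and "gap" in fields:
            thickness, gap = float(fields["thk"]), float(fields["gap"])
    except ValueError:
        pass
    return ImageStack(
        voxels=np.transpose(data, (2, 1, 0)),
        pixel_spacing=float(zooms[0]),
        slice_thickness=thickness,
        slice_gap=gap,
    )


def write_masks_nifti(masks: RegionMasks, stack: ImageStack, path: str | Path) -> None:
    """Export region masks as a labelled volume (0 bg, 1 myo, 2 septal, 3 remote)."""
    labels = np.zeros(stack.shape, dtype=np.uint8)
    labels[masks.myocardium] = 1
    labels[masks.septal] = 2
    labels[masks.remote] = 3
    data = np.transpose(labels, (2, 1, 0))
    affine = np.diag([stack.pixel_spacing, stack.pixel_spacing, stack.slice_spacing, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


# ---------------------------------------------------------------------------
# Contours and ground truth (JSON)
# ---------------------------------------------------------------------------


def _poly_to_list(poly: np.ndarray | None):
    return None if poly is None else np.asarray(poly, dtype=float).tolist()


def write_contours_json(contours: ContourSet, path: str | Path) -> None:
    payload = {
        "coordinate_system": "mm, origin at image corner, x rightward, y downward",
        "slices": {
            str(idx): {
                "endo": _poly_to_list(sc.endo),
                "epi": _poly_to_list(sc.epi),
                "insertion_points": _poly_to_list(sc.insertion_points),
                "remote": _poly_to_list(sc.remote),
                "exclusions": [_poly_to_list(p) for p in sc.exclusions],
            }
            for idx, sc in sorted(contours.items())
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_contours_json(path: str | Path) -> ContourSet:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"{path}: malformed contour JSON at line {err.lineno}: {err.msg}") from err
    if "slices" not in payload:
        raise ValueError(f"{path}: contour JSON missing 'slices' field")
    contours = ContourSet()
    for key, entry in payload["slices"].items():
        for required in ("endo", "epi"):
            if entry.get(required) is None:
                raise ValueError(f"{path}: slice {key} missing '{required}' polygon")
        contours[int(key)] = SliceContours(
            endo=np.asarray(entry["endo"], dtype=float),
            epi=np.asarray(entry["epi"], dtype=float),
            insertion_points=(
                None
                if entry.get("insertion_points") is None
                else np.asarray(entry["insertion_points"], dtype=float)
            ),
            remote=None if entry.get("remote") is None else np.asarray(entry["remote"], dtype=float),
            exclusions=[np.asarray(p, dtype=float) for p in entry.get("exclusions", [])],
        )
    return contours


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    """Ground truth as JSON (lesion mask as nested lists of 0/1)."""
    payload = {
        "true_total_pct": truth.true_total_pct,
        "true_septal_pct": truth.true_septal_pct,
        "true_lv_mass_g": truth.true_lv_mass_g,
        "lesion_mask_shape": list(truth.lesion_mask.shape),
        "lesion_voxels": np.argwhere(truth.lesion_mask).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth_json(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    mask = np.zeros(tuple(payload["lesion_mask_shape"]), dtype=bool)
    vox = np.asarray(payload["lesion_voxels"], dtype=int)
    if vox.size:
        mask[tuple(vox.T)] = True
    return GroundTruth(
        lesion_mask=mask,
        true_total_pct=payload["true_total_pct"],
        true_septal_pct=payload["true_septal_pct"],
        true_lv_mass_g=payload["true_lv_mass_g"],
    )


# ---------------------------------------------------------------------------
# Cohort CSV and reports
# ---------------------------------------------------------------------------


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort CSV missing columns: {missing}")
    if (df["followup_years"] <= 0).any():
        rows = df.index[df["followup_years"] <= 0].tolist()
        raise ValueError(f"{path}: non-positive followup_years in rows {rows}")
    for col in ("cardiac_death", "appropriate_icd", "scd", "noncardiac_death"):
        vals = set(pd.unique(df[col]))
        if not vals <= {0, 1, True, False}:
            raise ValueError(f"{path}: column {col!r} must be binary, found {sorted(vals)}")
    return df


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=1))


def read_report_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
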