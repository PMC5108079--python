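"""Myocardial and septal-region mask construction from short-axis contours.

The septum is defined anatomically as the myocardium between, and inclusive
of, the two RV insertion regions; the border of each insertion region is
extended a fixed distance (default 10 mm) beyond the point of contact.  The
extension is measured as arc length along the mid-wall circumference, so in
angular terms each border moves by ``extension_mm / midwall_radius`` radians.

Voxel membership is decided by centre-point inclusion, matching the binary
thresholding applied downstream; no partial-volume weighting is done.
"""

from __future__ import annotations

import logging

import numpy as np
import shapely
from shapely.geometry import Polygon

from .core import (
    MYOCARDIAL_DENSITY_G_PER_ML,
    ContourSet,
    GeometryError,
    ImageStack,
    RegionMasks,
    SliceContours,
)

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


def _voxel_centers_mm(n_rows: int, n_cols: int, pixel_spacing: float):
    """Flattened (x, y) voxel-centre coordinates in mm for one slice."""
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    x = (cols.ravel() + 0.5) * pixel_spacing
    y = (rows.ravel() + 0.5) * pixel_spacing
    return x, y


def _validated_polygon(points: np.ndarray, name: str) -> Polygon:
    poly = Polygon(points)
    if not poly.is_valid or poly.area <= 0:
        raise GeometryError(f"{name} polygon is degenerate or self-intersecting")
    return poly


def polygon_mask(points: np.ndarray, n_rows: int, n_cols: int, pixel_spacing: float) -> np.ndarray:
    """Rasterize a closed polygon (mm coordinates) by voxel-centre inclusion."""
    poly = _validated_polygon(points, "region")
    x, y = _voxel_centers_mm(n_rows, n_cols, pixel_spacing)
    inside = shapely.contains_xy(poly, x, y)
    return inside.reshape(n_rows, n_cols)


def build_myocardium_mask(contours: ContourSet, stack: ImageStack) -> np.ndarray:
    """Per-slice myocardial mask: inside epicardium, outside endocardium.

    Exclusion polygons are subtracted after the annulus is formed.  Slices
    without contour annotations are left empty.

    Raises
    ------
    GeometryError
        If the endocardial contour is not strictly inside the epicardial
        contour, or either polygon is degenerate.
    """
    n_slices, n_rows, n_cols = stack.shape
    mask = np.zeros(stack.shape, dtype=bool)
    x, y = _voxel_centers_mm(n_rows, n_cols, stack.pixel_spacing)
    for idx, sc in sorted(contours.items()):
        if idx < 0 or idx >= n_slices:
            raise GeometryError(f"contour slice index {idx} outside stack of {n_slices}")
        endo = _validated_polygon(sc.endo, f"slice {idx} endo")
        epi = _validated_polygon(sc.epi, f"slice {idx} epi")
        if not epi.contains(endo):
            raise GeometryError(
                f"slice {idx}: endocardial contour must lie strictly inside the epicardial contour"
            )
        sl = shapely.contains_xy(epi, x, y) & ~shapely.contains_xy(endo, x, y)
        if not sl.any():
            raise GeometryError(f"slice {idx}: contours enclose no myocardial voxels")
        for excl in sc.exclusions:
            epoly = _validated_polygon(excl, f"slice {idx} exclusion")
            sl &= ~shapely.contains_xy(epoly, x, y)
        if not sl.any():
            logger.warning("slice %d: exclusions removed the entire myocardium", idx)
        mask[idx] = sl.reshape(n_rows, n_cols)
    return mask


def _slice_centroid_and_midwall(sc: SliceContours) -> tuple[np.ndarray, float]:
    """Epicardial centroid and mid-wall radius (mm) for one slice.

    The mid-wall radius is the mean of the average endo- and epicardial
    vertex distances from the centroid; it converts the mm extension of the
    insertion borders into an angle.
    """
    epi = _validated_polygon(sc.epi, "epi")
    centroid = np.asarray(epi.centroid.coords[0])
    r_epi = np.linalg.norm(sc.epi - centroid, axis=1).mean()
    r_endo = np.linalg.norm(sc.endo - centroid, axis=1).mean()
    return centroid, 0.5 * (r_endo + r_epi)


def _septal_arc(
    insertion_points: np.ndarray,
    centroid: np.ndarray,
    midwall_radius: float,
    extension_mm: float,
) -> tuple[float, float]:
    """Start angle and angular span (radians, CCW from start) of the septal wedge.

    The septal arc is the minor arc between the two insertion-point angles
    (ties at exactly pi resolved CCW from the first point), each end
    extended by ``extension_mm / midwall_radius``.
    """
    d = insertion_points - centroid
    if np.linalg.norm(insertion_points[0] - insertion_points[1]) < 1e-9:
        raise GeometryError("insertion points coincide")
    a0, a1 = np.arctan2(d[:, 1], d[:, 0])
    span_ccw = (a1 - a0) % TWO_PI
    if span_ccw <= np.pi:
        start, span = a0, span_ccw
    else:
        start, span = a1, TWO_PI - span_ccw
    ext = extension_mm / midwall_radius
    start -= ext
    span += 2 * ext
    if span >= TWO_PI:
        raise GeometryError(
            f"extension {extension_mm} mm makes the septal wedge cover the full "
            f"circumference ({np.degrees(span):.1f} deg of 360)"
        )
    return start % TWO_PI, span


def define_septal_region(
    contours: ContourSet,
    stack: ImageStack,
    extension_mm: float = 10.0,
    myocardium: np.ndarray | None = None,
) -> np.ndarray:
    """Septal mask: myocardial voxels inside the extended insertion-point wedge.

    Parameters
    ----------
    contours
        Per-slice annotations; insertion points missing on a slice are
        propagated from the nearest annotated slice.
    extension_mm
        Distance beyond each RV insertion point, as arc length along the
        mid-wall circumference, included in the septal region.
    myocardium
        Precomputed myocardial mask; built from ``contours`` if omitted.

    Returns
    -------
    Boolean grid, a subset of the myocardial mask.
    """
    if extension_mm < 0:
        raise ValueError("extension_mm must be non-negative")
    if myocardium is None:
        myocardium = build_myocardium_mask(contours, stack)
    n_slices, n_rows, n_cols = stack.shape
    annotated = {i: sc.insertion_points for i, sc in contours.items() if sc.insertion_points is not None}
    if not annotated:
        raise GeometryError("no slice carries RV insertion points")
    septal = np.zeros(stack.shape, dtype=bool)
    x, y = _voxel_centers_mm(n_rows, n_cols, stack.pixel_spacing)
    for idx, sc in sorted(contours.items()):
        pts = sc.insertion_points
        if pts is None:
            nearest = min(annotated, key=lambda j: abs(j - idx))
            pts = annotated[nearest]
            logger.info("slice %d: insertion points propagated from slice %d", idx, nearest)
        centroid, midwall = _slice_centroid_and_midwall(sc)
        start, span = _septal_arc(pts, centroid, midwall, extension_mm)
        theta = np.arctan2(y - centroid[1], x - centroid[0])
        in_wedge = ((theta - start) % TWO_PI) <= span
        septal[idx] = in_wedge.reshape(n_rows, n_cols) & myocardium[idx]
    return septal


def build_region_masks(
    contours: ContourSet,
    stack: ImageStack,
    extension_mm: float = 10.0,
) -> RegionMasks:
    """Myocardial, septal and remote masks from one contour set.

    The remote mask rasterizes each slice's remote-ROI polygon restricted
    to the myocardium; septal voxels are removed from it so the reference
    region can never overlap the region being measured.
    """
    myocardium = build_myocardium_mask(contours, stack)
    septal = define_septal_region(contours, stack, extension_mm, myocardium=myocardium)
    n_slices, n_rows, n_cols = stack.shape
    remote = np.zeros(stack.shape, dtype=bool)
    for idx, sc in contours.items():
        if sc.remote is None:
            continue
        remote[idx] = polygon_mask(sc.remote, n_rows, n_cols, stack.pixel_spacing)
    remote &= myocardium & ~septal
    return RegionMasks(myocardium=myocardium, septal=septal, remote=remote)


def compute_lv_mass(
    myocardium: np.ndarray,
    stack: ImageStack,
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> float:
    """LV mass in grams from the myocardial mask and voxel geometry.

    mass = voxel count x pixel_spacing^2 x (slice thickness + gap) x density,
    with mm^3 converted to mL.  An empty mask yields 0 g with a warning.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    count = int(np.count_nonzero(myocardium))
    if count == 0:
        logger.warning("empty myocardial mask: LV mass is 0 g")
        return 0.0
    return count * stack.voxel_volume_ml * density
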