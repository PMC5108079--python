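"""Core containers and errors shared across the package.

Coordinate conventions
----------------------
Images are ``(slice, row, col)`` arrays.  Contours live in millimetres in
the image plane with the origin at the image corner, *x* increasing with
column (rightward) and *y* increasing with row (downward).  A voxel with
index ``(row, col)`` has its centre at ``((col + 0.5) * s, (row + 0.5) * s)``
where ``s`` is the in-plane pixel spacing.  Voxel indices are 0-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

MYOCARDIAL_DENSITY_G_PER_ML = 1.05
"""Myocardial tissue density in g/mL, the standard CMR mass convention."""


class GeometryError(ValueError):
    """Degenerate or inconsistent contour geometry."""


class CollinearityError(ValueError):
    """Covariate matrix is rank deficient (e.g. duplicated columns)."""


class FitError(RuntimeError):
    """A model fit failed to converge or the likelihood is degenerate."""


@dataclass(frozen=True)
class ImageStack:
    """Short-axis signal-intensity stack.

    Parameters
    ----------
    voxels
        ``(n_slices, n_rows, n_cols)`` float array of signal intensities.
    pixel_spacing
        In-plane pixel size in mm (isotropic).
    slice_thickness, slice_gap
        Acquired slice thickness and inter-slice gap in mm.  The effective
        through-plane spacing used for volumes is their sum, assuming the
        stack tiles the ventricle contiguously.
    """

    voxels: np.ndarray
    pixel_spacing: float
    slice_thickness: float = 8.0
    slice_gap: float = 2.0

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3:
            raise ValueError(f"voxels must be 3-D (slice,row,col), got {vox.ndim}-D")
        object.__setattr__(self, "voxels", vox)
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be > 0")
        if not self.slice_spacing > 0:
            raise ValueError("slice_thickness + slice_gap must be > 0")

    @property
    def slice_spacing(self) -> float:
        """Effective through-plane spacing (thickness + gap) in mm."""
        return self.slice_thickness + self.slice_gap

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of a single voxel in mL."""
        return self.pixel_spacing**2 * self.slice_spacing / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class SliceContours:
    """Contour annotation for one short-axis slice (mm coordinates).

    ``endo`` and ``epi`` are closed ``(n, 2)`` polygons (first point need
    not be repeated).  ``insertion_points`` are the two RV–LV contact
    points delimiting the septum.  ``remote`` outlines the reference ROI
    in remote (non-septal) myocardium.  ``exclusions`` remove artifact
    regions from the myocardial mask.
    """

    endo: np.ndarray
    epi: np.ndarray
    insertion_points: np.ndarray | None = None
    remote: np.ndarray | None = None
    exclusions: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.endo = np.asarray(self.endo, dtype=float)
        self.epi = np.asarray(self.epi, dtype=float)
        for name in ("endo", "epi"):
            poly = getattr(self, name)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise GeometryError(f"{name} polygon must be (n>=3, 2)")
        if self.insertion_points is not None:
            pts = np.asarray(self.insertion_points, dtype=float)
            if pts.shape != (2, 2):
                raise GeometryError("insertion_points must be two (x, y) points")
            self.insertion_points = pts
        if self.remote is not None:
            self.remote = np.asarray(self.remote, dtype=float)
        self.exclusions = [np.asarray(p, dtype=float) for p in self.exclusions]


class ContourSet(dict):
    """Mapping ``slice index -> SliceContours``."""

    def __init__(self, slices: Mapping[int, SliceContours] | None = None):
        super().__init__()
        if slices:
            for k, v in slices.items():
                self[int(k)] = v


@dataclass(frozen=True)
class RegionMasks:
    """Boolean voxel masks for the anatomical regions of interest."""

    myocardium: np.ndarray
    septal: np.ndarray
    remote: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.septal & ~self.myocardium):
            raise GeometryError("septal mask must be a subset of myocardium")
        if np.any(self.remote & ~self.myocardium):
            raise GeometryError("remote mask must be a subset of myocardium")
        if np.any(self.septal & self.remote):
            raise GeometryError("septal and remote masks must be disjoint")


@dataclass(frozen=True)
class RemoteStats:
    """Signal statistics of the remote reference myocardium."""

    mean: float
    sd: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels < 2:
            raise ValueError("remote ROI must contain at least 2 voxels")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class LgeResult:
    """Scar burden at one threshold, in grams and % of LV mass.

    Both percentages share the total LV mass as denominator.
    """

    threshold_k: float | str
    total_mass_g: float
    total_pct: float
    septal_mass_g: float
    septal_pct: float
    lv_mass_g: float

    def __post_init__(self) -> None:
        if not 0 <= self.septal_mass_g <= self.total_mass_g + 1e-9:
            raise ValueError("septal mass must lie in [0, total mass]")
        for pct in (self.total_pct, self.septal_pct):
            if not -1e-9 <= pct <= 100 + 1e-9:
                raise ValueError("percentages must lie in [0, 100]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GroundTruth:
    """Known fibrosis truth attached to a generated phantom."""

    lesion_mask: np.ndarray
    true_total_pct: float
    true_septal_pct: float
    true_lv_mass_g: float


@dataclass(frozen=True)
class DiagnosticResult:
    """2x2 diagnostic performance of a binary test against an outcome."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    n_missed: int
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class AgreementResult:
    """Observer-agreement summary: ICC and Bland–Altman bias/limits."""

    icc: float | None = None
    icc_ci: tuple[float, float] | None = None
    bias: float | None = None
    sd_diff: float | None = None
    loa_lower: float | None = None
    loa_upper: float | None = None


@dataclass(frozen=True)
class CovariateEffect:
    """Single-covariate row of a Cox model summary."""

    name: str
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    chi2: float
    p: float


@dataclass(frozen=True)
class SurvivalFit:
    """Cox proportional-hazards fit summary."""

    effects: tuple[CovariateEffect, ...]
    log_likelihood: float
    n: int
    n_events: int
    ph_test_p: Mapping[str, float]

    def effect(self, name: str) -> CovariateEffect:
        for eff in self.effects:
            if eff.name == name:
                return eff
        raise KeyError(name)


def as_bool_mask(mask: np.ndarray, shape: Sequence[int] | None = None) -> np.ndarray:
    """Validate and coerce a boolean voxel mask."""
    arr = np.asarray(mask)
    if arr.dtype != bool:
        arr = arr.astype(bool)
    if shape is not None and tuple(arr.shape) != tuple(shape):
        raise ValueError(f"mask shape {arr.shape} does not match grid {tuple(shape)}")
    return arr
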