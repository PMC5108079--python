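"""Synthetic phantoms and cohorts with known ground truth.

The phantom is an annular "myocardium" on a short-axis grid: remote tissue
has Gaussian signal around ``remote_mean`` with spread ``remote_sd``,
hyperenhanced lesions sit a configurable number of remote SDs above it, and
two RV insertion angles delimit the septum.  A mild in-plane point-spread
smoothing (``psf_sigma_px``) is applied to the final image, emulating the
spatially correlated noise of filtered MRI reconstructions; set it to 0 for
strictly white noise.  Because each lesion is painted as a known voxel set,
every phantom carries exact burden ground truth for downstream validation.

The cohort simulator draws patient covariates (LVEF, a zero-inflated septal
burden) and event times from an exponential proportional-hazards model, so
a Cox fit on a large simulated cohort should recover the configured hazard
ratios.  Non-cardiac death and random loss to follow-up act as independent
censoring, mirroring how such registries are analysed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import (
    MYOCARDIAL_DENSITY_G_PER_ML,
    ContourSet,
    GeometryError,
    GroundTruth,
    ImageStack,
    SliceContours,
)

TWO_PI = 2.0 * np.pi

LesionPattern = Literal["septal_striae", "rv_insertion", "subepicardial", "diffuse"]

COHORT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "lvef_pct",
    "septal_pct_5sd",
    "septal_pct_3sd",
    "septal_pct_2sd",
    "followup_years",
    "cardiac_death",
    "appropriate_icd",
    "scd",
    "noncardiac_death",
]


@dataclass(frozen=True)
class LesionSpec:
    """One hyperenhanced lesion, an angular/transmural sector of the wall.

    ``transmural_range`` gives the wall-depth band as fractions from the
    endocardium (0) to the epicardium (1); ``intensity_offset_sd`` is the
    lesion's signal elevation in multiples of ``remote_sd``.
    """

    pattern: LesionPattern = "septal_striae"
    angular_center_deg: float | None = None
    angular_extent_deg: float = 90.0
    transmural_range: tuple[float, float] | None = None
    intensity_offset_sd: float = 6.0
    slices: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.intensity_offset_sd <= 0:
            raise ValueError("lesion intensity offset must be positive")
        if not 0 < self.angular_extent_deg <= 360:
            raise ValueError("angular extent must lie in (0, 360]")
        if self.transmural_range is not None:
            f0, f1 = self.transmural_range
            if not (0 <= f0 < f1 <= 1):
                raise ValueError("transmural range must satisfy 0 <= f0 < f1 <= 1")


_PATTERN_TRANSMURAL = {
    "septal_striae": (0.30, 0.70),  # mid-wall band
    "rv_insertion": (0.0, 1.0),
    "subepicardial": (0.70, 1.0),
    "diffuse": (0.0, 1.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, signal and lesion recipe for one phantom stack."""

    n_slices: int = 6
    grid_size: int = 96
    pixel_spacing: float = 1.0
    slice_thickness: float = 8.0
    slice_gap: float = 2.0
    endo_radius: float = 20.0
    epi_radius: float = 32.0
    insertion_angles: tuple[float, float] = (120.0, 240.0)
    remote_mean: float = 30.0
    remote_sd: float = 5.0
    blood_mean: float | None = None
    lesion_list: tuple[LesionSpec, ...] = ()
    septal_extension_mm: float = 10.0
    psf_sigma_px: float = 0.5
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if not self.endo_radius < self.epi_radius:
            raise GeometryError("endo_radius must be smaller than epi_radius")
        if self.epi_radius * 2 >= self.grid_size * self.pixel_spacing:
            raise GeometryError("epicardium does not fit inside the grid")
        if self.remote_sd <= 0:
            raise ValueError("remote_sd must be positive")
        a0, a1 = self.insertion_angles
        if abs((a0 - a1) % 360.0) < 1e-9:
            raise ValueError("insertion angles must be distinct")
        if self.n_slices < 1 or self.grid_size < 8:
            raise ValueError("degenerate grid")
        object.__setattr__(self, "lesion_list", tuple(self.lesion_list))

    @property
    def center_mm(self) -> tuple[float, float]:
        c = 0.5 * self.grid_size * self.pixel_spacing
        return (c, c)

    @property
    def septal_mid_angle_deg(self) -> float:
        """Mid-angle of the minor arc between the insertion angles."""
        a0, a1 = self.insertion_angles
        span = (a1 - a0) % 360.0
        if span <= 180.0:
            return (a0 + span / 2.0) % 360.0
        return (a1 + (360.0 - span) / 2.0) % 360.0


def _circle_polygon(center: tuple[float, float], radius: float, n: int = 256) -> np.ndarray:
    ang = np.linspace(0.0, TWO_PI, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )


def _sector_polygon(
    center: tuple[float, float],
    r_inner: float,
    r_outer: float,
    start_deg: float,
    span_deg: float,
    n: int = 48,
) -> np.ndarray:
    ang = np.radians(np.linspace(start_deg, start_deg + span_deg, n))
    outer = np.column_stack([center[0] + r_outer * np.cos(ang), center[1] + r_outer * np.sin(ang)])
    inner = np.column_stack([center[0] + r_inner * np.cos(ang), center[1] + r_inner * np.sin(ang)])
    return np.vstack([outer, inner[::-1]])


def _polar_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Radius (mm) and angle (deg in [0, 360)) of each in-plane voxel centre."""
    n = spec.grid_size
    rows, cols = np.mgrid[0:n, 0:n]
    cx, cy = spec.center_mm
    x = (cols + 0.5) * spec.pixel_spacing - cx
    y = (rows + 0.5) * spec.pixel_spacing - cy
    return np.hypot(x, y), np.degrees(np.arctan2(y, x)) % 360.0


def _in_arc(angle_deg: np.ndarray, start_deg: float, span_deg: float) -> np.ndarray:
    return ((angle_deg - start_deg) % 360.0) <= span_deg


def septal_wedge_bounds(spec: PhantomSpec) -> tuple[float, float]:
    """Start angle and span (deg) of the extended septal wedge, as the
    quantification pipeline defines it (minor insertion arc plus the
    mid-wall arc-length extension on each side)."""
    a0, a1 = spec.insertion_angles
    span = (a1 - a0) % 360.0
    start = a0 if span <= 180.0 else a1
    span = min(span, 360.0 - span)
    midwall = 0.5 * (spec.endo_radius + spec.epi_radius)
    ext = math.degrees(spec.septal_extension_mm / midwall)
    return (start - ext) % 360.0, span + 2 * ext


def _remote_wedge(spec: PhantomSpec, angle_offset_deg: float = 0.0, span_deg: float = 60.0):
    """Angular placement of the remote reference ROI: a mid-myocardial wedge
    centred diametrically opposite the septal mid-angle."""
    center_angle = (spec.septal_mid_angle_deg + 180.0 + angle_offset_deg) % 360.0
    wall = spec.epi_radius - spec.endo_radius
    r_inner = spec.endo_radius + 0.25 * wall
    r_outer = spec.endo_radius + 0.75 * wall
    return center_angle - span_deg / 2.0, span_deg, r_inner, r_outer


def _lesion_mask(
    lesion: LesionSpec, spec: PhantomSpec, radius: np.ndarray, angle: np.ndarray, myo2d: np.ndarray
) -> np.ndarray:
    center = lesion.angular_center_deg
    if center is None:
        if lesion.pattern == "rv_insertion":
            center = spec.insertion_angles[0]
        elif lesion.pattern == "subepicardial":
            center = (spec.septal_mid_angle_deg + 180.0) % 360.0
        else:
            center = spec.septal_mid_angle_deg
    extent = 360.0 if lesion.pattern == "diffuse" else lesion.angular_extent_deg
    trans = lesion.transmural_range or _PATTERN_TRANSMURAL[lesion.pattern]
    wall = spec.epi_radius - spec.endo_radius
    r0 = spec.endo_radius + trans[0] * wall
    r1 = spec.endo_radius + trans[1] * wall
    in_band = (radius >= r0) & (radius < r1)
    in_arc = _in_arc(angle, center - extent / 2.0, extent)
    return myo2d & in_band & in_arc


def generate_phantom(spec: PhantomSpec) -> tuple[ImageStack, ContourSet, GroundTruth]:
    """Build one phantom stack with contours and exact burden ground truth.

    Identical specs (including ``noise_seed``) produce bit-identical output.
    """
    rng = np.random.default_rng(spec.noise_seed)
    n = spec.grid_size
    radius, angle = _polar_grids(spec)
    myo2d = (radius >= spec.endo_radius) & (radius < spec.epi_radius)
    blood2d = radius < spec.endo_radius

    sept_start, sept_span = septal_wedge_bounds(spec)
    if sept_span >= 360.0:
        raise GeometryError("septal extension covers the full circumference")
    septal2d = myo2d & _in_arc(angle, sept_start, sept_span)

    blood_mean = 1.5 * spec.remote_mean if spec.blood_mean is None else spec.blood_mean
    lesion_mask = np.zeros((spec.n_slices, n, n), dtype=bool)
    voxels = np.empty((spec.n_slices, n, n), dtype=float)
    for s in range(spec.n_slices):
        structure = np.zeros((n, n))
        structure[blood2d] = blood_mean
        structure[myo2d] = spec.remote_mean
        for lesion in spec.lesion_list:
            lo, hi = lesion.slices or (0, spec.n_slices - 1)
            if not lo <= s <= hi:
                continue
            lmask = _lesion_mask(lesion, spec, radius, angle, myo2d)
            structure[lmask] = spec.remote_mean + lesion.intensity_offset_sd * spec.remote_sd
            lesion_mask[s] |= lmask
        img = structure + rng.normal(0.0, spec.remote_sd, size=(n, n))
        if spec.psf_sigma_px > 0:
            img = gaussian_filter(img, sigma=spec.psf_sigma_px, mode="nearest")
        voxels[s] = img

    stack = ImageStack(
        voxels=voxels,
        pixel_spacing=spec.pixel_spacing,
        slice_thickness=spec.slice_thickness,
        slice_gap=spec.slice_gap,
    )

    center = spec.center_mm
    endo_poly = _circle_polygon(center, spec.endo_radius)
    epi_poly = _circle_polygon(center, spec.epi_radius)
    ins = np.array(
        [
            [
                center[0] + spec.epi_radius * math.cos(math.radians(a)),
                center[1] + spec.epi_radius * math.sin(math.radians(a)),
            ]
            for a in spec.insertion_angles
        ]
    )
    rstart, rspan, r_in, r_out = _remote_wedge(spec)
    remote_poly = _sector_polygon(center, r_in, r_out, rstart, rspan)
    contours = ContourSet(
        {
            s: SliceContours(
                endo=endo_poly.copy(),
                epi=epi_poly.copy(),
                insertion_points=ins.copy(),
                remote=remote_poly.copy(),
            )
            for s in range(spec.n_slices)
        }
    )

    myo_voxels = int(myo2d.sum()) * spec.n_slices
    vox_ml = spec.pixel_spacing**2 * (spec.slice_thickness + spec.slice_gap) / 1000.0
    septal_lesion = lesion_mask & septal2d[None, :, :]
    truth = GroundTruth(
        lesion_mask=lesion_mask,
        true_total_pct=100.0 * lesion_mask.sum() / myo_voxels,
        true_septal_pct=100.0 * septal_lesion.sum() / myo_voxels,
        true_lv_mass_g=myo_voxels * vox_ml * MYOCARDIAL_DENSITY_G_PER_ML,
    )
    return stack, contours, truth


def with_perturbed_remote(
    contours: ContourSet,
    spec: PhantomSpec,
    angle_offset_deg: float,
    span_deg: float = 60.0,
) -> ContourSet:
    """Copy of ``contours`` with the remote ROI wedge rotated/resized,
    emulating a second reader's independent ROI placement."""
    rstart, rspan, r_in, r_out = _remote_wedge(spec, angle_offset_deg, span_deg)
    poly = _sector_polygon(spec.center_mm, r_in, r_out, rstart, rspan)
    out = ContourSet()
    for idx, sc in contours.items():
        out[idx] = SliceContours(
            endo=sc.endo.copy(),
            epi=sc.epi.copy(),
            insertion_points=None if sc.insertion_points is None else sc.insertion_points.copy(),
            remote=poly.copy(),
            exclusions=[p.copy() for p in sc.exclusions],
        )
    return out


def random_phantom_spec(
    seed: int,
    intensity_offset_sd: float = 6.0,
    base: PhantomSpec | None = None,
) -> PhantomSpec:
    """Phantom spec with randomized septal lesion burden (deterministic in seed).

    Draws one mid-wall septal striae lesion of variable arc and depth and,
    half the time, an RV-insertion lesion, giving phantom-to-phantom burden
    variability for recovery and reproducibility studies.
    """
    rng = np.random.default_rng(seed)
    base = base or PhantomSpec()
    lesions = [
        LesionSpec(
            pattern="septal_striae",
            angular_center_deg=base.septal_mid_angle_deg + rng.uniform(-15, 15),
            angular_extent_deg=rng.uniform(60, 110),
            transmural_range=tuple(
                np.round(sorted(rng.uniform([0.2, 0.55], [0.45, 0.85])), 3)
            ),
            intensity_offset_sd=intensity_offset_sd,
        )
    ]
    if rng.random() < 0.5:
        lesions.append(
            LesionSpec(
                pattern="rv_insertion",
                angular_center_deg=base.insertion_angles[int(rng.integers(2))],
                angular_extent_deg=rng.uniform(20, 35),
                intensity_offset_sd=intensity_offset_sd,
            )
        )
    return replace(base, lesion_list=tuple(lesions), noise_seed=int(rng.integers(2**31 - 1)))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeptalMixture:
    """Zero-inflated positive distribution for septal burden (% LV mass).

    With probability ``p_zero`` the burden is exactly 0; otherwise it is
    Gamma with the given mean and shape (``shape=None`` degenerates to the
    constant ``pos_mean``, handy for binary-marker simulations).
    """

    p_zero: float = 0.45
    pos_mean: float = 5.3
    pos_shape: float | None = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_zero < 1:
            raise ValueError("p_zero must lie in [0, 1)")
        if self.pos_mean <= 0:
            raise ValueError("positive-component mean must be > 0")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        zero = rng.random(size) < self.p_zero
        if self.pos_shape is None:
            pos = np.full(size, self.pos_mean)
        else:
            pos = rng.gamma(self.pos_shape, self.pos_mean / self.pos_shape, size)
        return np.where(zero, 0.0, pos)


@dataclass(frozen=True)
class CohortSpec:
    """Simulation recipe for a follow-up cohort.

    Event times follow an exponential proportional-hazards model with
    linear predictor ``log_hr_per_pct * septal_pct_5sd +
    log_hr_per_lvef * (lvef - lvef_mean)``; administrative censoring,
    random loss to follow-up and non-cardiac death censor independently.
    All rates are per patient-year.
    """

    n_patients: int = 118
    lvef_mean: float = 32.0
    lvef_sd: float = 12.0
    age_mean: float = 57.0
    age_sd: float = 14.0
    female_fraction: float = 0.42
    septal_mixture: SeptalMixture = field(default_factory=SeptalMixture)
    log_hr_per_pct: float = math.log(1.21)
    log_hr_per_lvef: float = math.log(0.93)
    baseline_hazard: float = 0.02
    censoring_rate: float = 0.02
    noncardiac_death_rate: float = 0.02
    max_followup_years: float = 4.2
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.baseline_hazard, self.censoring_rate, self.noncardiac_death_rate)
        if not all(np.isfinite(rates)) or any(r < 0 for r in rates):
            raise ValueError("hazard, censoring and death rates must be finite and >= 0")
        if not np.isfinite(self.log_hr_per_pct) or not np.isfinite(self.log_hr_per_lvef):
            raise ValueError("log hazard-ratio slopes must be finite")
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.max_followup_years <= 0:
            raise ValueError("max_followup_years must be positive")


def _exponential_times(rng: np.random.Generator, rate: float, size: int) -> np.ndarray:
    if rate == 0:
        return np.full(size, np.inf)
    return rng.exponential(1.0 / rate, size)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate one cohort table (one row per patient, schema ``COHORT_COLUMNS``).

    The septal burden at the 3SD and 2SD thresholds is the 5SD burden plus
    independent positive increments, preserving the nesting
    ``5SD <= 3SD <= 2SD`` that lower thresholds imply.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18, 95)
    sex = np.where(rng.random(n) < spec.female_fraction, "F", "M")
    lvef = np.clip(rng.normal(spec.lvef_mean, spec.lvef_sd, n), 8, 70)
    septal5 = spec.septal_mixture.sample(rng, n)
    septal3 = septal5 + rng.gamma(2.0, 4.0 / 2.0, n)
    septal2 = septal3 + rng.gamma(2.0, 4.2 / 2.0, n)

    lp = spec.log_hr_per_pct * septal5 + spec.log_hr_per_lvef * (lvef - spec.lvef_mean)
    hazard = spec.baseline_hazard * np.exp(lp)
    with np.errstate(divide="ignore"):
        t_event = np.where(hazard > 0, rng.exponential(1.0, n) / np.where(hazard > 0, hazard, 1.0), np.inf)
    t_admin = rng.uniform(0.1, spec.max_followup_years, n)
    t_lost = _exponential_times(rng, spec.censoring_rate, n)
    t_nc = _exponential_times(rng, spec.noncardiac_death_rate, n)

    followup = np.minimum.reduce([t_event, t_admin, t_lost, t_nc])
    had_event = t_event <= followup
    nc_death = (~had_event) & (t_nc <= followup)

    # split the composite event into its components (ICD therapy dominates,
    # occasionally coinciding with cardiac death; a minority of cardiac
    # deaths are sudden)
    u = rng.random(n)
    icd = had_event & (u < 0.70)
    cdeath = had_event & (u >= 0.65)  # 5 % overlap band gets both
    scd = cdeath & (rng.random(n) < 0.15)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "age": np.round(age, 1),
            "sex": sex,
            "lvef_pct": np.round(lvef, 1),
            "septal_pct_5sd": septal5,
            "septal_pct_3sd": septal3,
            "septal_pct_2sd": septal2,
            "followup_years": followup,
            "cardiac_death": cdeath.astype(int),
            "appropriate_icd": icd.astype(int),
            "scd": scd.astype(int),
            "noncardiac_death": nc_death.astype(int),
        }
    )
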