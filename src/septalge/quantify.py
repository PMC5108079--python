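"""Scar segmentation and burden reporting.

The Signal Threshold versus Reference Mean (STRM) rule flags a myocardial
voxel as hyperenhanced when its signal strictly exceeds
``mean + k * sd`` of a remote reference ROI, for an SD multiplier ``k``
(conventionally 2, 3 or 5).  An expert-style alternative applies a manually
chosen absolute signal threshold, optionally per slice.  Burden is reported
as absolute mass (g) and as a percentage of total LV mass; the septal and
total percentages share the LV-mass denominator.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

from .core import (
    MYOCARDIAL_DENSITY_G_PER_ML,
    ImageStack,
    LgeResult,
    RemoteStats,
    as_bool_mask,
)
from .geometry import compute_lv_mass

logger = logging.getLogger(__name__)


def remote_stats(stack: ImageStack, remote_mask: np.ndarray) -> RemoteStats:
    """Sample mean and SD (n-1 denominator) of the remote ROI, pooled across slices."""
    remote_mask = as_bool_mask(remote_mask, stack.shape)
    values = stack.voxels[remote_mask]
    if values.size < 2:
        raise ValueError(f"remote ROI must contain at least 2 voxels, got {values.size}")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0:
        logger.warning("remote ROI has zero signal variance; STRM thresholds will be degenerate")
    return RemoteStats(mean=mean, sd=sd, n_voxels=int(values.size))


def strm_segment(
    stack: ImageStack,
    myocardium: np.ndarray,
    stats: RemoteStats,
    k: float,
) -> np.ndarray:
    """STRM scar mask: myocardial voxels with signal > mean + k*sd (strict)."""
    if k <= 0:
        raise ValueError("SD multiplier k must be positive")
    if stats.sd == 0:
        raise ValueError(
            "remote SD is zero; revise the remote reference ROI before STRM segmentation"
        )
    myocardium = as_bool_mask(myocardium, stack.shape)
    threshold = stats.mean + k * stats.sd
    return myocardium & (stack.voxels > threshold)


def manual_threshold_segment(
    stack: ImageStack,
    myocardium: np.ndarray,
    si_threshold: float | Sequence[float] | Mapping[int, float],
) -> np.ndarray:
    """Scar mask from an absolute signal-intensity threshold (strict >).

    ``si_threshold`` may be a single value, a per-slice sequence, or a
    mapping from slice index to threshold (unlisted slices use +inf).
    A threshold outside the observed myocardial signal range only warns.
    """
    myocardium = as_bool_mask(myocardium, stack.shape)
    n_slices = stack.shape[0]
    if isinstance(si_threshold, Mapping):
        thr = np.full(n_slices, np.inf)
        for idx, t in si_threshold.items():
            thr[int(idx)] = float(t)
    elif np.ndim(si_threshold) == 0:
        thr = np.full(n_slices, float(si_threshold))
    else:
        thr = np.asarray(si_threshold, dtype=float)
        if thr.shape != (n_slices,):
            raise ValueError("per-slice thresholds must have one entry per slice")
    if myocardium.any():
        vals = stack.voxels[myocardium]
        finite = thr[np.isfinite(thr)]
        if finite.size and (finite.min() < vals.min() or finite.max() > vals.max()):
            logger.warning(
                "manual threshold outside observed myocardial signal range [%.3g, %.3g]",
                vals.min(),
                vals.max(),
            )
    return myocardium & (stack.voxels > thr[:, None, None])


def quantify_lge(
    scar: np.ndarray,
    septal: np.ndarray,
    myocardium: np.ndarray,
    stack: ImageStack,
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
    threshold_k: float | str = "manual",
) -> LgeResult:
    """Scar burden in grams and % of LV mass, total and within the septum.

    ``scar`` and ``septal`` must be subsets of ``myocardium``; the septal
    percentage uses the total LV mass as denominator.
    """
    myocardium = as_bool_mask(myocardium)
    scar = as_bool_mask(scar, myocardium.shape)
    septal = as_bool_mask(septal, myocardium.shape)
    if not myocardium.any():
        raise ValueError("myocardial mask is empty")
    if np.any(scar & ~myocardium):
        raise ValueError("scar mask extends outside the myocardium")
    if np.any(septal & ~myocardium):
        raise ValueError("septal mask extends outside the myocardium")
    voxel_mass = stack.voxel_volume_ml * density
    lv_mass = compute_lv_mass(myocardium, stack, density)
    total_mass = int(np.count_nonzero(scar)) * voxel_mass
    septal_mass = int(np.count_nonzero(scar & septal)) * voxel_mass
    return LgeResult(
        threshold_k=threshold_k,
        total_mass_g=total_mass,
        total_pct=100.0 * total_mass / lv_mass,
        septal_mass_g=septal_mass,
        septal_pct=100.0 * septal_mass / lv_mass,
        lv_mass_g=lv_mass,
    )


def classify_septal_positive(result: LgeResult, cutoff_pct: float) -> bool:
    """Binary septal-fibrosis criterion: positive iff septal % > cutoff (strict)."""
    if cutoff_pct < 0:
        raise ValueError("cutoff must be non-negative")
    return bool(result.septal_pct > cutoff_pct)
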