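"""Target registration error (TRE) evaluation.

TRE at a voxel is the Euclidean distance between where the test field and
the ground-truth field send that voxel: ``|u_test(x) - u_gt(x)|``.
Statistics are accumulated per ROI; the TG-132 goal (95% of voxels within
2 mm) and the two-SD failure rule operate on these summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import ROIMask, ScalarVolume, VectorField

__all__ = [
    "TREStats",
    "TREHistogram",
    "FlagResult",
    "TG132_LIMIT_MM",
    "TG132_FRACTION",
    "tre_map",
    "roi_tre_stats",
    "tg132_check",
    "flag_failures",
    "dice",
    "tre_histogram",
]

#: TG-132 goal: this fraction of voxels within this TRE.
TG132_LIMIT_MM = 2.0
TG132_FRACTION = 0.95


@dataclass(frozen=True)
class TREStats:
    """Per-ROI TRE summary (mm): mean, population SD, max, <=2 mm fraction."""

    roi: str
    tre_mean: float
    tre_sd: float
    tre_max: float
    frac_within_2mm: float
    n_voxels: int


@dataclass(frozen=True)
class TREHistogram:
    roi: str
    bin_edges: np.ndarray  # mm, len = len(counts) + 1
    counts: np.ndarray


@dataclass(frozen=True)
class FlagResult:
    """Outcome of the two-SD failure rule over a pooled TREμ table."""

    tre_avg: float
    tre_sd: float
    threshold: float
    flags: np.ndarray | pd.DataFrame


def tre_map(gt_field: VectorField, test_field: VectorField) -> ScalarVolume:
    """Voxel-wise TRE (mm): ``|u_test - u_gt|`` on the shared grid."""
    if gt_field.grid != test_field.grid:
        raise ValueError("fields must share one grid; resample the test field first")
    diff = test_field.displacements - gt_field.displacements
    return ScalarVolume(gt_field.grid, np.linalg.norm(diff, axis=-1))


def roi_tre_stats(tre: ScalarVolume, mask: ROIMask) -> TREStats:
    """Mean, population SD, max, and <=2 mm fraction over ROI member voxels."""
    if tre.grid != mask.grid:
        raise ValueError("TRE map and mask must share one grid")
    vals = tre.values[mask.membership]
    return TREStats(
        roi=mask.name,
        tre_mean=float(vals.mean()),
        tre_sd=float(vals.std()),
        tre_max=float(vals.max()),
        frac_within_2mm=float((vals <= TG132_LIMIT_MM).mean()),
        n_voxels=int(vals.size),
    )


def tg132_check(stats: TREStats) -> bool:
    """TG-132 goal: pass iff >= 95% of ROI voxels have TRE within 2 mm."""
    return stats.frac_within_2mm >= TG132_FRACTION


def flag_failures(tre_means) -> FlagResult:
    """Two-SD failure rule over a pooled TREμ table for one ROI.

    The system-independent average and SD are computed over *all* entries
    (pooled across registration sources and phantoms, population SD); an
    entry is flagged when its TREμ reaches the average plus two SDs.  A
    zero pooled SD yields no flags.
    """
    is_frame = isinstance(tre_means, pd.DataFrame)
    vals = tre_means.to_numpy(dtype=float) if is_frame else np.asarray(tre_means, dtype=float)
    if vals.size < 3:
        raise ValueError("need >= 3 TREμ entries to pool")
    avg = float(vals.mean())
    sd = float(vals.std())
    threshold = avg + 2.0 * sd
    if sd == 0:
        flags = np.zeros_like(vals, dtype=bool)
    else:
        flags = vals >= threshold
    if is_frame:
        flags = pd.DataFrame(flags, index=tre_means.index, columns=tre_means.columns)
    return FlagResult(tre_avg=avg, tre_sd=sd, threshold=threshold, flags=flags)


def dice(mask_a: ROIMask, mask_b: ROIMask) -> float:
    """DICE similarity ``2|A∩B| / (|A|+|B|)`` of two masks on one grid."""
    if mask_a.grid != mask_b.grid:
        raise ValueError("masks must share one grid")
    a, b = mask_a.membership, mask_b.membership
    return float(2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum()))


def tre_histogram(
    tre: ScalarVolume, mask: ROIMask, bin_width: float = 0.5
) -> TREHistogram:
    """Voxel counts in half-open TRE bins ``[k*w, (k+1)*w)`` over the ROI."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    vals = tre.values[mask.membership]
    n_bins = max(int(np.floor(vals.max() / bin_width)) + 1, 1)
    edges = bin_width * np.arange(n_bins + 1)
    counts = np.histogram(vals, bins=edges)[0]
    # np.histogram closes the last bin; that matches "last bin extends to max"
    return TREHistogram(roi=mask.name, bin_edges=edges, counts=counts)
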