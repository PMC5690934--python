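"""Dosimetric error evaluation: dose warping, DVHs, and error statistics.

The end-of-treatment dose is pulled back to the planning (SOT) anatomy
through both the ground-truth and a test displacement field; the
registration's dosimetric impact is scored per ROI as the difference in
mean dose (Gy and % of the ground-truth mean), maximum dose, and the mean
point-by-point DVH difference (ΔDVHmean, evaluated on the volume axis as
dose-at-volume differences averaged over 1-99%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import ROIMask, ScalarVolume, VectorField, trilinear_sample

__all__ = [
    "DVHCurve",
    "DoseErrorStats",
    "transfer_dose",
    "compute_dvh",
    "dvh_mean_difference",
    "dose_error_stats",
]


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram: fraction of ROI volume >= dose."""

    roi: str
    dose_gy: np.ndarray  # ascending bin edges
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dose_gy, dtype=float)
        v = np.asarray(self.volume_fraction, dtype=float)
        if d.shape != v.shape or d.ndim != 1:
            raise ValueError("dose and volume arrays must be equal-length 1-D")
        if np.any(np.diff(d) <= 0):
            raise ValueError("dose edges must be strictly ascending")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("cumulative DVH must be monotone non-increasing")
        object.__setattr__(self, "dose_gy", d)
        object.__setattr__(self, "volume_fraction", v)

    def dose_at_volume(self, fractions) -> np.ndarray:
        """Invert the curve: dose received by at least the given volume fraction."""
        f = np.asarray(fractions, dtype=float)
        # volume_fraction is non-increasing in dose; np.interp needs ascending x
        return np.interp(f, self.volume_fraction[::-1], self.dose_gy[::-1])

    def mean_dose(self) -> float:
        """Mean ROI dose as the integral of dose-at-volume over the volume axis."""
        v = np.linspace(0.0, 1.0, 1001)
        return float(np.trapezoid(self.dose_at_volume(v), v))


@dataclass(frozen=True)
class DoseErrorStats:
    """Per-ROI dosimetric error between ground-truth- and test-transferred dose.

    Magnitudes are reported (the correlation analysis uses them); signed
    versions are retained for direction-of-error interpretation.
    """

    roi: str
    d_mean_pct: float | None  # % of ground-truth mean dose; None if that mean is 0
    d_mean_gy: float
    d_max_gy: float
    dvh_mean_gy: float
    signed_d_mean_gy: float
    signed_d_max_gy: float


def transfer_dose(
    eot_dose: ScalarVolume, field: VectorField, region: ROIMask | None = None
) -> ScalarVolume:
    """Pull the EOT dose back to the SOT grid: ``D_sot(x) = D_eot(x + u(x))``.

    Pure pull-back mapping (no energy/mass rescaling); points landing
    outside the dose grid receive 0 Gy.  A warning is attached when more
    than 1% of the voxels of ``region`` (typically the external contour;
    the whole grid when omitted) map outside the dose grid.
    """
    x = field.grid.world_coordinates().reshape(-1, 3)
    pts = x + field.displacements.reshape(-1, 3)
    vals, outside = trilinear_sample(eot_dose, pts, fill=0.0, return_outside=True)
    outside = outside.reshape(field.grid.shape)
    frac = outside[region.membership].mean() if region is not None else outside.mean()
    if frac > 0.01:
        warnings.warn(
            f"{100 * frac:.1f}% of target voxels mapped outside the "
            "dose grid; filled with 0 Gy",
            stacklevel=2,
        )
    return ScalarVolume(field.grid, vals.reshape(field.grid.shape))


def compute_dvh(
    dose: ScalarVolume, mask: ROIMask, bin_width: float = 0.02
) -> DVHCurve:
    """Cumulative DVH of the ROI at the given dose bin width (Gy)."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if dose.grid != mask.grid:
        raise ValueError("dose and mask must share one grid")
    vals = dose.values[mask.membership]
    top = max(float(vals.max()), bin_width)
    edges = bin_width * np.arange(int(np.ceil(top / bin_width)) + 2)
    frac = (vals[None, :] >= edges[:, None]).mean(axis=1)
    frac[0] = 1.0  # every voxel receives >= 0 Gy
    return DVHCurve(roi=mask.name, dose_gy=edges, volume_fraction=frac)


def dvh_mean_difference(gt: DVHCurve, test: DVHCurve) -> float:
    """ΔDVHmean (Gy): mean |dose-at-volume difference| over 1%..99% volume."""
    if gt.roi != test.roi:
        raise ValueError(f"DVH curves are for different ROIs: {gt.roi!r} vs {test.roi!r}")
    v = np.arange(1, 100) / 100.0
    return float(np.mean(np.abs(test.dose_at_volume(v) - gt.dose_at_volume(v))))


def dose_error_stats(
    dose_gt: ScalarVolume,
    dose_test: ScalarVolume,
    mask: ROIMask,
    dvh_bin_width: float = 0.02,
) -> DoseErrorStats:
    """Mean/max/DVH dose-error summary for one ROI."""
    if dose_gt.grid != dose_test.grid:
        raise ValueError("doses must share one grid")
    g = dose_gt.values[mask.membership]
    t = dose_test.values[mask.membership]
    mean_gt, mean_test = float(g.mean()), float(t.mean())
    max_gt, max_test = float(g.max()), float(t.max())
    dvh = dvh_mean_difference(
        compute_dvh(dose_gt, mask, dvh_bin_width),
        compute_dvh(dose_test, mask, dvh_bin_width),
    )
    d_mean = mean_test - mean_gt
    d_max = max_test - max_gt
    return DoseErrorStats(
        roi=mask.name,
        d_mean_pct=100.0 * abs(d_mean) / mean_gt if mean_gt > 0 else None,
        d_mean_gy=abs(d_mean),
        d_max_gy=abs(d_max),
        dvh_mean_gy=dvh,
        signed_d_mean_gy=d_mean,
        signed_d_max_gy=d_max,
    )
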