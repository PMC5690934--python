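"""Test-DVF producers: a built-in demons registration and error-injection models.

The benchmark needs displacement fields to score.  Two sources are
provided: a classic multi-resolution demons registration (the algorithm
family behind several clinical systems) and parametric error models that
add controlled misregistration to a ground-truth field, emulating observed
failure modes — a constant bias, spatially correlated noise, and a compact
localized misregistration blob.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

from .grid import ImageGrid, ROIMask, ScalarVolume, VectorField

__all__ = ["DemonsConfig", "ErrorModel", "demons_register", "inject_error"]


@dataclass(frozen=True)
class DemonsConfig:
    """Multi-resolution demons parameters.

    ``smoothing_sigma_mm`` is the Gaussian regularization applied to the
    displacement field after every iteration; ``step_normalization``
    homogenizes the update denominator so single-iteration steps stay below
    half the voxel spacing.
    """

    levels: int = 3
    iterations: tuple[int, ...] = (60, 50, 50)
    smoothing_sigma_mm: float = 2.5
    step_normalization: bool = True

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("need >= 1 pyramid level")
        if self.smoothing_sigma_mm <= 0:
            raise ValueError("smoothing sigma must be positive")
        if len(self.iterations) != self.levels:
            raise ValueError("iterations must list one count per level")


@dataclass(frozen=True)
class ErrorModel:
    """Controlled misregistration added to a ground-truth field.

    Modes: ``bias`` (constant vector of length ``magnitude_mm``),
    ``smooth_noise`` (Gaussian random field with the given correlation
    length, rescaled so the region-mean displacement magnitude equals
    ``magnitude_mm``), and ``local_blob`` (compactly supported bump of peak
    length ``magnitude_mm`` at ``blob_center_mm``).
    """

    mode: str = "bias"
    magnitude_mm: float = 3.0
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    correlation_length_mm: float = 20.0
    blob_center_mm: tuple[float, float, float] | None = None
    blob_radius_mm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("bias", "smooth_noise", "local_blob"):
            raise ValueError(f"unknown error mode {self.mode!r}")
        if self.magnitude_mm < 0:
            raise ValueError("magnitude must be >= 0")
        if self.mode == "local_blob":
            if self.blob_radius_mm <= 0:
                raise ValueError("blob radius must be positive")
            if self.blob_center_mm is None:
                raise ValueError("local_blob requires blob_center_mm")


# ---------------------------------------------------------------------------
# demons


def _downsample(values: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return values
    smoothed = gaussian_filter(values, factor / 2.0)
    # edge-replicating resample keeps the result invariant to intensity offsets
    return zoom(smoothed, 1.0 / factor, order=1, mode="nearest")


def _warp_level(moving: np.ndarray, disp_vox: np.ndarray) -> np.ndarray:
    from scipy.ndimage import map_coordinates

    idx = np.indices(moving.shape, dtype=float)
    coords = idx + np.moveaxis(disp_vox, -1, 0)
    return map_coordinates(moving, coords, order=1, mode="nearest")


def demons_register(
    fixed: ScalarVolume, moving: ScalarVolume, config: DemonsConfig = DemonsConfig()
) -> VectorField:
    """Classic intensity-driven demons registration, coarse to fine.

    Per voxel, each iteration applies the update
    ``du = (m(phi(x)) - f(x)) * grad f / (|grad f|^2 + k * (m(phi(x)) - f(x))^2)``
    followed by Gaussian smoothing of the field.  ``k`` homogenizes units
    (1/mean-spacing^2) when step normalization is on.  No initial rigid
    registration is applied; the output field maps the fixed (SOT) grid
    into the moving (EOT) image, directly comparable to a ground truth.
    """
    if fixed.grid != moving.grid:
        raise ValueError("demons_register expects both volumes on one grid")
    grid = fixed.grid
    sp = np.asarray(grid.spacing)

    disp_mm: np.ndarray | None = None
    for level in range(config.levels):
        factor = 2 ** (config.levels - 1 - level)
        f = _downsample(fixed.values, factor)
        m = _downsample(moving.values, factor)
        lsp = sp * factor
        grads = np.gradient(f, *lsp)
        grad2 = sum(g * g for g in grads)
        k = 1.0 / float(np.mean(lsp) ** 2) if config.step_normalization else 1.0
        sig_vox = config.smoothing_sigma_mm / lsp

        if disp_mm is None:
            disp_mm = np.zeros(f.shape + (3,))
        else:
            scale = np.asarray(f.shape) / np.asarray(disp_mm.shape[:3])
            disp_mm = np.stack(
                [zoom(disp_mm[..., c], scale, order=1, mode='nearest') for c in range(3)], axis=-1
            )

        for _ in range(config.iterations[level]):
            warped = _warp_level(m, disp_mm / lsp)
            diff = warped - f
            denom = grad2 + k * diff * diff
            # descent direction for m(x+u) -> f under the pull-back convention
            with np.errstate(invalid="ignore", divide="ignore"):
                gain = np.where(denom > 1e-9, -diff / denom, 0.0)
            for c in range(3):
                disp_mm[..., c] += gain * grads[c]
                disp_mm[..., c] = gaussian_filter(disp_mm[..., c], sig_vox[c])

    if disp_mm.shape[:3] != grid.shape:
        scale = np.asarray(grid.shape) / np.asarray(disp_mm.shape[:3])
        disp_mm = np.stack(
            [zoom(disp_mm[..., c], scale, order=1, mode='nearest') for c in range(3)], axis=-1
        )
    return VectorField(grid, disp_mm)


# ---------------------------------------------------------------------------
# error injection


def _error_displacements(
    grid: ImageGrid, model: ErrorModel, region: np.ndarray | None
) -> np.ndarray:
    d = np.asarray(model.direction, dtype=float)
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ValueError("direction must be a nonzero vector")
    d = d / nrm

    if model.mode == "bias":
        e = np.empty(grid.shape + (3,))
        e[...] = model.magnitude_mm * d
        return e

    if model.mode == "smooth_noise":
        rng = np.random.default_rng(model.seed)
        sig_vox = [model.correlation_length_mm / s for s in grid.spacing]
        e = np.stack(
            [
                gaussian_filter(rng.standard_normal(grid.shape), sig_vox)
                for _ in range(3)
            ],
            axis=-1,
        )
        mag = np.linalg.norm(e, axis=-1)
        sel = mag if region is None else mag[region]
        mean_mag = float(sel.mean())
        if mean_mag == 0:
            return np.zeros(grid.shape + (3,))
        return e * (model.magnitude_mm / mean_mag)

    # local_blob: Wendland-style bump (1 - r^2)^2, peak at the center
    coords = grid.world_coordinates()
    r = (
        np.linalg.norm(coords - np.asarray(model.blob_center_mm), axis=-1)
        / model.blob_radius_mm
    )
    w = np.where(r < 1.0, (1.0 - r**2) ** 2, 0.0)
    return model.magnitude_mm * w[..., None] * d


def inject_error(
    gt_field: VectorField, model: ErrorModel, region: ROIMask | None = None
) -> VectorField:
    """Return ``gt_field + e`` for the configured error model.

    ``region`` restricts the smooth-noise magnitude normalization (the
    region-mean |e| equals the requested magnitude); it does not mask the
    error itself.  Deterministic given the model seed.
    """
    member = region.membership if region is not None else None
    e = _error_displacements(gt_field.grid, model, member)
    return VectorField(gt_field.grid, gt_field.displacements + e)
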