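"""Head-and-neck virtual phantom synthesis with known ground-truth deformation.

A phantom emulates a paired start-of-treatment (SOT) / end-of-treatment
(EOT) CT study: a CT-like SOT volume with six ROI masks (brainstem, spinal
cord, mandible, both parotids, external body contour), a smooth invertible
SOT-to-EOT deformation composed of anatomically motivated components (rigid
head motion, spine flexion, mandible rotation, parotid shrinkage, weight
loss, and a thin-plate-spline residual), the forward-deformed EOT volume,
and a single-fraction 2 Gy dose distribution on the EOT grid whose gradient
placement relative to a named organ at risk is a controllable knob.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .grid import (
    ImageGrid,
    ROIMask,
    ScalarVolume,
    VectorField,
    compose_fields,
    invert_field,
    jacobian_determinant,
    trilinear_sample,
    warp_volume,
)

__all__ = [
    "AnatomyConfig",
    "DeformationModel",
    "DosePlanSpec",
    "Phantom",
    "PhantomBuildError",
    "build_anatomy",
    "tps_field",
    "build_ground_truth_mapping",
    "synthesize_eot",
    "synthesize_dose",
    "build_phantom",
    "generate_suite",
]

# Tissue attenuation values (HU).
_HU = {
    "air": -1000.0,
    "soft": 45.0,
    "brain": 35.0,
    "brainstem": 25.0,
    "cord": 35.0,
    "parotid": 110.0,
    "bone": 700.0,
    "mandible": 900.0,
}


class PhantomBuildError(RuntimeError):
    """Raised when a generated phantom violates a build invariant."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class AnatomyConfig:
    """Grid and texture parameters of the synthetic anatomy.

    The default 64^3 grid at 3 mm isotropic spacing covers a ~19 cm
    head-and-neck field of view — a scaled-down stand-in for clinical CT
    resolution that keeps every organ several voxels across.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    texture_hu: float = 25.0  # low-frequency intra-tissue texture amplitude
    texture_sigma_mm: float = 9.0
    blur_sigma_mm: float = 4.2  # partial-volume smoothing of tissue boundaries

    def grid(self) -> ImageGrid:
        return ImageGrid(self.shape, self.spacing, self.origin)


@dataclass(frozen=True)
class DeformationModel:
    """Magnitudes of the anatomical-change components of the ground truth.

    Defaults emulate changes over a 6-7 week head-and-neck course: a few
    degrees of head pose change, slight jaw rotation, gradual spine flexion,
    20-30% parotid volume loss, and several millimetres of surface
    regression from weight loss.  All-zero magnitudes give the identity map.
    """

    head_rotation_deg: float = 2.5
    head_rotation_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    head_translation_mm: tuple[float, float, float] = (1.5, -2.0, 1.0)
    mandible_rotation_deg: float = 2.0
    spine_flexion_deg_per_cm: float = 0.20
    parotid_shrinkage: tuple[float, float] = (0.25, 0.25)  # (left, right) volume loss
    parotid_support_mm: float = 28.0
    weight_loss_peak_mm: float = 5.0
    weight_loss_falloff_mm: float = 18.0
    tps_amplitude_mm: float = 1.5
    tps_n_points: int = 6
    head_blend_mm: tuple[float, float] = (70.0, 130.0)  # falloff start/end radii
    mandible_blend_mm: tuple[float, float] = (25.0, 55.0)

    def is_identity(self) -> bool:
        return (
            self.head_rotation_deg == 0
            and all(t == 0 for t in self.head_translation_mm)
            and self.mandible_rotation_deg == 0
            and self.spine_flexion_deg_per_cm == 0
            and all(s == 0 for s in self.parotid_shrinkage)
            and self.weight_loss_peak_mm == 0
            and self.tps_amplitude_mm == 0
        )

    def scaled(self, k: float) -> "DeformationModel":
        return replace(
            self,
            head_rotation_deg=k * self.head_rotation_deg,
            head_translation_mm=tuple(k * t for t in self.head_translation_mm),
            mandible_rotation_deg=k * self.mandible_rotation_deg,
            spine_flexion_deg_per_cm=k * self.spine_flexion_deg_per_cm,
            parotid_shrinkage=tuple(k * s for s in self.parotid_shrinkage),
            weight_loss_peak_mm=k * self.weight_loss_peak_mm,
            tps_amplitude_mm=k * self.tps_amplitude_mm,
        )


@dataclass(frozen=True)
class DosePlanSpec:
    """Synthetic single-fraction plan: ellipsoidal target, Gaussian penumbra.

    ``gradient_margin_mm`` places the 50% isodose surface at the given
    distance from the named OAR — the knob governing how exposed that organ
    is to registration-induced dose error.
    """

    target_center_mm: tuple[float, float, float] | None = None
    target_radii_mm: tuple[float, float, float] = (24.0, 24.0, 30.0)
    prescription_gy: float = 2.0
    penumbra_sigma_mm: float = 6.0
    gradient_margin_mm: float | None = None
    margin_roi: str = "brainstem"

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")
        if self.penumbra_sigma_mm <= 0:
            raise ValueError("penumbra sigma must be positive")


# ---------------------------------------------------------------------------
# anatomy


def _ellipsoid(coords: np.ndarray, center, radii) -> np.ndarray:
    rho = np.zeros(coords.shape[:-1])
    for a in range(3):
        rho += ((coords[..., a] - center[a]) / radii[a]) ** 2
    return rho <= 1.0


def build_anatomy(
    config: AnatomyConfig = AnatomyConfig(), seed: int = 0
) -> tuple[ScalarVolume, dict[str, ROIMask]]:
    """Construct the CT-like SOT volume and its six ROI masks.

    Geometry is parameterized by the grid extent: an ellipsoidal cranium
    with bony shell atop a neck cylinder, brainstem continuing into a spinal
    cord inside a vertebral column, a mandibular arch, and two parotid
    glands lateral to the airway.  Deterministic given (config, seed).
    """
    grid = config.grid()
    coords = grid.world_coordinates()
    ex, ey, ez = grid.extent_mm
    if min(ex, ey, ez) < 120.0:
        raise ValueError("grid too small: need >= 120 mm extent per axis")
    cx = grid.origin[0] + ex / 2
    cy = grid.origin[1] + ey / 2
    z0 = grid.origin[2]

    head_c = (cx, cy, z0 + 0.70 * ez)
    head_r = (0.36 * ex, 0.42 * ey, 0.26 * ez)
    head = _ellipsoid(coords, head_c, head_r)
    neck = (
        (((coords[..., 0] - cx) / (0.24 * ex)) ** 2
         + ((coords[..., 1] - cy) / (0.28 * ey)) ** 2) <= 1.0
    ) & (coords[..., 2] <= head_c[2]) & (coords[..., 2] >= z0 + 0.05 * ez)
    external = head | neck

    cranium = head & ~_ellipsoid(coords, head_c, tuple(0.90 * r for r in head_r))

    bs_c = (cx, cy + 0.10 * ey, z0 + 0.66 * ez)
    brainstem = _ellipsoid(coords, bs_c, (9.0, 9.0, 0.09 * ez))

    cord_y = cy + 0.10 * ey
    cord = (
        (((coords[..., 0] - cx) ** 2 + (coords[..., 1] - cord_y) ** 2) <= 6.0**2)
        & (coords[..., 2] >= z0 + 0.06 * ez)
        & (coords[..., 2] <= z0 + 0.54 * ez)
    )
    r_sp = np.sqrt((coords[..., 0] - cx) ** 2 + (coords[..., 1] - cord_y) ** 2)
    vertebra = (
        (r_sp >= 9.0) & (r_sp <= 16.0)
        & (coords[..., 2] >= z0 + 0.07 * ez)
        & (coords[..., 2] <= z0 + 0.56 * ez)
    )

    # mandibular arch: anterior half-torus
    mand_c = (cx, cy - 0.06 * ey, z0 + 0.50 * ez)
    arch_r, tube_r = 0.17 * min(ex, ey), 6.0
    r_ax = np.sqrt((coords[..., 0] - mand_c[0]) ** 2 + (coords[..., 1] - mand_c[1]) ** 2)
    mandible = (
        (np.sqrt((r_ax - arch_r) ** 2 + (coords[..., 2] - mand_c[2]) ** 2) <= tube_r)
        & (coords[..., 1] <= mand_c[1] + 0.35 * arch_r)
    )

    par_dx, par_y, par_z = 0.26 * ex, cy + 0.02 * ey, z0 + 0.56 * ez
    parotid_l = _ellipsoid(coords, (cx - par_dx, par_y, par_z), (11.0, 15.0, 19.0))
    parotid_r = _ellipsoid(coords, (cx + par_dx, par_y, par_z), (11.0, 15.0, 19.0))
    # the gland wraps the ramus; keep bone out of the gland masks
    parotid_l &= ~mandible
    parotid_r &= ~mandible

    for organ in (brainstem, cord, mandible, parotid_l, parotid_r):
        organ &= external

    hu = np.full(grid.shape, _HU["air"])
    hu[external] = _HU["soft"]
    hu[head & ~cranium] = _HU["brain"]
    hu[cranium] = _HU["bone"]
    hu[vertebra & external] = _HU["bone"]
    hu[mandible] = _HU["mandible"]
    hu[brainstem] = _HU["brainstem"]
    hu[cord] = _HU["cord"]
    hu[parotid_l | parotid_r] = _HU["parotid"]

    rng = np.random.default_rng(seed)
    sig_vox = [config.texture_sigma_mm / s for s in grid.spacing]
    texture = gaussian_filter(rng.standard_normal(grid.shape), sig_vox)
    texture *= config.texture_hu / max(texture.std(), 1e-12)
    hu[external] += texture[external]

    hu = gaussian_filter(hu, [config.blur_sigma_mm / s for s in grid.spacing])

    masks = {
        "brainstem": ROIMask(grid, "brainstem", brainstem),
        "cord": ROIMask(grid, "cord", cord),
        "mandible": ROIMask(grid, "mandible", mandible),
        "parotid_l": ROIMask(grid, "parotid_l", parotid_l),
        "parotid_r": ROIMask(grid, "parotid_r", parotid_r),
        "external": ROIMask(grid, "external", external),
    }
    return ScalarVolume(grid, hu), masks


# ---------------------------------------------------------------------------
# thin-plate splines


def tps_field(
    control_points: np.ndarray, displacements: np.ndarray, grid: ImageGrid
) -> VectorField:
    """3-D thin-plate-spline interpolant of control-point displacements.

    Kernel phi(r) = r plus a full affine term, fitted per component by the
    standard TPS linear system; exact at the control points.
    """
    pts = np.asarray(control_points, dtype=float)
    disp = np.asarray(displacements, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape != disp.shape:
        raise ValueError("control points and displacements must be (n, 3)")
    if pts.shape[0] < 4:
        raise ValueError("need >= 4 control points")
    if np.linalg.matrix_rank(np.c_[pts, np.ones(len(pts))]) < 4:
        raise ValueError("control points are coplanar")
    uniq = np.unique(pts, axis=0)
    if len(uniq) < len(pts):
        raise ValueError("duplicate control points make the TPS system singular")
    interp = RBFInterpolator(pts, disp, kernel="linear", degree=1)
    x = grid.world_coordinates().reshape(-1, 3)
    return VectorField(grid, interp(x).reshape(grid.shape + (3,)))


# ---------------------------------------------------------------------------
# deformation components


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _blend_weight(coords: np.ndarray, center, r_in: float, r_out: float) -> np.ndarray:
    """C1 radial weight: 1 inside r_in, 0 beyond r_out."""
    d = np.linalg.norm(coords - np.asarray(center), axis=-1)
    return 1.0 - _smoothstep((d - r_in) / max(r_out - r_in, 1e-9))


def _rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def _blended_rigid(
    grid: ImageGrid, coords, axis, angle_deg, center, translation, r_in, r_out
) -> VectorField:
    R = _rotation_matrix(axis, angle_deg)
    c = np.asarray(center)
    t = np.asarray(translation, dtype=float)
    x = coords.reshape(-1, 3)
    u = (x - c) @ R.T + c + t - x
    w = _blend_weight(coords, center, r_in, r_out).reshape(-1, 1)
    return VectorField(grid, (w * u).reshape(grid.shape + (3,)))


def _spine_flexion_field(grid, coords, masks, deg_per_cm: float) -> VectorField:
    """Progressive sagittal bend about a left-right axis on the spine.

    The bending angle grows linearly with superior distance above a pivot
    near the neck base, so inferior anatomy stays put.
    """
    ext = masks["external"].membership
    cord = masks["cord"].membership
    xs = grid.world_coordinates()  # == coords
    pivot_z = xs[..., 2][cord].min()
    pivot_y = xs[..., 1][cord].mean()
    dz = np.maximum(coords[..., 2] - pivot_z, 0.0)
    angle = np.deg2rad(deg_per_cm) * dz / 10.0
    y = coords[..., 1] - pivot_y
    z = coords[..., 2] - pivot_z
    u = np.zeros(grid.shape + (3,))
    cosa, sina = np.cos(angle), np.sin(angle)
    u[..., 1] = cosa * y - sina * z - y
    u[..., 2] = sina * y + cosa * z - z
    del ext
    return VectorField(grid, u)


def _parotid_shrink_field(
    grid, coords, mask: ROIMask, volume_loss: float, support_mm: float
) -> VectorField:
    """Radially inward contraction with Gaussian envelope, amplitude
    calibrated so the forward-warped parotid loses the requested volume
    fraction (mean Jacobian determinant over the mask = 1 - loss)."""
    if volume_loss <= 0:
        return VectorField.zero(grid)
    if not 0 < volume_loss < 0.6:
        raise ValueError("parotid volume loss must lie in (0, 0.6)")
    xs = coords.reshape(-1, 3)
    c = coords[mask.membership].mean(axis=0)
    r2 = np.sum((xs - c) ** 2, axis=1)
    env = np.exp(-r2 / (2.0 * support_mm**2))
    unit = (c - xs) * env[:, None]  # inward, mm-scaled by distance

    def mean_jac(amp: float) -> float:
        f = VectorField(grid, (amp * unit).reshape(grid.shape + (3,)))
        return float(jacobian_determinant(f).values[mask.membership].mean())

    target = 1.0 - volume_loss
    lo, hi = 0.0, 1.0 - (1.0 - volume_loss) ** (1.0 / 3.0) + 0.2
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if mean_jac(mid) > target:
            lo = mid
        else:
            hi = mid
    amp = 0.5 * (lo + hi)
    return VectorField(grid, (amp * unit).reshape(grid.shape + (3,)))


def _weight_loss_field(
    grid, coords, masks, peak_mm: float, falloff_mm: float
) -> VectorField:
    """Inward surface-normal displacement decaying with depth below the skin."""
    if peak_mm == 0:
        return VectorField.zero(grid)
    ext = masks["external"].membership
    sp = grid.spacing
    d_in = distance_transform_edt(ext, sampling=sp)
    d_out = distance_transform_edt(~ext, sampling=sp)
    d_signed = d_in - d_out  # > 0 inside, grows toward the interior
    env = peak_mm * np.exp(-np.abs(d_signed) / falloff_mm)
    # inward normal = gradient of the signed depth, smoothed for C1 continuity
    n = np.stack(np.gradient(gaussian_filter(d_signed, 1.5), *sp), axis=-1)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    n = n / np.maximum(norm, 1e-9)
    u = env[..., None] * n
    for c in range(3):
        u[..., c] = gaussian_filter(u[..., c], [1.0] * 3)
    return VectorField(grid, u)


def build_ground_truth_mapping(
    model: DeformationModel,
    masks: dict[str, ROIMask],
    grid: ImageGrid,
    seed: int = 0,
) -> VectorField:
    """Compose the analytic deformation components into the SOT-to-EOT field.

    Fixed composition order (outermost first): rigid head -> spine flexion
    -> mandible rotation -> parotid shrinkage -> weight loss -> TPS
    residual.  Raises :class:`PhantomBuildError` naming the offending
    component if any single component, or the composition, folds space
    (Jacobian determinant <= 0).
    """
    coords = grid.world_coordinates()
    ext = masks["external"].membership
    head_center = coords[masks["brainstem"].membership].mean(axis=0) + np.array(
        [0.0, 0.0, 25.0]
    )
    mand_pts = coords[masks["mandible"].membership]
    condyle = np.array(
        [mand_pts[:, 0].mean(), mand_pts[:, 1].max(), mand_pts[:, 2].max()]
    )

    components: list[tuple[str, VectorField]] = []
    components.append((
        "head_rigid",
        _blended_rigid(
            grid, coords, model.head_rotation_axis, model.head_rotation_deg,
            head_center, model.head_translation_mm, *model.head_blend_mm,
        ),
    ))
    components.append((
        "spine_flexion",
        _spine_flexion_field(grid, coords, masks, model.spine_flexion_deg_per_cm),
    ))
    components.append((
        "mandible_rotation",
        _blended_rigid(
            grid, coords, (1.0, 0.0, 0.0), model.mandible_rotation_deg,
            condyle, (0.0, 0.0, 0.0), *model.mandible_blend_mm,
        ),
    ))
    par = VectorField.zero(grid)
    for side, loss in zip(("parotid_l", "parotid_r"), model.parotid_shrinkage):
        f = _parotid_shrink_field(grid, coords, masks[side], loss, model.parotid_support_mm)
        par = VectorField(grid, par.displacements + f.displacements)
    components.append(("parotid_shrinkage", par))
    components.append((
        "weight_loss",
        _weight_loss_field(
            grid, coords, masks, model.weight_loss_peak_mm, model.weight_loss_falloff_mm
        ),
    ))

    if model.tps_amplitude_mm > 0 and model.tps_n_points >= 4:
        rng = np.random.default_rng(seed)
        body_pts = coords[ext]
        picks = body_pts[rng.choice(len(body_pts), model.tps_n_points, replace=False)]
        disp = rng.normal(0.0, model.tps_amplitude_mm / 2.0, size=picks.shape)
        components.append(("tps_residual", tps_field(picks, disp, grid)))
    else:
        components.append(("tps_residual", VectorField.zero(grid)))

    for name, f in components:
        if float(jacobian_determinant(f).values.min()) <= 0:
            raise PhantomBuildError(f"component {name!r} is not invertible")

    total = components[-1][1]  # innermost
    for name, f in reversed(components[:-1]):
        total = compose_fields(f, total)
    if float(jacobian_determinant(total).values.min()) <= 0:
        raise PhantomBuildError("composed ground-truth field is not invertible")
    return total


# ---------------------------------------------------------------------------
# EOT image and dose


def synthesize_eot(
    sot: ScalarVolume, gt_field: VectorField, noise_sd: float = 4.0, seed: int = 0
) -> ScalarVolume:
    """Forward-deform the SOT through the ground truth to the EOT anatomy.

    ``EOT(y) = SOT(y + v(y))`` with ``v`` the inverse of the forward field,
    plus independent Gaussian HU noise.
    """
    inverse = invert_field(gt_field)
    eot = warp_volume(sot, inverse, fill=float(sot.values.min()))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eot = ScalarVolume(
            eot.grid, eot.values + rng.normal(0.0, noise_sd, size=eot.values.shape)
        )
    return eot


def _signed_target_distance(coords: np.ndarray, center, radii) -> np.ndarray:
    rho = np.zeros(coords.shape[:-1])
    for a in range(3):
        rho += ((coords[..., a] - center[a]) / radii[a]) ** 2
    rho = np.sqrt(rho)
    r_eff = float(np.exp(np.mean(np.log(radii))))  # geometric mean radius
    return (rho - 1.0) * r_eff


def synthesize_dose(
    spec: DosePlanSpec, grid: ImageGrid, masks: dict[str, ROIMask]
) -> ScalarVolume:
    """Deterministic synthetic plan: full prescription inside an ellipsoidal
    target, Gaussian-tail penumbra outside.

    When ``gradient_margin_mm`` is set, the target center is rigidly offset
    along the target-to-OAR axis until the 50% isodose surface sits that
    many mm from the named OAR.
    """
    coords = grid.world_coordinates()
    center = np.asarray(
        spec.target_center_mm
        if spec.target_center_mm is not None
        else coords[masks["external"].membership].mean(axis=0)
    , dtype=float)
    radii = spec.target_radii_mm
    sigma = spec.penumbra_sigma_mm
    d50 = sigma * np.sqrt(2.0 * np.log(2.0))  # falloff distance of the 50% isodose

    if spec.gradient_margin_mm is not None:
        oar_pts = coords[masks[spec.margin_roi].membership]
        axis = center - oar_pts.mean(axis=0)
        nrm = np.linalg.norm(axis)
        axis = axis / nrm if nrm > 0 else np.array([0.0, 1.0, 0.0])

        def oar_clearance(shift: float) -> float:
            c = center + shift * axis
            return float(
                _signed_target_distance(oar_pts, c, radii).min() - d50
            )

        lo, hi = -nrm, float(max(grid.extent_mm))
        want = spec.gradient_margin_mm
        if not oar_clearance(lo) < want < oar_clearance(hi):
            raise ValueError(
                f"gradient margin {want} mm for {spec.margin_roi!r} is not "
                "achievable inside the grid"
            )
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if oar_clearance(mid) < want:
                lo = mid
            else:
                hi = mid
        center = center + 0.5 * (lo + hi) * axis
        in_grid = (center >= grid.index_to_world([0, 0, 0])) & (
            center <= grid.index_to_world(np.asarray(grid.shape) - 1)
        )
        if not in_grid.all():
            raise ValueError("requested margin pushes the target outside the grid")

    d = _signed_target_distance(coords, center, radii)
    dose = np.where(d <= 0, 1.0, np.exp(-(d**2) / (2.0 * sigma**2)))
    return ScalarVolume(grid, spec.prescription_gy * dose)


# ---------------------------------------------------------------------------
# full phantom


@dataclass
class Phantom:
    """One SOT/EOT pair with ground truth, masks, and EOT dose."""

    sot: ScalarVolume
    eot: ScalarVolume
    gt_field: VectorField
    masks: dict[str, ROIMask]
    eot_dose: ScalarVolume
    model: DeformationModel
    seed: int
    roundtrip_nrmse: float = dc_field(default=float("nan"))

    @property
    def grid(self) -> ImageGrid:
        return self.sot.grid


def _roundtrip_nrmse(phantom_sot, eot, gt_field, external) -> float:
    back = warp_volume(eot, gt_field, fill=float(eot.values.min()))
    m = external.membership
    err = back.values[m] - phantom_sot.values[m]
    span = phantom_sot.values[m].max() - phantom_sot.values[m].min()
    return float(np.sqrt(np.mean(err**2)) / span)


def build_phantom(
    anatomy: AnatomyConfig = AnatomyConfig(),
    model: DeformationModel = DeformationModel(),
    plan: DosePlanSpec = DosePlanSpec(),
    seed: int = 0,
    noise_sd: float = 4.0,
    build_tolerance: float = 0.02,
) -> Phantom:
    """Generate a complete virtual phantom; pure function of (config, seed).

    Verifies the round-trip invariant that warping the EOT back through the
    ground-truth field reproduces the SOT with normalized RMS intensity
    error below ``build_tolerance`` inside the body contour.
    """
    sot, masks = build_anatomy(anatomy, seed)
    gt = build_ground_truth_mapping(model, masks, sot.grid, seed)
    eot = synthesize_eot(sot, gt, noise_sd=noise_sd, seed=seed + 1)
    dose = synthesize_dose(plan, sot.grid, masks)
    nrmse = _roundtrip_nrmse(sot, eot, gt, masks["external"])
    if nrmse >= build_tolerance:
        raise PhantomBuildError(
            f"round-trip NRMSE {nrmse:.4f} exceeds build tolerance {build_tolerance}"
        )
    return Phantom(sot, eot, gt, masks, dose, model, seed, roundtrip_nrmse=nrmse)


def generate_suite(
    n: int = 10,
    anatomy: AnatomyConfig = AnatomyConfig(),
    model: DeformationModel = DeformationModel(),
    plan: DosePlanSpec = DosePlanSpec(),
    seed: int = 0,
    magnitude_jitter: float = 0.3,
) -> list[Phantom]:
    """Generate a study-shaped suite of phantoms with varied change magnitudes.

    Each phantom scales the base deformation magnitudes by a factor drawn
    uniformly from ``1 +/- magnitude_jitter``, emulating inter-patient
    variation in anatomical change.
    """
    rng = np.random.default_rng(seed)
    phantoms = []
    for i in range(n):
        k = float(rng.uniform(1.0 - magnitude_jitter, 1.0 + magnitude_jitter))
        phantoms.append(
            build_phantom(anatomy, model.scaled(k), plan, seed=int(seed + 1000 * (i + 1)))
        )
    return phantoms
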