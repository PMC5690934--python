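# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind `dirqa`. It is written for users who need to judge what
a passing benchmark does — and does not — say about a clinical DIR system.

## Coordinate and field conventions

All geometry is in mm on axis-aligned regular grids with 0-based voxel
indices and the voxel-*center* convention: `world(i) = origin + i·spacing`.
A displacement field `u` lives on the target (SOT) grid and maps target
world points into source (EOT) space, `φ(x) = x + u(x)`; the zero field is
the identity. Dose defined on the EOT grid is pulled back to the SOT
anatomy by `D_sot(x) = D_eot(φ(x))` — the adaptive-radiotherapy direction,
where daily dose is evaluated on the planning CT. Fields serialized to
NIfTI/MetaImage carry a `dvf_convention` header tag; a field declared in
the opposite (`source_to_target`) convention is inverted on load.

Sampling is trilinear throughout. Points outside the hull of voxel centers
receive a declared fill value (the volume minimum for CT-like images, 0 for
dose) and are flagged, never extrapolated: extrapolated HU or dose has no
physical meaning. Displacement fields are edge-clamped when sampled during
composition and inversion, which keeps the fixed-point iteration stable
near borders.

Field inversion uses the fixed-point iteration `v_{k+1}(y) = −u(y + v_k(y))`
with tolerance 0.01 mm and at most 50 iterations; it converges rapidly for
the small-deformation, Jacobian-positive fields generated here (the
measured forward∘inverse residual on a default phantom is < 0.005 mm).
Jacobian determinants use central differences in physical coordinates,
one-sided at borders.

## The virtual phantom

The anatomy is a parametric head-and-neck section on a 64³ grid at 3 mm
isotropic spacing (≈19 cm field of view): an ellipsoidal cranium with a
bony shell atop a neck cylinder, a brainstem continuing into a spinal cord
inside a vertebral column, a mandibular arch, and two parotid glands. The
body floats fully inside the grid so that no deformation maps tissue
outside the image hull. Tissue HU values are piecewise constant
(air −1000, soft tissue ≈45, parotid 110, bone 700–900) plus a smooth
intra-tissue texture (25 HU, 9 mm correlation length) that gives
intensity-driven registration information inside otherwise flat regions.
The volume is smoothed with a 4.2 mm Gaussian as a stand-in for partial
volume and reconstruction-kernel blur; this value keeps the round-trip
build invariant (below) satisfied with margin while preserving boundary
gradients. The 64³/3 mm resolution is a deliberately scaled-down stand-in
for clinical CT that keeps every organ several voxels across; all
statistics are resolution-consistent rather than resolution-matched to any
clinical protocol.

The ground-truth SOT→EOT field composes analytic components in a fixed
order (outermost first): rigid head rotation+translation → spine flexion →
mandible rotation → parotid shrinkage → weight loss → thin-plate-spline
residual. Rigid components are blended to identity with a C¹ radial
smoothstep so the global field stays invertible. Spine flexion bends the
anatomy about a left-right axis with angle growing linearly with superior
distance above a pivot at the neck base. Parotid shrinkage is a radially
inward field with Gaussian envelope whose amplitude is calibrated (by
bisection on the mean Jacobian determinant over the gland) so the
forward-warped gland loses exactly the requested volume fraction. Weight
loss displaces the body surface inward along the smoothed signed-distance
normal, decaying exponentially with depth (default peak 5 mm, falloff
18 mm). The TPS residual (kernel |r| plus affine term, solved per
component) adds seeded, small (≈1.5 mm) soft-tissue irregularity; localized
changes such as shoulder or hyoid shifts and nodal shrinkage can be
expressed through the same TPS mechanism with user control points rather
than dedicated components, since the repository's purpose is evaluation,
not anatomical fidelity. Default magnitudes (2.5° head rotation, ~2 mm
translation, 2° mandible rotation, 0.2°/cm flexion, 25% parotid volume
loss) emulate the anatomical change reported over a 6–7 week head-and-neck
course; a suite generator scales them ±30% per phantom to emulate
inter-patient variation.

Every component, and the composition, must have a strictly positive
Jacobian determinant; violations name the offending component and abort
the build. The EOT image is the SOT pulled through the *inverse* of the
ground truth plus Gaussian HU noise (default SD 4). A build invariant is
enforced at construction: warping the EOT back through the ground truth
must reproduce the SOT with normalized RMS intensity error below 2% of the
intensity range inside the body (measured ≈1.5%).

The synthetic plan is an ellipsoidal target at full prescription (2 Gy,
one fraction) with a Gaussian-tail penumbra (default σ = 6 mm). The
`gradient_margin_mm` knob rigidly offsets the target along the
target-to-OAR axis (by bisection on the OAR's clearance) until the 50%
isodose sits the requested distance from a named OAR. The default suite
plan places the target anterior-superior so the 50% isodose lies 2 mm from
the brainstem while the cord — inferior, behind its planning margin —
receives essentially no dose: the geometry that drives the contrasting
dose-error sensitivity of the two organs.

## Test-field sources

The built-in registration is classic intensity-driven demons: per voxel
`du = −(m(φ(x)) − f(x))·∇f / (|∇f|² + k·(m(φ(x)) − f(x))²)` with the
fixed-image gradient, Gaussian field regularization (σ = 2.5 mm) after
every iteration, and a 3-level coarse-to-fine pyramid (60/50/50
iterations). `k = 1/mean-spacing²` homogenizes units and bounds single
steps near half a voxel. The update uses only intensity differences and
gradients, so the result is exactly invariant to a global intensity offset.
No initial rigid registration is applied. Like any gradient-driven method
it under-recovers motion where the aperture problem leaves components
unconstrained (e.g. tangential motion of a smooth boundary); the shipped
configuration recovers a known 2 mm translation of a textured object to
within ~20%.

Error-injection models add controlled misregistration `e` to the ground
truth: `bias` (a constant vector — the analogue of a systematic shift),
`smooth_noise` (a seeded Gaussian random field with a given correlation
length, rescaled so the region-mean |e| equals the requested magnitude
exactly), and `local_blob` (a compactly supported `(1−r²)²` bump of given
peak and radius — the analogue of a localized gross failure confined to
one organ). Because `e` is added to the truth, every scored TRE is known
by construction, which is what makes the evaluation stack testable
end-to-end.

## Scoring

TRE is evaluated on the SOT grid at the voxels of SOT-defined masks.
Within-ROI summaries use the population SD (the ROI is the full
population of scored voxels). The TG-132 goal is `frac(TRE ≤ 2 mm) ≥ 95%`.
The failure rule pools all TREμ entries for one ROI across phantoms and
registration sources, computes their mean and population SD, and flags
entries at or above mean + 2·SD; a zero pooled SD flags nothing. The
boundary is inclusive so that an entry sitting exactly two SDs out — the
canonical single-outlier configuration — counts as a failure.

DVHs are cumulative (fraction of ROI volume receiving ≥ d) at 0.02 Gy
bins. ΔDVHmean is computed on the volume axis: both curves are inverted to
dose-at-volume `D(v)` by linear interpolation and the mean |difference|
taken over v = 1…99% in 1% steps, reported in Gy. Dose-error statistics
report magnitudes (|Δ mean dose| in Gy and in % of the ground-truth mean,
|Δ max dose|, ΔDVHmean) with signed versions retained, because the
direction of error relative to the dose gradient determines whether an
organ's DVH shifts hot or cold. Percent mean-dose error is normalized by
the ground-truth mean (undefined and reported missing when that mean is
zero).

Correlation tables pool all (phantom × source) records per ROI and report
Pearson r for five pairings (TREμ against Δmean%, ΔmeanGy, ΔDVHmean,
ΔmaxGy; TREmax against ΔmaxGy). Verbal strength labels use |r| thresholds
0.2/0.4/0.6/0.8 (very weak → very strong). Between-source comparison is a
paired two-sided t-test on per-phantom TREμ with df = n−1; zero-variance
differences are reported as degenerate rather than given a fabricated p.

## What the synthetic data does and does not show

The generator reproduces the *structure* of a DIR commissioning study —
paired CTs with known truth, organ-wise statistics, dose propagation
through competing fields — under fully controlled conditions. It does not
model sliding interfaces, appearing/disappearing cavities, CT artifacts,
couch/immobilization differences, or biomechanically constrained tissue,
and its demons registration is a reference implementation, not a model of
any vendor's algorithm. Passing benchmarks here validates the evaluation
machinery and exposes the TRE-dose interplay mechanisms; it does not
certify any particular clinical system, whose error modes must be measured
on the real phantom datasets this pipeline is designed to score.

## Problem sizes

Defaults were chosen so a full benchmark is interactive on one CPU: 64³
phantoms (~6 s each to build), demons registration ~2 s, and the 3-phantom
× 4-source correlation suite ~20 s. Larger grids need only configuration
changes; every algorithm is resolution-independent.
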