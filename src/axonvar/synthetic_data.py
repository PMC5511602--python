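"""Synthetic inputs for the whole pipeline.

Real studies of fiber-geometry variability start from cohort diffusion MRI
and a finite-element head mesh; at desk scale both are replaced by
constructions with known ground truth:

* tensor phantoms — curved single-fiber bundles (straight, circular arc,
  u-shaped callosal-like, inclined helical/corticospinal-like) embedded in
  a regular grid, with prescribed FA inside and outside the bundle;
* simulated diffusion-weighted signals S = S0 exp(-b g^T D g) with
  optional Rician magnitude noise;
* subject populations with controlled angular and FA dispersion (each
  subject is the base phantom rigidly rotated and FA-perturbed, with the
  draws recorded for recovery tests);
* axis-aligned toy hexahedral meshes;
* prescribed deformation-gradient histories (uniaxial isochoric stretch,
  simple shear, rigid rotation, volumetric expansion) ramping linearly
  from the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .fe_coupling import HexMesh
from .tensor_fit import GradientTable, TensorVolume


@dataclass
class PhantomSpec:
    """Geometry and diffusion properties of a single-bundle phantom.

    ``radius`` is the centerline bend radius (arc/u_shape/helix),
    ``extent`` the bundle arc length in mm, ``inclination`` the out-of-plane
    pitch in degrees (straight/helix). ``mean_diffusivity`` defaults to a
    white-matter-like 0.7e-3 mm^2/s.
    """

    bundle_kind: str = "straight"
    radius: float = 20.0
    extent: float = 40.0
    inclination: float = 0.0
    bundle_radius: float = 4.0
    fa_inside: float = 0.6
    fa_outside: float = 0.0
    mean_diffusivity: float = 0.7e-3
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 1.0
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.fa_inside <= 1.0 and 0.0 <= self.fa_outside <= 1.0):
            raise ValueError("FA values must lie in [0, 1]")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.bundle_kind not in {"straight", "arc", "u_shape", "helix"}:
            raise ValueError(f"unknown bundle_kind {self.bundle_kind!r}")
        if self.affine is None:
            # grid centered on the world origin
            shape = np.asarray(self.grid_shape, dtype=float)
            aff = np.eye(4)
            aff[:3, :3] *= self.voxel_size
            aff[:3, 3] = -(shape - 1) / 2.0 * self.voxel_size
            self.affine = aff


@dataclass
class PopulationSpec:
    """Controlled inter-subject variability of a phantom cohort."""

    n_subjects: int = 485
    angle_sd: float = 0.0  # degrees, rigid tilt of the bundle orientation
    fa_sd: float = 0.0
    length_sd: float = 0.0  # mm, perturbation of the bundle extent
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if min(self.angle_sd, self.fa_sd, self.length_sd) < 0:
            raise ValueError("dispersion SDs must be non-negative")


def prolate_eigenvalues(fa: float, md: float) -> tuple[float, float, float]:
    """Closed-form prolate (l2 = l3) eigenvalues with given FA and trace/3.

    l1 = md (1 + 2 d), l2 = l3 = md (1 - d) with d = fa / sqrt(3 - 2 fa^2)
    inverts the FA definition uniquely for fa in [0, 1].
    """
    if not 0.0 <= fa <= 1.0:
        raise ValueError("FA must lie in [0, 1]")
    d = fa / np.sqrt(3.0 - 2.0 * fa**2)
    return md * (1.0 + 2.0 * d), md * (1.0 - d), md * (1.0 - d)


def _prolate_tensor(direction: np.ndarray, fa: float, md: float) -> np.ndarray:
    l1, l2, _ = prolate_eigenvalues(fa, md)
    t = direction / np.linalg.norm(direction)
    return l2 * np.eye(3) + (l1 - l2) * np.outer(t, t)


def centerline(spec: PhantomSpec, n_samples: int = 400) -> tuple[np.ndarray, np.ndarray]:
    """Analytic centerline points and unit tangents (world mm, unrotated).

    Arc-length parameterized over ``spec.extent``; the curve is centered on
    the world origin.
    """
    s = np.linspace(-spec.extent / 2.0, spec.extent / 2.0, n_samples)
    alpha = np.radians(spec.inclination)
    if spec.bundle_kind == "straight":
        d = np.array([np.sin(alpha), 0.0, np.cos(alpha)])
        pts = s[:, None] * d
        tans = np.tile(d, (n_samples, 1))
    elif spec.bundle_kind == "arc":
        R = spec.radius
        phi = s / R
        pts = np.stack([R * np.sin(phi), R * np.cos(phi) - R, np.zeros_like(phi)], axis=1)
        tans = np.stack([np.cos(phi), -np.sin(phi), np.zeros_like(phi)], axis=1)
    elif spec.bundle_kind == "u_shape":
        # half-turn in the transverse (x-y) plane, opening toward -y
        R = spec.radius
        phi = s / R  # in [-pi/2, pi/2] when extent = pi R
        pts = np.stack(
            [R * np.sin(phi), R * np.cos(phi) - R / 2.0, np.zeros_like(phi)], axis=1
        )
        tans = np.stack([np.cos(phi), -np.sin(phi), np.zeros_like(phi)], axis=1)
    else:  # helix
        R = spec.radius
        ca, sa = np.cos(alpha), np.sin(alpha)
        psi = s * ca / R
        pts = np.stack([R * np.cos(psi) - R, R * np.sin(psi), s * sa], axis=1)
        tans = np.stack([-np.sin(psi) * ca, np.cos(psi) * ca, np.full_like(psi, sa)], axis=1)
    return pts, tans


def make_phantom(
    spec: PhantomSpec,
    seed: int = 0,
    rotation: np.ndarray | None = None,
) -> tuple[TensorVolume, dict]:
    """Build a tensor phantom with a known bundle geometry.

    Every in-bundle voxel (within ``bundle_radius`` of the centerline)
    holds a cylindrically symmetric tensor whose principal eigenvector is
    the local centerline tangent and whose FA is ``fa_inside``;
    out-of-bundle voxels hold a z-oriented prolate tensor with
    ``fa_outside`` (isotropic when 0). The trace is 3 x mean_diffusivity
    everywhere. ``rotation`` rigidly rotates the bundle about the origin.

    The construction is deterministic; ``seed`` is accepted for interface
    uniformity. Returns the volume and a ground-truth dict (centerline,
    tangents, in-bundle mask, degenerate flag for fa_inside = 0).
    """
    del seed
    pts, tans = centerline(spec)
    if rotation is not None:
        rotation = np.asarray(rotation, dtype=float)
        pts = pts @ rotation.T
        tans = tans @ rotation.T

    shape = spec.grid_shape
    ijk = np.indices(shape).reshape(3, -1).T.astype(float)
    centers = ijk @ spec.affine[:3, :3].T + spec.affine[:3, 3]

    lo = centers.min(axis=0) - spec.voxel_size / 2.0
    hi = centers.max(axis=0) + spec.voxel_size / 2.0
    if np.any(pts < lo) or np.any(pts > hi):
        raise ValueError("grid too small to contain the bundle centerline")

    # nearest centerline sample per voxel center
    dist, nearest = cKDTree(pts).query(centers, k=1)
    # open-ended tube: require the nearest-point foot to fall on the curve
    # interior, so no spherical caps extend the bundle beyond its ends
    interior = (nearest > 0) & (nearest < len(pts) - 1)
    in_bundle = (dist <= spec.bundle_radius) & interior

    md = spec.mean_diffusivity
    l1, l2, _ = prolate_eigenvalues(spec.fa_inside, md)
    t = tans[nearest[in_bundle]]
    D_flat = np.empty((len(centers), 3, 3))
    D_flat[in_bundle] = l2 * np.eye(3) + (l1 - l2) * np.einsum("ni,nj->nij", t, t)
    D_flat[~in_bundle] = _prolate_tensor(np.array([0.0, 0.0, 1.0]), spec.fa_outside, md)

    D = D_flat.reshape(shape + (3, 3))
    vol = TensorVolume(D=D, affine=spec.affine, mask=np.ones(shape, dtype=bool))
    gt = {
        "centerline": pts,
        "tangents": tans,
        "in_bundle": in_bundle.reshape(shape),
        "fa_inside": spec.fa_inside,
        "degenerate": spec.fa_inside == 0.0,
        "base_direction": tans[len(tans) // 2].copy(),
    }
    return vol, gt


def simulate_dwi(
    tensors: TensorVolume,
    gt: GradientTable,
    s0: float = 1000.0,
    rician_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Mono-exponential DWI signals S = S0 exp(-b g^T D g), Rician-noised.

    Rician noise is the magnitude of the complex signal with independent
    N(0, sigma^2) perturbations on both channels: |S + n1 + i n2|.
    Deterministic under a fixed seed.
    """
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    if rician_sigma < 0:
        raise ValueError("rician_sigma must be non-negative")
    bg = gt.bvals[:, None] * gt.bvecs  # (n, 3) scaled directions
    exponent = np.einsum("xyzij,ni,nj->xyzn", tensors.D, bg, gt.bvecs)
    signal = s0 * np.exp(-exponent)
    if rician_sigma > 0:
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, rician_sigma, signal.shape)
        n2 = rng.normal(0.0, rician_sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)
    return signal


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    a = axis / np.linalg.norm(axis)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


@dataclass
class SubjectPhantom:
    """One cohort member: a perturbed spec plus the recorded ground truth.

    ``rotation_axis`` is perpendicular to the base bundle direction, so the
    angle between the rotated and base fiber direction equals the drawn
    ``rotation_angle_deg`` exactly.
    """

    subject_id: int
    spec: PhantomSpec
    rotation: np.ndarray
    rotation_axis: np.ndarray
    rotation_angle_deg: float
    fa_inside: float
    extent: float
    base_direction: np.ndarray

    def build(self) -> tuple[TensorVolume, dict]:
        return make_phantom(self.spec, rotation=self.rotation)


def make_population(spec: PhantomSpec, pop: PopulationSpec) -> list[SubjectPhantom]:
    """Cohort of rigidly rotated, FA-perturbed copies of a base phantom.

    Subject i draws a signed tilt angle ~ N(0, angle_sd) about a random
    axis perpendicular to the base fiber direction, an in-bundle FA
    ~ N(fa_inside, fa_sd) (clipped to [0, 0.99]) and a bundle extent
    ~ N(extent, length_sd). Each subject's random stream is derived from
    (seed, subject_id), so any subject is reproducible in isolation.
    Volumes are built on demand via :meth:`SubjectPhantom.build`.
    """
    _, tans = centerline(spec, n_samples=3)
    base_dir = tans[1] / np.linalg.norm(tans[1])
    subjects = []
    for i in range(pop.n_subjects):
        rng = np.random.default_rng([pop.seed, i])
        angle = rng.normal(0.0, np.radians(pop.angle_sd))
        # random unit axis in the plane perpendicular to the base direction
        raw = rng.normal(size=3)
        perp = raw - np.dot(raw, base_dir) * base_dir
        while np.linalg.norm(perp) < 1e-8:  # pragma: no cover - measure-zero
            raw = rng.normal(size=3)
            perp = raw - np.dot(raw, base_dir) * base_dir
        axis = perp / np.linalg.norm(perp)
        R = _rotation_about_axis(axis, angle)
        fa_i = float(np.clip(rng.normal(spec.fa_inside, pop.fa_sd), 0.0, 0.99))
        extent_i = float(max(rng.normal(spec.extent, pop.length_sd), 4 * spec.voxel_size))
        subjects.append(
            SubjectPhantom(
                subject_id=i,
                spec=replace(spec, fa_inside=fa_i, extent=extent_i, affine=spec.affine.copy()),
                rotation=R,
                rotation_axis=axis,
                rotation_angle_deg=float(np.degrees(angle)),
                fa_inside=fa_i,
                extent=extent_i,
                base_direction=base_dir,
            )
        )
    return subjects


def make_toy_mesh(extent: tuple[float, float, float], element_size: float) -> HexMesh:
    """Axis-aligned hexahedral grid mesh centered on the origin.

    ``extent`` (mm) must be divisible by ``element_size``. Node ordering
    within each brick is right-handed: bottom face counter-clockwise
    (viewed from +z), then the top face.
    """
    extent = np.asarray(extent, dtype=float)
    if element_size <= 0 or np.any(extent <= 0):
        raise ValueError("extent and element_size must be positive")
    n = extent / element_size
    if not np.allclose(n, np.round(n)):
        raise ValueError("extent must be divisible by element_size")
    nx, ny, nz = np.round(n).astype(int)

    xs = np.linspace(-extent[0] / 2, extent[0] / 2, nx + 1)
    ys = np.linspace(-extent[1] / 2, extent[1] / 2, ny + 1)
    zs = np.linspace(-extent[2] / 2, extent[2] / 2, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    elements = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                elements.append(
                    [
                        nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
                        nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                    ]
                )
    return HexMesh(nodes=nodes, elements=np.array(elements, dtype=int))


@dataclass
class DeformationHistory:
    """Deformation gradient time history at a material point."""

    times: np.ndarray
    F: np.ndarray  # (T, 3, 3)
    fiber_dir0: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.fiber_dir0 = np.asarray(self.fiber_dir0, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.F.shape != (len(self.times), 3, 3):
            raise ValueError("F must be (T, 3, 3)")
        if np.any(np.linalg.det(self.F) <= 0):
            raise ValueError("det F must stay positive")
        if not np.allclose(self.F[0], np.eye(3), atol=1e-12):
            raise ValueError("history must start from the identity")
        if abs(np.linalg.norm(self.fiber_dir0) - 1.0) > 1e-6:
            raise ValueError("fiber_dir0 must be a unit vector")


def make_deformation_history(
    mode: str,
    amplitude: float,
    duration: float = 0.01,
    dt: float = 5e-4,
    fiber_dir0: np.ndarray = (0.0, 0.0, 1.0),
) -> DeformationHistory:
    """Linear ramp from the identity in the mode's parameter.

    * ``uniaxial_isochoric`` — F = diag(lam, lam^-1/2, lam^-1/2) with lam
      ramping 1 -> amplitude (volume preserving);
    * ``simple_shear`` — F = I + gamma e1 (x) e2, gamma 0 -> amplitude;
    * ``rigid_rotation`` — rotation about e3 by 0 -> amplitude radians;
    * ``volumetric`` — F = J^(1/3) I with J ramping 1 -> amplitude.
    """
    if dt <= 0 or duration < dt:
        raise ValueError("need dt > 0 and duration >= dt")
    times = np.arange(0.0, duration + dt / 2, dt)
    frac = times / times[-1]
    F = np.empty((len(times), 3, 3))
    if mode == "uniaxial_isochoric":
        if amplitude <= 0:
            raise ValueError("stretch amplitude must be positive")
        lam = 1.0 + (amplitude - 1.0) * frac
        F[:] = 0.0
        F[:, 0, 0] = lam
        F[:, 1, 1] = F[:, 2, 2] = lam**-0.5
    elif mode == "simple_shear":
        F[:] = np.eye(3)
        F[:, 0, 1] = amplitude * frac
    elif mode == "rigid_rotation":
        ang = amplitude * frac
        F[:] = 0.0
        F[:, 0, 0] = F[:, 1, 1] = np.cos(ang)
        F[:, 0, 1] = -np.sin(ang)
        F[:, 1, 0] = np.sin(ang)
        F[:, 2, 2] = 1.0
    elif mode == "volumetric":
        if amplitude <= 0:
            raise ValueError("volume ratio must be positive")
        J = 1.0 + (amplitude - 1.0) * frac
        F[:] = np.eye(3) * J[:, None, None] ** (1.0 / 3.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DeformationHistory(times=times, F=F, fiber_dir0=np.asarray(fiber_dir0, dtype=float))
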