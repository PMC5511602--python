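"""Mapping diffusion tensors onto a hexahedral finite-element mesh.

Each brain element receives a distance-weighted average of the diffusion
tensors of the voxels it contains,

    DiffT_element = sum_i DiffT_i e^{-D_i} / sum_i e^{-D_i},

where D_i is the voxel-center-to-element-centroid distance normalized by
the largest such distance within the element (so weights span [1/e, 1]
regardless of element size). Element FA is discretized into nine intervals
that set the fiber dispersion parameter k of the anisotropic constitutive
model: FA < 0.2 is treated as gray matter (k = 1/3, isotropic) and the
eight white-matter groups become progressively more aligned up to k = 0.
The element fiber vector P is the principal eigenvector of the averaged
tensor, reported as elevation/azimuth angles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tensor_fit import (
    TensorVolume,
    canonical_sign,
    fractional_anisotropy,
    principal_direction,
)

logger = logging.getLogger(__name__)

# FA discretization: interval lower bounds and the dispersion parameter k
# of each group. Intervals are half-open [lower, upper); the last is closed
# at FA = 1. Part 0 is gray matter; parts 1-8 are white-matter groups.
FA_BOUNDS = np.array([0.0, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
K_VALUES = np.array(
    [0.3333, 0.2732, 0.2500, 0.2273, 0.2000, 0.1667, 0.1282, 0.0769, 0.0000]
)
GRAY_PART = 0


def assign_part(fa):
    """Dispersion parameter k and part index from FA.

    Half-open intervals [lower, upper), last closed at 1.0. Returns
    ``(k, part)``; part 0 is gray matter (k = 0.3333), parts 1-8 the
    white-matter anisotropy groups. Accepts scalars or arrays.
    """
    fa_arr = np.asarray(fa, dtype=float)
    if np.any(fa_arr < 0) or np.any(fa_arr > 1):
        raise ValueError("FA outside [0, 1]")
    part = np.searchsorted(FA_BOUNDS, fa_arr, side="right") - 1
    part = np.minimum(part, len(K_VALUES) - 1)  # FA = 1.0 -> last interval
    k = K_VALUES[part]
    if np.isscalar(fa) or fa_arr.ndim == 0:
        return float(k), int(part)
    return k, part


@dataclass
class HexMesh:
    """Eight-node hexahedral mesh: node coordinates (mm) and connectivity.

    ``elements`` holds 0-based node indices in the standard right-handed
    brick ordering (bottom face counter-clockwise, then top face).
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)
        if self.elements.ndim != 2 or self.elements.shape[1] != 8:
            raise ValueError("elements must be (E, 8) node indices")
        if self.element_ids is None:
            self.element_ids = np.arange(len(self.elements))
        else:
            self.element_ids = np.asarray(self.element_ids, dtype=int)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def element_volumes(self) -> np.ndarray:
        """Volumes by decomposition of each brick into six tetrahedra."""
        corners = self.nodes[self.elements]  # (E, 8, 3)
        tets = [(0, 1, 3, 4), (1, 2, 3, 4), (2, 6, 3, 4), (3, 6, 7, 4), (1, 5, 2, 4), (2, 5, 6, 4)]
        vol = np.zeros(len(corners))
        for a, b, c, d in tets:
            u = corners[:, b] - corners[:, a]
            v = corners[:, c] - corners[:, a]
            w = corners[:, d] - corners[:, a]
            vol += np.abs(np.einsum("ij,ij->i", np.cross(u, v), w)) / 6.0
        return vol

    def face_neighbors(self) -> list[list[int]]:
        """Element indices sharing a full (4-node) face."""
        faces: dict[tuple, list[int]] = {}
        face_defs = [
            (0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4),
            (1, 2, 6, 5), (2, 3, 7, 6), (3, 0, 4, 7),
        ]
        for e, conn in enumerate(self.elements):
            for fd in face_defs:
                key = tuple(sorted(conn[list(fd)]))
                faces.setdefault(key, []).append(e)
        nbrs: list[list[int]] = [[] for _ in range(self.n_elements)]
        for members in faces.values():
            for i in members:
                for j in members:
                    if i != j:
                        nbrs[i].append(j)
        return nbrs


@dataclass
class VoxelAssignment:
    """Per-element voxel membership with normalized distances and weights."""

    voxel_indices: dict[int, np.ndarray]  # element idx -> (N, 3) voxel ijk
    distances: dict[int, np.ndarray]  # element idx -> (N,) normalized D_i
    weights: dict[int, np.ndarray]  # element idx -> (N,) e^{-D_i}


def _grid_ownership(mesh: HexMesh, centers: np.ndarray) -> np.ndarray | None:
    """Fast containment lookup when the mesh is a regular axis-aligned grid.

    Returns the owning element per point (-1 outside), or None when the
    mesh is not a complete grid. Points exactly on an interior face go to
    the cell with the lower coordinate (the lower element index for
    lexicographically numbered grids).
    """
    edges = [np.unique(np.round(mesh.nodes[:, ax], 9)) for ax in range(3)]
    shape = tuple(len(e) - 1 for e in edges)
    if np.prod(shape) != mesh.n_elements or min(shape) < 1:
        return None
    cent = mesh.centroids()
    cell = np.stack(
        [np.searchsorted(edges[ax], cent[:, ax]) - 1 for ax in range(3)], axis=1
    )
    if np.any(cell < 0) or np.any(cell >= np.array(shape)):
        return None
    lattice = np.full(shape, -1, dtype=int)
    lattice[cell[:, 0], cell[:, 1], cell[:, 2]] = np.arange(mesh.n_elements)
    if np.any(lattice < 0):  # not a complete grid
        return None
    idx = np.empty((len(centers), 3), dtype=int)
    inside = np.ones(len(centers), dtype=bool)
    for ax in range(3):
        x = centers[:, ax]
        i = np.searchsorted(edges[ax], x, side="left") - 1
        i = np.clip(i, 0, shape[ax] - 1)
        idx[:, ax] = i
        inside &= (x >= edges[ax][0] - 1e-9) & (x <= edges[ax][-1] + 1e-9)
    owner = np.where(inside, lattice[idx[:, 0], idx[:, 1], idx[:, 2]], -1)
    return owner


def voxelize_mesh(mesh: HexMesh, tensors: TensorVolume) -> VoxelAssignment:
    """Assign masked voxel centers to the axis-aligned element containing them.

    Boundary ties (a voxel center exactly on a shared face) go to the lower
    element index. The normalized distance D_i of a voxel is its
    center-to-element-centroid distance divided by the maximum such
    distance in that element's voxel set (0 for a single voxel).
    """
    ijk = np.argwhere(tensors.mask)
    homog = np.hstack([ijk, np.ones((len(ijk), 1))])
    centers = (tensors.affine @ homog.T).T[:, :3]

    centroids = mesh.centroids()

    owner = _grid_ownership(mesh, centers)
    if owner is None:
        # generic path: per-element interval tests, lowest element wins ties
        corners = mesh.nodes[mesh.elements]
        lo = corners.min(axis=1)  # (E, 3)
        hi = corners.max(axis=1)
        owner = np.full(len(centers), -1, dtype=int)
        for e in range(mesh.n_elements):
            inside = np.all(
                (centers >= lo[e] - 1e-9) & (centers <= hi[e] + 1e-9), axis=1
            )
            new = inside & (owner < 0)
            owner[new] = e

    voxel_indices, distances, weights = {}, {}, {}
    for e in range(mesh.n_elements):
        sel = owner == e
        if not sel.any():
            continue
        pts = centers[sel]
        d = np.linalg.norm(pts - centroids[e], axis=1)
        dmax = d.max()
        d_norm = d / dmax if dmax > 0 else np.zeros_like(d)
        voxel_indices[e] = ijk[sel]
        distances[e] = d_norm
        weights[e] = np.exp(-d_norm)
    return VoxelAssignment(voxel_indices, distances, weights)


def element_tensor(tensors: TensorVolume, assignment: VoxelAssignment, elem: int) -> np.ndarray:
    """Distance-weighted average tensor of one element's voxels."""
    ijk = assignment.voxel_indices[elem]
    w = assignment.weights[elem]
    D = tensors.D[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
    return np.einsum("nij,n->ij", D, w) / w.sum()


def element_orientation_angles(P: np.ndarray) -> tuple[float, float]:
    """Elevation and azimuth (radians) of a unit fiber vector.

    The sign of P is first canonicalized (non-negative z, ties to y then x),
    then Theta = arccos(P_z) in [0, pi] and Phi = atan2(P_y, P_x) mapped
    into [0, 2 pi).
    """
    P = np.asarray(P, dtype=float)
    if abs(np.linalg.norm(P) - 1.0) > 1e-6:
        raise ValueError("fiber vector must be unit length")
    P = canonical_sign(P)
    theta = float(np.arccos(np.clip(P[2], -1.0, 1.0)))
    phi = float(np.mod(np.arctan2(P[1], P[0]), 2.0 * np.pi))
    return theta, phi


@dataclass
class ElementAnisotropy:
    """Averaged anisotropy information of one finite element."""

    element_id: int
    D: np.ndarray
    fa: float
    k: float
    part: int
    P: np.ndarray
    theta: float
    phi: float
    inherited: bool = False  # True when filled from face neighbors


def _orthogonal_unit(P: np.ndarray) -> np.ndarray:
    """Deterministic unit vector orthogonal to P (least-aligned axis)."""
    axis = np.zeros(3)
    axis[np.argmin(np.abs(P))] = 1.0
    d = axis - np.dot(axis, P) * P
    return d / np.linalg.norm(d)


def build_element_anisotropy(
    mesh: HexMesh, tensors: TensorVolume, assignment: VoxelAssignment | None = None
) -> list[ElementAnisotropy]:
    """Element-wise anisotropy for a whole mesh.

    Elements that contain no masked voxel inherit the mean tensor of their
    face neighbors (iterated until resolved); this is logged loudly since
    it signals a mesh/volume mismatch.
    """
    if assignment is None:
        assignment = voxelize_mesh(mesh, tensors)
    D_elem: dict[int, np.ndarray] = {
        e: element_tensor(tensors, assignment, e) for e in assignment.voxel_indices
    }
    inherited: set[int] = set()
    empty = [e for e in range(mesh.n_elements) if e not in D_elem]
    if empty:
        logger.warning(
            "%d of %d elements contain no voxels; inheriting neighbor averages",
            len(empty), mesh.n_elements,
        )
        nbrs = mesh.face_neighbors()
        pending = list(empty)
        while pending:
            progressed = False
            still = []
            for e in pending:
                avail = [D_elem[j] for j in nbrs[e] if j in D_elem]
                if avail:
                    D_elem[e] = np.mean(avail, axis=0)
                    inherited.add(e)
                    progressed = True
                else:
                    still.append(e)
            if not progressed:
                raise ValueError("isolated empty elements: no neighbor carries data")
            pending = still

    out = []
    for e in range(mesh.n_elements):
        D = D_elem[e]
        evals = np.clip(np.linalg.eigvalsh(D), 0.0, None)
        fa = float(fractional_anisotropy(evals[::-1]))
        k, part = assign_part(fa)
        P, degenerate = principal_direction(D)
        if degenerate:
            P = np.array([0.0, 0.0, 1.0])  # conventional axis for isotropic elements
        theta, phi = element_orientation_angles(P)
        out.append(
            ElementAnisotropy(
                element_id=int(mesh.element_ids[e]), D=D, fa=fa, k=float(k),
                part=int(part), P=P, theta=theta, phi=phi, inherited=e in inherited,
            )
        )
    return out


def elements_to_dataframe(elements: list[ElementAnisotropy]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "element_id": [e.element_id for e in elements],
            "fa": [e.fa for e in elements],
            "k": [e.k for e in elements],
            "part": [e.part for e in elements],
            "theta_deg": [np.degrees(e.theta) for e in elements],
            "phi_deg": [np.degrees(e.phi) for e in elements],
        }
    )


def composition_summary(
    elements: list[ElementAnisotropy], volumes: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-part element counts and volume fractions (part 0 = gray)."""
    parts = np.array([e.part for e in elements])
    if volumes is None:
        volumes = np.ones(len(elements))
    volumes = np.asarray(volumes, dtype=float)
    total = volumes.sum()
    rows = []
    for p in range(len(K_VALUES)):
        sel = parts == p
        rows.append(
            {
                "part": p,
                "k": K_VALUES[p],
                "n_elements": int(sel.sum()),
                "volume_fraction": volumes[sel].sum() / total,
            }
        )
    return pd.DataFrame(rows)


def population_composition(summaries: list[pd.DataFrame]) -> pd.DataFrame:
    """Across-subject mean/SD/CV of per-part volume fractions.

    Also useful for the gray-fraction range: the part-0 row's min/max
    columns bound the gray-matter share over the population.
    """
    stacked = np.stack([s["volume_fraction"].to_numpy() for s in summaries])
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0, ddof=1) if len(summaries) > 1 else np.zeros_like(mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / mean, np.nan)
    return pd.DataFrame(
        {
            "part": np.arange(len(mean)),
            "k": K_VALUES,
            "mean_fraction": mean,
            "sd_fraction": sd,
            "cv_percent": cv,
            "min_fraction": stacked.min(axis=0),
            "max_fraction": stacked.max(axis=0),
        }
    )
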