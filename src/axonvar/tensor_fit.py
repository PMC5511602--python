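"""Diffusion tensor estimation and scalar parametric maps.

Implements the single-tensor DTI fit used throughout the pipeline: a
two-pass weighted linear least squares (WLLS) estimator restricted to the
low-b shells (b < 1500 s/mm^2, where the mono-exponential signal model
holds), negative-eigenvalue clamping to enforce positive semidefiniteness,
fractional anisotropy (FA), principal-direction extraction, and the
two-stage across-subject FA statistics per region of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class UnfittableError(ValueError):
    """Raised when a gradient table cannot support a tensor fit."""


@dataclass
class GradientTable:
    """Diffusion acquisition geometry: one (b-value, direction) per volume.

    bvals are in s/mm^2; bvecs are unit 3-vectors (rows). Directions for
    b = 0 entries are ignored and may be zero.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValueError("bvecs must be an (n, 3) array")
        if len(self.bvals) != len(self.bvecs):
            raise ValueError("bvals and bvecs must have equal length")
        if not np.any(self.bvals == 0):
            raise ValueError("gradient table needs at least one b = 0 entry")
        nz = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise ValueError("non-unit b-vector for a b > 0 volume")

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0


def select_shells(gt: GradientTable, bmax: float = 1500.0) -> tuple[GradientTable, np.ndarray]:
    """Keep volumes with b < bmax (b = 0 always retained).

    Returns the restricted gradient table and the index array mapping the
    kept entries back to the original volume ordering. Raises
    ``UnfittableError`` if fewer than six b > 0 directions survive.
    """
    keep = gt.bvals < bmax
    idx = np.flatnonzero(keep)
    sub = GradientTable(gt.bvals[idx], gt.bvecs[idx])
    if np.count_nonzero(sub.bvals > 0) < 6:
        raise UnfittableError(
            f"only {np.count_nonzero(sub.bvals > 0)} non-zero directions below "
            f"b = {bmax:g} s/mm^2; at least 6 required"
        )
    return sub, idx


def fractional_anisotropy(evals: np.ndarray) -> np.ndarray:
    """FA from tensor eigenvalues (last axis of length 3).

    FA = sqrt( [(l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2] / [2 (l1^2+l2^2+l3^2)] ),
    clipped to [0, 1] against round-off. The all-zero triple maps to 0.
    Negative eigenvalues are rejected: clamping happens upstream in the fit.
    """
    lam = np.asarray(evals, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("expected eigenvalue triples on the last axis")
    if np.any(lam < 0):
        raise ValueError("negative eigenvalue passed to fractional_anisotropy")
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    den = 2.0 * (l1**2 + l2**2 + l3**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(num / den)
    fa = np.where(den == 0, 0.0, fa)
    return np.clip(fa, 0.0, 1.0)[()]


def canonical_sign(v: np.ndarray) -> np.ndarray:
    """Canonical sign for an axial (sign-free) direction.

    Non-negative z-component; ties broken by non-negative y, then x.
    """
    v = np.asarray(v, dtype=float)
    flip = (v[..., 2] < 0) | (
        (v[..., 2] == 0) & ((v[..., 1] < 0) | ((v[..., 1] == 0) & (v[..., 0] < 0)))
    )
    return np.where(flip[..., None], -v, v)


def principal_direction(D: np.ndarray, rel_tol: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Unit eigenvector of the largest eigenvalue, canonically signed.

    Returns ``(e1, degenerate)``; the direction is meaningless (and flagged)
    when the two largest eigenvalues coincide to within ``rel_tol``.
    """
    D = np.asarray(D, dtype=float)
    evals, evecs = np.linalg.eigh(D)
    l1, l2 = evals[2], evals[1]
    scale = max(abs(l1), 1e-300)
    degenerate = (l1 - l2) <= rel_tol * scale
    e1 = canonical_sign(evecs[:, 2])
    return e1, bool(degenerate)


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensors on a regular grid.

    ``D`` has shape (X, Y, Z, 3, 3) in mm^2/s, ``affine`` maps 0-based
    voxel indices to world mm, ``mask`` marks voxels with a valid fit.
    """

    D: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    _evals: np.ndarray | None = field(default=None, repr=False, compare=False)
    _evecs: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.D.shape[:3]

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (descending) and matching eigenvector columns."""
        if self._evals is None:
            evals, evecs = np.linalg.eigh(self.D)
            self._evals = evals[..., ::-1]
            self._evecs = evecs[..., ::-1]
        return self._evals, self._evecs

    def fa(self) -> np.ndarray:
        evals, _ = self.eigensystem()
        fa = fractional_anisotropy(np.clip(evals, 0.0, None))
        return np.where(self.mask, fa, 0.0)

    def principal_directions(self, rel_tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
        """Canonically signed e1 map and a degenerate-voxel flag map."""
        evals, evecs = self.eigensystem()
        e1 = canonical_sign(evecs[..., 0])
        scale = np.maximum(np.abs(evals[..., 0]), 1e-300)
        degenerate = (evals[..., 0] - evals[..., 1]) <= rel_tol * scale
        return e1, degenerate | ~self.mask


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows of ln S = ln S0 - b g^T D g for the b > 0 volumes.

    Unknown vector: [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz].
    """
    b = bvals[:, None]
    g = bvecs
    return np.hstack(
        [
            np.ones_like(b),
            -b * g[:, 0:1] ** 2,
            -b * g[:, 1:2] ** 2,
            -b * g[:, 2:3] ** 2,
            -2 * b * g[:, 0:1] * g[:, 1:2],
            -2 * b * g[:, 0:1] * g[:, 2:3],
            -2 * b * g[:, 1:2] * g[:, 2:3],
        ]
    )


def _tensors_from_coeffs(x: np.ndarray) -> np.ndarray:
    """Assemble symmetric tensors from [lnS0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
    out = np.empty(x.shape[:-1] + (3, 3))
    out[..., 0, 0] = x[..., 1]
    out[..., 1, 1] = x[..., 2]
    out[..., 2, 2] = x[..., 3]
    out[..., 0, 1] = out[..., 1, 0] = x[..., 4]
    out[..., 0, 2] = out[..., 2, 0] = x[..., 5]
    out[..., 1, 2] = out[..., 2, 1] = x[..., 6]
    return out


def clamp_negative_eigenvalues(D: np.ndarray) -> np.ndarray:
    """Zero negative eigenvalues and reassemble, enforcing PSD tensors."""
    evals, evecs = np.linalg.eigh(D)
    evals = np.clip(evals, 0.0, None)
    return np.einsum("...ij,...j,...kj->...ik", evecs, evals, evecs)


def fit_tensor_wlls(
    dwi: np.ndarray,
    gt: GradientTable,
    affine: np.ndarray,
    mask: np.ndarray | None = None,
    bmax: float = 1500.0,
    clamp: bool = True,
) -> TensorVolume:
    """Two-pass weighted linear least squares tensor fit.

    Pass 1 is ordinary least squares on the log signals; pass 2 reweights
    with the squared predicted signals (the large-signal observations carry
    the small log-domain noise) and solves once more. All b = 0 volumes are
    averaged into a single S0 regressor row. Voxels containing non-positive
    signals are flagged and excluded from the output mask. Negative
    eigenvalues of the fitted tensor are set to zero.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4 or dwi.shape[3] != len(gt):
        raise ValueError("dwi must be 4-D with one volume per gradient entry")
    gt_sub, idx = select_shells(gt, bmax)
    data = dwi[..., idx]
    shape = dwi.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    b0 = gt_sub.b0_mask
    s0_mean = data[..., b0].mean(axis=-1)
    signals = np.concatenate([s0_mean[..., None], data[..., ~b0]], axis=-1)
    fit_mask = mask & np.all(signals > 0, axis=-1)

    X = np.vstack(
        [
            np.array([[1.0, 0, 0, 0, 0, 0, 0]]),
            _design_matrix(gt_sub.bvals[~b0], gt_sub.bvecs[~b0]),
        ]
    )
    y = np.log(signals[fit_mask])  # (V, m)
    if y.size:
        # OLS pass
        coeffs, *_ = np.linalg.lstsq(X, y.T, rcond=None)
        coeffs = coeffs.T  # (V, 7)
        # WLLS pass: weights = squared predicted signals
        w = np.exp(coeffs @ X.T) ** 2  # (V, m)
        A = np.einsum("mi,vm,mj->vij", X, w, X)
        rhs = np.einsum("mi,vm,vm->vi", X, w, y)
        coeffs = np.linalg.solve(A, rhs[..., None])[..., 0]
        D_flat = _tensors_from_coeffs(coeffs)
        if clamp:
            D_flat = clamp_negative_eigenvalues(D_flat)
    else:
        D_flat = np.zeros((0, 3, 3))

    D = np.zeros(shape + (3, 3))
    D[fit_mask] = D_flat
    return TensorVolume(D=D, affine=np.asarray(affine, dtype=float), mask=fit_mask)


def fa_roi_statistics(
    fa_maps: list[np.ndarray],
    labels: np.ndarray,
    roi_labels: list[int] | None = None,
) -> pd.DataFrame:
    """Two-stage across-subject FA statistics per labeled region.

    Stage 1: per subject, the mean FA over each ROI's voxels. Stage 2:
    across subjects, the mean, sample SD (n-1) and CV = 100 SD/mean of
    those per-subject means. Empty ROIs are excluded with a warning.
    """
    labels = np.asarray(labels)
    if roi_labels is None:
        roi_labels = sorted(int(v) for v in np.unique(labels) if v != 0)
    rows = []
    for lab in roi_labels:
        roi = labels == lab
        if not roi.any():
            warnings.warn(f"ROI label {lab} is empty; excluded", stacklevel=2)
            continue
        means = np.array([np.asarray(m)[roi].mean() for m in fa_maps])
        mean = means.mean()
        sd = means.std(ddof=1) if len(means) > 1 else 0.0
        rows.append(
            {
                "roi": lab,
                "mean": mean,
                "sd": sd,
                "cv_percent": 100.0 * sd / mean if mean > 0 else np.nan,
                "n_subjects": len(means),
            }
        )
    return pd.DataFrame(rows)
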