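"""Along-tract geometric descriptors and their population statistics.

A fiber r(s), sampled uniformly in arc length, is characterized by its
length l = dm (n - 1), the unit tangent T(s) = r'(s)/|r'(s)| (central
differences inside, one-sided at the endpoints), the elevation/azimuth
angles (Theta, Phi) of T in the fixed laboratory frame, and the curvature
k(s) = |dT/ds|. Within a region of interest, fibers are aligned to a
reference fiber (the one passing closest to the ROI center) by matching
each fiber's seed point to the nearest reference point within a +/- 12 mm
arc-length search window; descriptor profiles then share a signed
arc-length axis. Statistics are two-stage: within subject across fibers,
then across subjects (sample SD, CV = 100 SD/mean). Azimuth profiles are
unwrapped along arc length before averaging to avoid the 0/2 pi seam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tractography import Streamline, StreamlineSet


def fiber_length(n: int, dm: float) -> float:
    """Length of a uniformly sampled fiber: dm (n - 1)."""
    if n < 1 or dm <= 0:
        raise ValueError("need n >= 1 points and positive spacing")
    return dm * (n - 1)


def tangent_vectors(points: np.ndarray, dm: float | None = None) -> np.ndarray:
    """Unit tangents: central differences interior, one-sided at ends."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
        raise ValueError("coincident consecutive points")
    if dm is None:
        dm = float(np.linalg.norm(pts[1] - pts[0]))
    d = np.gradient(pts, dm, axis=0, edge_order=1)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def angles_from_tangent(T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Elevation Theta in [0, pi] and azimuth Phi in [0, 2 pi) of unit vectors.

    Theta = arccos(T . e3); Phi = atan2(T . e2, T . e1) mapped into
    [0, 2 pi) (0 at the poles by the atan2(0, 0) convention). The spherical
    reconstruction sin(Theta)cos(Phi) e1 + sin(Theta)sin(Phi) e2 +
    cos(Theta) e3 returns T to round-off.
    """
    T = np.asarray(T, dtype=float)
    norms = np.linalg.norm(T, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("tangents must be unit vectors")
    theta = np.arccos(np.clip(T[..., 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(T[..., 1], T[..., 0]), 2.0 * np.pi)
    return theta[()], phi[()]


def tangent_from_angles(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Spherical reconstruction of the unit tangent."""
    theta, phi = np.asarray(theta, dtype=float), np.asarray(phi, dtype=float)
    return np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)], axis=-1
    )


def curvature(points: np.ndarray, dm: float | None = None) -> np.ndarray:
    """Pointwise curvature |dT/ds| by finite differences of the unit tangent."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points for curvature")
    if dm is None:
        dm = float(np.linalg.norm(pts[1] - pts[0]))
    T = tangent_vectors(pts, dm)
    dT = np.gradient(T, dm, axis=0, edge_order=1)
    return np.linalg.norm(dT, axis=1)


def select_reference_fiber(sset: StreamlineSet, roi_centroid: np.ndarray) -> tuple[Streamline, int]:
    """The streamline passing closest to the ROI centroid (ties: lower index)."""
    if len(sset) == 0:
        raise ValueError("empty streamline set")
    c = np.asarray(roi_centroid, dtype=float)
    dists = [np.min(np.linalg.norm(s.points - c, axis=1)) for s in sset.streamlines]
    idx = int(np.argmin(dists))  # argmin returns the first minimum -> lower index
    return sset.streamlines[idx], idx


def align_to_reference(
    sset: StreamlineSet, ref: Streamline, window: float = 12.0
) -> list[tuple[int, bool]]:
    """Match each fiber's seed to the closest reference point.

    The search covers only reference points within +/- ``window`` mm of
    arc length from the reference seed point. Returns, per fiber, the
    matched reference index and a flag set when the match saturates at a
    window endpoint (seed far from the reference).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    half = int(np.floor(window / ref.step + 1e-9))
    lo = max(ref.seed_index - half, 0)
    hi = min(ref.seed_index + half, len(ref) - 1)
    segment = ref.points[lo : hi + 1]
    out = []
    for s in sset.streamlines:
        seed_pt = s.points[s.seed_index]
        j = int(np.argmin(np.linalg.norm(segment - seed_pt, axis=1)))
        match = lo + j
        clamped = match in (lo, hi) and len(segment) > 1
        out.append((match, clamped))
    return out


@dataclass
class SubjectProfile:
    """Within-subject along-tract means on a signed arc-length grid.

    ``arc`` is measured from the reference seed point (negative = before).
    Scalar fields carry per-subject bundle averages.
    """

    arc: np.ndarray
    mean_T: np.ndarray  # (m, 3)
    mean_theta: np.ndarray
    mean_phi: np.ndarray
    mean_k: np.ndarray
    n_fibers: np.ndarray
    mean_length: float
    scalar_theta: float
    scalar_phi: float
    scalar_k: float


def subject_profile(
    sset: StreamlineSet, roi_centroid: np.ndarray, window: float = 12.0
) -> SubjectProfile:
    """Align a subject's bundle to its reference fiber and average descriptors.

    Fiber point j of a fiber matched at reference index m sits at signed
    arc (m - ref_seed) step + (j - fiber_seed) step; positions are exact
    multiples of the step, so profiles bin without resampling error.
    """
    ref, _ = select_reference_fiber(sset, roi_centroid)
    matches = align_to_reference(sset, ref, window)
    offsets, data = [], []
    for s, (m, _clamped) in zip(sset.streamlines, matches):
        base = (m - ref.seed_index) - s.seed_index  # in units of step
        T = tangent_vectors(s.points, s.step)
        theta, phi = angles_from_tangent(T)
        phi = np.unwrap(phi)
        k = curvature(s.points, s.step)
        idx = base + np.arange(len(s))
        offsets.append(idx)
        data.append((T, theta, phi, k))

    lo = min(int(i[0]) for i in offsets)
    hi = max(int(i[-1]) for i in offsets)
    m = hi - lo + 1
    step = sset.streamlines[0].step
    sums = {
        "T": np.zeros((m, 3)), "theta": np.zeros(m), "phi": np.zeros(m),
        "k": np.zeros(m), "n": np.zeros(m),
    }
    for idx, (T, theta, phi, k) in zip(offsets, data):
        sl = idx - lo
        sums["T"][sl] += T
        sums["theta"][sl] += theta
        sums["phi"][sl] += phi
        sums["k"][sl] += k
        sums["n"][sl] += 1
    n = sums["n"]
    valid = n > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_T = np.where(valid[:, None], sums["T"] / np.maximum(n, 1)[:, None], np.nan)
        mean_theta = np.where(valid, sums["theta"] / np.maximum(n, 1), np.nan)
        mean_phi = np.where(valid, sums["phi"] / np.maximum(n, 1), np.nan)
        mean_k = np.where(valid, sums["k"] / np.maximum(n, 1), np.nan)

    lengths = [s.length for s in sset.streamlines]
    return SubjectProfile(
        arc=(np.arange(lo, hi + 1)) * step,
        mean_T=mean_T,
        mean_theta=mean_theta,
        mean_phi=mean_phi,
        mean_k=mean_k,
        n_fibers=n,
        mean_length=float(np.mean(lengths)),
        scalar_theta=float(np.nanmean(mean_theta)),
        scalar_phi=float(np.nanmean(mean_phi)),
        scalar_k=float(np.nanmean(mean_k)),
    )


def population_profile(
    profiles: list[SubjectProfile],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Across-subject statistics of aligned descriptor profiles.

    Returns (tract profile, scalar summary). The tract profile carries,
    per arc-length grid point, the across-subject mean and sample SD of
    the within-subject means (SD only where >= 2 subjects contribute).
    The scalar summary reports mean/SD/CV of the per-subject bundle
    averages of length, curvature, elevation and azimuth.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 subjects")
    step = profiles[0].arc[1] - profiles[0].arc[0] if len(profiles[0].arc) > 1 else 0.5
    lo = min(int(round(p.arc[0] / step)) for p in profiles)
    hi = max(int(round(p.arc[-1] / step)) for p in profiles)
    m = hi - lo + 1
    grids = {name: np.full((len(profiles), m), np.nan) for name in ("theta", "phi", "k")}
    T_grid = np.full((len(profiles), m, 3), np.nan)
    for i, p in enumerate(profiles):
        start = int(round(p.arc[0] / step)) - lo
        sl = slice(start, start + len(p.arc))
        grids["theta"][i, sl] = p.mean_theta
        grids["phi"][i, sl] = p.mean_phi
        grids["k"][i, sl] = p.mean_k
        T_grid[i, sl] = p.mean_T

    n_contrib = np.sum(~np.isnan(grids["theta"]), axis=0)
    with np.errstate(invalid="ignore"):
        mean_T = np.nanmean(T_grid, axis=0)
        stats = {}
        for name, g in grids.items():
            stats[f"mean_{name}"] = np.nanmean(g, axis=0)
            sd = np.full(m, np.nan)
            enough = n_contrib >= 2
            if enough.any():
                sd[enough] = np.nanstd(g[:, enough], axis=0, ddof=1)
            stats[f"sd_{name}"] = sd

    profile_df = pd.DataFrame(
        {
            "arc_mm": np.arange(lo, hi + 1) * step,
            "mean_theta_deg": np.degrees(stats["mean_theta"]),
            "sd_theta_deg": np.degrees(stats["sd_theta"]),
            "mean_phi_deg": np.degrees(stats["mean_phi"]),
            "sd_phi_deg": np.degrees(stats["sd_phi"]),
            "mean_k": stats["mean_k"],
            "sd_k": stats["sd_k"],
            "mean_Tx": mean_T[:, 0],
            "mean_Ty": mean_T[:, 1],
            "mean_Tz": mean_T[:, 2],
            "n_contributing": n_contrib,
        }
    )

    rows = []
    for name, values, to_deg in (
        ("length_mm", [p.mean_length for p in profiles], False),
        ("curvature_per_mm", [p.scalar_k for p in profiles], False),
        ("theta_deg", [p.scalar_theta for p in profiles], True),
        ("phi_deg", [p.scalar_phi for p in profiles], True),
    ):
        v = np.degrees(values) if to_deg else np.asarray(values, dtype=float)
        mean, sd = v.mean(), v.std(ddof=1)
        rows.append(
            {
                "descriptor": name,
                "mean": mean,
                "sd": sd,
                "cv_percent": 100.0 * sd / mean if mean != 0 else np.nan,
                "n_subjects": len(v),
            }
        )
    return profile_df, pd.DataFrame(rows)
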