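"""File formats: NIfTI volumes, FSL gradient tables, CSV side-cars.

Volumes travel as NIfTI-1 (via nibabel), gradient tables as FSL-dialect
whitespace text (one row of b-values; three rows of b-vector components),
meshes as two CSVs (nodes: id,x,y,z; elements: id,n1..n8 with 1-based
node ids), deformation histories as CSV (t, F11..F33 row-major),
streamlines as long-format CSV or TrackVis .trk, and element
orientations as a solid-element orthotropic keyword-style text block.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fe_coupling import ElementAnisotropy, HexMesh, _orthogonal_unit
from .synthetic_data import DeformationHistory
from .tensor_fit import GradientTable
from .tractography import Streamline, StreamlineSet, TrackingParams


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_nifti(path: str | Path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))


def read_bvals_bvecs(bvals_path: str | Path, bvecs_path: str | Path) -> GradientTable:
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T  # FSL stores one row per component
    elif bvecs.shape == (3, 3) and len(bvals) == 3:
        bvecs = bvecs.T
    return GradientTable(bvals, bvecs)


def write_bvals_bvecs(gt: GradientTable, bvals_path: str | Path, bvecs_path: str | Path) -> None:
    np.savetxt(bvals_path, gt.bvals[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, gt.bvecs.T, fmt="%.8f")


def write_mesh_csv(mesh: HexMesh, nodes_path: str | Path, elements_path: str | Path) -> None:
    nodes = pd.DataFrame(mesh.nodes, columns=["x", "y", "z"])
    nodes.insert(0, "id", np.arange(1, len(nodes) + 1))
    nodes.to_csv(nodes_path, index=False)
    elems = pd.DataFrame(mesh.elements + 1, columns=[f"n{i}" for i in range(1, 9)])
    elems.insert(0, "id", mesh.element_ids + 1)
    elems.to_csv(elements_path, index=False)


def read_mesh_csv(nodes_path: str | Path, elements_path: str | Path) -> HexMesh:
    nodes = pd.read_csv(nodes_path)
    elems = pd.read_csv(elements_path)
    return HexMesh(
        nodes=nodes[["x", "y", "z"]].to_numpy(),
        elements=elems[[f"n{i}" for i in range(1, 9)]].to_numpy() - 1,
        element_ids=elems["id"].to_numpy() - 1,
    )


def write_history_csv(history: DeformationHistory, path: str | Path) -> None:
    cols = [f"F{i}{j}" for i in range(1, 4) for j in range(1, 4)]
    df = pd.DataFrame(history.F.reshape(len(history.times), 9), columns=cols)
    df.insert(0, "t", history.times)
    df.to_csv(path, index=False)


def read_history_csv(path: str | Path, fiber_dir0=(0.0, 0.0, 1.0)) -> DeformationHistory:
    df = pd.read_csv(path)
    cols = [f"F{i}{j}" for i in range(1, 4) for j in range(1, 4)]
    return DeformationHistory(
        times=df["t"].to_numpy(),
        F=df[cols].to_numpy().reshape(-1, 3, 3),
        fiber_dir0=np.asarray(fiber_dir0, dtype=float),
    )


def write_streamlines_csv(sset: StreamlineSet, path: str | Path) -> None:
    rows = []
    for sid, s in enumerate(sset.streamlines):
        for j, pt in enumerate(s.points):
            rows.append((sid, j, pt[0], pt[1], pt[2], s.seed_index, s.roi_label))
    pd.DataFrame(
        rows, columns=["streamline_id", "point_index", "x", "y", "z", "seed_index", "roi_label"]
    ).to_csv(path, index=False)


def read_streamlines_csv(path: str | Path, step: float = 0.5) -> StreamlineSet:
    df = pd.read_csv(path)
    streamlines = []
    for _, grp in df.groupby("streamline_id", sort=True):
        grp = grp.sort_values("point_index")
        streamlines.append(
            Streamline(
                points=grp[["x", "y", "z"]].to_numpy(),
                step=step,
                seed_index=int(grp["seed_index"].iloc[0]),
                roi_label=int(grp["roi_label"].iloc[0]),
            )
        )
    return StreamlineSet(streamlines=streamlines, params=TrackingParams(step=step))


def write_trk(sset: StreamlineSet, path: str | Path) -> None:
    """TrackVis .trk export (world/RAS mm coordinates)."""
    tractogram = nib.streamlines.Tractogram(
        [s.points for s in sset.streamlines], affine_to_rasmm=np.eye(4)
    )
    nib.streamlines.save(tractogram, str(path))


def write_element_orientation(elements: list[ElementAnisotropy], path: str | Path) -> None:
    """Orthotropic solid-element orientation block.

    One row per element: element_id, part, the fiber vector a1 a2 a3, and
    a deterministic unit vector d1 d2 d3 orthogonal to it.
    """
    with open(path, "w") as fh:
        fh.write("# element_id part a1 a2 a3 d1 d2 d3\n")
        for e in elements:
            d = _orthogonal_unit(e.P)
            fh.write(
                f"{e.element_id} {e.part} "
                f"{e.P[0]:.8f} {e.P[1]:.8f} {e.P[2]:.8f} "
                f"{d[0]:.8f} {d[1]:.8f} {d[2]:.8f}\n"
            )
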