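"""File formats: delimited matrices, result TSVs, NIfTI volumes, truth tables.

Vertex indexing is 0-based and row-major with x fastest, matching
``build_lattice_graph``; result TSVs carry explicit lattice coordinates so
downstream tools need not re-derive the convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import Graph
from .model import TwoGroupData

__all__ = [
    "read_two_group_data",
    "write_two_group_data",
    "read_nifti_group",
    "write_lfdr_tsv",
    "write_lfdr_nifti",
    "write_truth_tsv",
    "read_truth_tsv",
]


def read_two_group_data(path_x, path_y) -> TwoGroupData:
    """Read two whitespace/TSV numeric matrices (vertices x samples)."""
    X = np.loadtxt(path_x, ndmin=2)
    Y = np.loadtxt(path_y, ndmin=2)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"vertex counts differ: {path_x} has {X.shape[0]} rows, "
            f"{path_y} has {Y.shape[0]}")
    return TwoGroupData(X, Y)


def write_two_group_data(data: TwoGroupData, path_x, path_y) -> None:
    np.savetxt(path_x, data.X, fmt="%.10g", delimiter="\t")
    np.savetxt(path_y, data.Y, fmt="%.10g", delimiter="\t")


def read_nifti_group(paths: list) -> np.ndarray:
    """Stack per-sample NIfTI volumes into a vertices x samples matrix.

    All volumes must share the grid; voxels are flattened x-fastest.
    """
    import nibabel as nib

    cols = []
    shape = None
    for p in paths:
        img = nib.load(str(p))
        arr = np.asanyarray(img.dataobj, dtype=float)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(f"volume {p} has shape {arr.shape}, expected {shape}")
        cols.append(arr.ravel(order="F"))
    return np.stack(cols, axis=1)


def write_lfdr_tsv(result, path, c: float = 0.05) -> None:
    """Result table: vertex_id, lattice coords, lfdr, discovery flag at c."""
    graph: Graph = result.graph
    coords = graph.coords
    if coords is None:
        coords = np.zeros((graph.n, 3), dtype=int)
    cols = {"vertex_id": np.arange(graph.n)}
    for i, name in enumerate(("x", "y", "z")):
        cols[name] = coords[:, i] if i < coords.shape[1] else np.zeros(graph.n, dtype=int)
    cols["lfdr"] = result.lfdr
    cols[f"discovered_at_{c:g}"] = (result.lfdr <= c).astype(int)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_lfdr_nifti(result, path) -> None:
    """Write the l_v values as a volume on the run's lattice geometry."""
    import nibabel as nib

    dims = result.graph.dims
    if dims is None:
        raise ValueError("NIfTI output needs a lattice run")
    vol = result.lfdr.reshape(dims, order="F")
    if vol.ndim == 2:
        vol = vol[:, :, None]
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4)), str(path))


def write_truth_tsv(truth, path) -> None:
    labels = truth.partition.labels()
    pd.DataFrame({
        "vertex_id": np.arange(labels.size),
        "block": labels,
        "is_null": truth.is_null.astype(int),
    }).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
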