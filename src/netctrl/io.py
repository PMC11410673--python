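"""Readers and writers for the tab-separated exchange formats.

Matrices are dense TSV with a header row of region (or state) labels; region
metadata is a TSV table with columns label, hemisphere, x, y, z and optional
sx, sy, sz (unit-sphere centroid).  Region order in the region table is
authoritative; other files are validated against it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .energy import StateMap, TransitionEnergyMatrix
from .graph import Connectome

__all__ = [
    "MatrixFormatError",
    "read_matrix_table",
    "write_matrix_table",
    "read_region_table",
    "read_state_table",
    "read_connectome",
    "write_connectome",
    "write_energy_matrix",
]


class MatrixFormatError(ValueError):
    pass


def read_matrix_table(path, square_required: bool = False):
    """Read a dense TSV matrix with a header row of labels.

    Returns ``(matrix, column_labels)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix table not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", header=0)
    except pd.errors.ParserError as exc:
        raise MatrixFormatError(f"ragged rows in {path}: {exc}") from exc
    labels = [str(c) for c in df.columns]
    try:
        matrix = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MatrixFormatError(f"non-numeric cell in {path}: {exc}") from exc
    if square_required and matrix.shape[0] != matrix.shape[1]:
        raise MatrixFormatError(
            f"square matrix required but {path} is {matrix.shape[0]}x{matrix.shape[1]}"
        )
    return matrix, labels


def write_matrix_table(path, matrix: np.ndarray, labels) -> None:
    pd.DataFrame(np.asarray(matrix), columns=list(labels)).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


REGION_COLUMNS = ["label", "hemisphere", "x", "y", "z"]


def read_region_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"region table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise MatrixFormatError(f"region table {path} missing columns {missing}")
    return df


def write_region_table(path, connectome: Connectome) -> None:
    df = pd.DataFrame(
        {
            "label": connectome.labels,
            "hemisphere": connectome.hemisphere
            if connectome.hemisphere is not None
            else ["?"] * connectome.n,
        }
    )
    coords = (
        connectome.coords3d
        if connectome.coords3d is not None
        else np.zeros((connectome.n, 3))
    )
    df[["x", "y", "z"]] = coords
    if connectome.sphere_coords is not None:
        df[["sx", "sy", "sz"]] = connectome.sphere_coords
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_connectome(matrix_path, region_path) -> Connectome:
    """Assemble a Connectome from a matrix TSV and a region-metadata TSV."""
    w, labels = read_matrix_table(matrix_path, square_required=True)
    regions = read_region_table(region_path)
    if list(regions["label"].astype(str)) != labels:
        raise MatrixFormatError(
            "region table order does not match connectome matrix header"
        )
    sphere = None
    if {"sx", "sy", "sz"}.issubset(regions.columns):
        sphere = regions[["sx", "sy", "sz"]].to_numpy(dtype=float)
    return Connectome(
        weights=w,
        labels=labels,
        coords3d=regions[["x", "y", "z"]].to_numpy(dtype=float),
        hemisphere=regions["hemisphere"].to_numpy(dtype=object),
        sphere_coords=sphere,
    )


def write_connectome(matrix_path, region_path, connectome: Connectome) -> None:
    write_matrix_table(matrix_path, connectome.weights, connectome.labels)
    write_region_table(region_path, connectome)


def read_state_table(path, region_labels=None) -> list[StateMap]:
    """Region x term TSV (rows = regions in connectome order, columns = maps)."""
    matrix, labels = read_matrix_table(path)
    if region_labels is not None and matrix.shape[0] != len(region_labels):
        raise MatrixFormatError(
            f"state table has {matrix.shape[0]} rows, expected {len(region_labels)} regions"
        )
    return [StateMap(values=matrix[:, j], label=labels[j]) for j in range(matrix.shape[1])]


def write_state_table(path, states: list[StateMap]) -> None:
    write_matrix_table(
        path,
        np.stack([s.values for s in states], axis=1),
        [s.label for s in states],
    )


def write_energy_matrix(path, te: TransitionEnergyMatrix) -> None:
    pd.DataFrame(
        te.energies, index=te.source_labels, columns=te.target_labels
    ).to_csv(path, sep="\t", index_label="source", float_format="%.12g")


def read_energy_matrix(path) -> TransitionEnergyMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TransitionEnergyMatrix(
        energies=df.to_numpy(dtype=float),
        source_labels=[str(i) for i in df.index],
        target_labels=[str(c) for c in df.columns],
    )
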