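"""Delimited-text readers and writers for connectome artifacts.

All on-disk formats are plain text: square matrices as TSV (CSV accepted)
with an optional first row/column of 1-based region IDs, region metadata as
a TSV table, and time series as TSV with rows = time points and columns =
regions.  Values are written at full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import BoldTrace, Parcellation, StructuralConnectome

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_regions",
    "write_regions",
    "read_timeseries",
    "write_timeseries",
    "read_connectome",
    "write_connectome",
]

PathLike = Union[str, Path]


def _sniff_delimiter(path: Path) -> str:
    first = path.open().readline()
    return "," if ("," in first and "\t" not in first) else "\t"


def read_matrix(path: PathLike, expected_n: Optional[int] = None) -> np.ndarray:
    """Read a square numeric matrix from a delimited text file.

    A non-numeric first row/column is treated as region-ID headers and
    stripped (after a consistency check that row and column orders agree).
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    # Detect header row/column by non-numeric top-left cell.
    def _is_number(s) -> bool:
        try:
            float(s)
            return True
        except (TypeError, ValueError):
            return False

    if not _is_number(df.iat[0, 0]):
        row_ids = df.iloc[0, 1:].tolist()
        col_ids = df.iloc[1:, 0].tolist()
        if row_ids != col_ids:
            raise ValueError(f"{path}: header row and column region IDs disagree")
        df = df.iloc[1:, 1:]
    try:
        m = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix table") from exc
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: expected a square table, got shape {m.shape}")
    if expected_n is not None and m.shape[0] != expected_n:
        raise ValueError(f"{path}: expected {expected_n} regions, found {m.shape[0]}")
    return m


def write_matrix(path: PathLike, matrix: np.ndarray, region_ids: Optional[list] = None,
                 delimiter: str = "\t") -> None:
    """Write a square matrix as delimited text, optionally with ID headers."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    path = Path(path)
    if region_ids is None:
        np.savetxt(path, m, delimiter=delimiter, fmt="%.17g")
        return
    if len(region_ids) != m.shape[0]:
        raise ValueError("region_ids length must match matrix size")
    ids = [str(r) for r in region_ids]
    with path.open("w") as fh:
        fh.write("id" + delimiter + delimiter.join(ids) + "\n")
        for rid, row in zip(ids, m):
            fh.write(rid + delimiter + delimiter.join(f"{v:.17g}" for v in row) + "\n")


REGION_COLUMNS = ["region_id", "label", "hemisphere", "homotopic_partner_id", "x", "y", "z"]


def write_regions(path: PathLike, parcellation: Parcellation,
                  labels: Optional[list[str]] = None) -> None:
    """Region metadata TSV: 1-based IDs, hemisphere L/R, homotopic partner, xyz."""
    n = parcellation.n_regions
    labels = labels or [f"region_{i + 1}" for i in range(n)]
    data = {
        "region_id": np.arange(1, n + 1),
        "label": labels,
        "hemisphere": parcellation.hemisphere,
        "homotopic_partner_id": parcellation.homotopic_partner + 1,
    }
    if parcellation.coordinates is not None:
        data["x"], data["y"], data["z"] = parcellation.coordinates.T
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_regions(path: PathLike) -> Parcellation:
    df = pd.read_csv(path, sep="\t")
    missing = {"region_id", "hemisphere", "homotopic_partner_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing region metadata columns {sorted(missing)}")
    order = np.argsort(df["region_id"].to_numpy())
    df = df.iloc[order]
    coords = None
    if {"x", "y", "z"} <= set(df.columns):
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    return Parcellation(
        hemisphere=df["hemisphere"].to_numpy(dtype=object),
        homotopic_partner=df["homotopic_partner_id"].to_numpy(dtype=int) - 1,
        coordinates=coords,
    )


def write_timeseries(path: PathLike, trace: BoldTrace) -> None:
    """Time-series TSV: rows = time points, columns = regions (1-based IDs)."""
    cols = [f"region_{i + 1}" for i in range(trace.n_regions)]
    pd.DataFrame(trace.values.T, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_timeseries(path: PathLike, sampling_interval: float) -> BoldTrace:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return BoldTrace(values=df.to_numpy(dtype=float).T, sampling_interval=sampling_interval)


def write_connectome(out_dir: PathLike, sc: StructuralConnectome,
                     manifest: Optional[dict] = None) -> None:
    """Write sc.tsv / lengths.tsv / regions.tsv (+ manifest.json) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = list(range(1, sc.n_regions + 1))
    write_matrix(out / "sc.tsv", sc.weights, region_ids=ids)
    write_matrix(out / "lengths.tsv", sc.lengths, region_ids=ids)
    write_regions(out / "regions.tsv", sc.parcellation)
    if manifest is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_connectome(in_dir: PathLike) -> StructuralConnectome:
    in_dir = Path(in_dir)
    parc = read_regions(in_dir / "regions.tsv")
    n = parc.n_regions
    weights = read_matrix(in_dir / "sc.tsv", expected_n=n)
    lengths = read_matrix(in_dir / "lengths.tsv", expected_n=n)
    return StructuralConnectome(parcellation=parc, weights=weights, lengths=lengths)
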