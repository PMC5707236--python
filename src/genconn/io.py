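"""Small TSV readers/writers shared by the CLI stages."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "parse_density_spec",
    "read_coords",
    "read_matrix_tsv",
    "read_timeseries_tsv",
    "write_matrix_tsv",
]


def read_timeseries_tsv(path) -> tuple[np.ndarray, list[str]]:
    """Volumes x ROIs table with ROI ids as header."""
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def read_coords(path) -> pd.DataFrame:
    """ROI coordinate table: roi_id, x, y, z (mm)."""
    df = pd.read_csv(path, sep="\t")
    required = {"roi_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"coordinate table needs columns {sorted(required)}")
    return df


def write_matrix_tsv(matrix: np.ndarray, roi_ids: list[str], path) -> None:
    """Square matrix with roi_id header row and column."""
    df = pd.DataFrame(matrix, index=roi_ids, columns=roi_ids)
    df.to_csv(path, sep="\t", index_label="roi_id", float_format="%.6f")


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col="roi_id")
    return df.to_numpy(dtype=float), list(df.columns)


def parse_density_spec(spec: str) -> np.ndarray:
    """Parse "start:stop:step" (inclusive stop) into a density grid."""
    parts = [float(p) for p in spec.split(":")]
    if len(parts) != 3:
        raise ValueError("density spec must be start:stop:step")
    start, stop, step = parts
    n = int(round((stop - start) / step)) + 1
    grid = np.round(start + step * np.arange(n), 10)
    return grid[grid <= stop + 1e-12]
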