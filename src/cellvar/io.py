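"""Readers and writers for the pipeline's plain-text formats.

Expression matrices as MatrixMarket (.mtx) triplets with features/cells
sidecar TSVs or as a single dense TSV; gene sets as GMT; CV tables,
allele-frequency tables and distance matrices as TSV (plus PHYLIP square
format for distances).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .core import CVRecord
from .scvar import ExpressionMatrix

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_expression_mtx",
    "write_expression_mtx",
    "read_gmt",
    "write_gmt",
    "write_cv_table",
    "read_vaf_tsv",
    "write_distance_tsv",
    "write_distance_phylip",
]

CELL_COLUMNS = ("population", "total_reads", "mapped_reads", "spikein_reads")


def _assemble(values: pd.DataFrame, cells: pd.DataFrame,
              features: pd.DataFrame | None) -> ExpressionMatrix:
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell metadata missing columns: {missing}")
    if features is None:
        features = pd.DataFrame({"is_spikein": False}, index=values.index)
    if "is_spikein" not in features.columns:
        features["is_spikein"] = False
    features["is_spikein"] = features["is_spikein"].astype(bool)
    return ExpressionMatrix(values=values, cells=cells, features=features)


def read_expression_tsv(
    matrix_path: str, cells_path: str, features_path: str | None = None
) -> ExpressionMatrix:
    """Dense feature x cell TSV plus cell (and optional feature) metadata."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    cells = pd.read_csv(cells_path, sep="\t", index_col=0)
    features = (
        pd.read_csv(features_path, sep="\t", index_col=0)
        if features_path
        else None
    )
    return _assemble(values.astype(float), cells, features)


def write_expression_tsv(matrix: ExpressionMatrix, prefix: str) -> None:
    matrix.values.to_csv(f"{prefix}_matrix.tsv", sep="\t")
    matrix.cells.to_csv(f"{prefix}_cells.tsv", sep="\t")
    matrix.features.to_csv(f"{prefix}_features.tsv", sep="\t")


def read_expression_mtx(
    mtx_path: str, features_path: str, cells_path: str
) -> ExpressionMatrix:
    """MatrixMarket triplet matrix with TSV sidecars (features x cells)."""
    mat = scipy_io.mmread(mtx_path)
    features = pd.read_csv(features_path, sep="\t", index_col=0)
    cells = pd.read_csv(cells_path, sep="\t", index_col=0)
    values = pd.DataFrame(
        np.asarray(mat.todense(), dtype=float),
        index=features.index,
        columns=cells.index,
    )
    return _assemble(values, cells, features)


def write_expression_mtx(matrix: ExpressionMatrix, prefix: str) -> None:
    scipy_io.mmwrite(
        f"{prefix}_matrix.mtx", sparse.coo_matrix(matrix.values.to_numpy())
    )
    matrix.features.to_csv(f"{prefix}_features.tsv", sep="\t")
    matrix.cells.to_csv(f"{prefix}_cells.tsv", sep="\t")


def read_gmt(path: str) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> member ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, _desc, *members = parts
            seen = list(dict.fromkeys(m for m in members if m))
            sets[name] = seen
    return sets


def write_gmt(sets: dict[str, list[str]], path: str,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_cv_table(records: dict[str, CVRecord], path: str) -> None:
    """CV records as TSV with columns feature_id, n, mean, sd, cv."""
    frame = pd.DataFrame(
        [
            {"feature_id": rec.feature_id or key, "n": rec.n,
             "mean": rec.mean, "sd": rec.sd, "cv": rec.cv}
            for key, rec in records.items()
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_vaf_tsv(path: str) -> pd.DataFrame:
    """Variant allele frequencies: variant_id column then one column per population."""
    freqs = pd.read_csv(path, sep="\t", index_col=0)
    vals = freqs.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("allele frequencies must lie in [0, 1]")
    return freqs


def write_distance_tsv(dm, path: str) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def write_distance_phylip(dm, path: str) -> None:
    """PHYLIP square distance format (name padded to 10 characters)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for i, name in enumerate(dm.ids):
            row = " ".join(f"{v:.6f}" for v in dm.data[i])
            fh.write(f"{str(name)[:10]:<10s} {row}\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
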