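"""Per-clone morphological variability scoring.

Debris filtering on (cytoplasmic - nuclear) area, sample-size-equalized
CVs of the six size parameters per clone, a PCA-based variability score,
high-variability flagging, and the mitotic index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import InsufficientDataError, equalized_cv
from .simulate import MORPHOLOGY_PARAMS

__all__ = [
    "MORPHOLOGY_PARAMS",
    "VariabilityScore",
    "debris_filter",
    "clone_cv_matrix",
    "variability_pc1",
    "mitotic_index",
]


@dataclass(frozen=True)
class VariabilityScore:
    clone_id: str
    pc1: float
    variance_explained: float
    hv_flag: bool


def _check_table(table: pd.DataFrame, params) -> None:
    missing = [c for c in ("clone_id", *params) if c not in table.columns]
    if missing:
        raise ValueError(f"morphology table missing columns: {missing}")


def debris_filter(
    table: pd.DataFrame, min_threshold: float
) -> tuple[pd.DataFrame, int]:
    """Drop rows with (cytoplasmic_area - nuclear_area) below the threshold.

    Returns the filtered table and the number of rows removed. Raises if
    the threshold eliminates every cell of some clone (naming the clone).
    """
    _check_table(table, ("cytoplasmic_area", "nuclear_area"))
    if min_threshold < 0:
        raise ValueError("threshold must be >= 0")
    diff = table["cytoplasmic_area"] - table["nuclear_area"]
    kept = table[diff >= min_threshold]
    removed = len(table) - len(kept)
    emptied = set(table["clone_id"]) - set(kept["clone_id"])
    if emptied:
        raise ValueError(
            f"debris threshold {min_threshold} removed all cells of clone(s): "
            f"{sorted(emptied)}"
        )
    return kept.reset_index(drop=True), removed


def clone_cv_matrix(
    table: pd.DataFrame,
    params=MORPHOLOGY_PARAMS,
    n_resamples: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Equalized CV of each size parameter per clone.

    The sampling size m is the smallest clone's cell count; larger clones
    are subsampled ``n_resamples`` times and their CVs averaged. Returns a
    clones x parameters frame with m, n_resamples and seed in ``attrs``.
    """
    _check_table(table, params)
    sizes = table.groupby("clone_id").size()
    if (sizes < 2).any():
        small = list(sizes.index[sizes < 2])
        raise InsufficientDataError(f"clones with fewer than 2 cells: {small}")
    # one child seed per parameter so each equalized_cv call is independently
    # seeded but the whole matrix is reproducible from `seed`
    children = np.random.SeedSequence(seed).spawn(len(params))
    columns = {}
    for param, child in zip(params, children):
        groups = {
            clone: sub[param].to_numpy()
            for clone, sub in table.groupby("clone_id")
        }
        records = equalized_cv(
            groups, n_resamples=n_resamples, seed=child.entropy
        )
        columns[param] = {clone: rec.cv for clone, rec in records.items()}
    out = pd.DataFrame(columns)
    out.index.name = "clone_id"
    out.attrs.update(
        {"m": int(sizes.min()), "n_resamples": n_resamples, "seed": seed}
    )
    return out


def variability_pc1(
    cv_matrix: pd.DataFrame,
    standardize: bool = True,
    flag_k_sd: float = 2.0,
) -> list[VariabilityScore]:
    """First-principal-component variability score per clone.

    PC1 is oriented so it correlates positively with the mean CV (larger =
    more variable); clones with pc1 > mean + ``flag_k_sd`` * sd are flagged
    as highly variable. Columns are z-scored by default.
    """
    if cv_matrix.shape[0] < 3:
        raise InsufficientDataError("need at least 3 clones")
    if cv_matrix.shape[1] < 1:
        raise ValueError("need at least 1 parameter column")
    x = cv_matrix.to_numpy(dtype=float)
    centered = x - x.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("constant CV matrix has no principal direction")
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("cannot standardize a constant CV column")
        centered = centered / sd
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, 0] * s[0]
    var = s**2 / (s**2).sum()
    mean_cv = x.mean(axis=1)
    corr = np.corrcoef(scores, mean_cv)[0, 1]
    if corr < 0:
        scores = -scores
    threshold = scores.mean() + flag_k_sd * scores.std(ddof=1)
    return [
        VariabilityScore(
            clone_id=str(clone),
            pc1=float(sc),
            variance_explained=float(var[0]),
            hv_flag=bool(sc > threshold),
        )
        for clone, sc in zip(cv_matrix.index, scores)
    ]


def mitotic_index(n_mitotic: int, n_total: int) -> float:
    """Mitotic cells over total cells for a tumour core."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_mitotic <= n_total:
        raise ValueError("need 0 <= n_mitotic <= n_total")
    return n_mitotic / n_total
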