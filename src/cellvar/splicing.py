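"""Intron-retention and exon-exon junction variability statistics.

The retention measure for an intron in a cell is
intron_reads / (up_exon_reads + down_exon_reads + pseudocount), missing
where the denominator is nonpositive. Comparisons reuse the shared paired
CV machinery; the knockdown shift test is a one-sample t-test of
per-transcript log2 retention ratios against zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import InsufficientDataError, PairedCVComparison, paired_cv_comparison

logger = logging.getLogger(__name__)

__all__ = [
    "KnockdownIRShift",
    "intron_retention_ratio",
    "ir_cv_comparison",
    "junction_cv_comparison",
    "knockdown_ir_shift",
]

INTRON_COLUMNS = (
    "gene_id", "intron_index", "cell_id",
    "intron_reads", "up_exon_reads", "down_exon_reads",
)
JUNCTION_COLUMNS = ("gene_id", "donor", "acceptor", "cell_id", "reads")


@dataclass
class KnockdownIRShift:
    """One-sample test of per-transcript log2 retention ratios vs zero."""

    log_ratio: pd.Series
    mean_log_ratio: float
    t_stat: float
    p_value: float
    frac_above_zero: float
    frac_below_zero: float
    metadata: dict = field(default_factory=dict)


def _check_long_table(table: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"table missing columns: {missing}")
    counts = table[[c for c in columns if c.endswith("reads")]]
    if (counts.to_numpy() < 0).any():
        raise ValueError("read counts must be nonnegative")


def intron_retention_ratio(
    table: pd.DataFrame, pseudocount: float = 0.0
) -> pd.DataFrame:
    """Retention ratio matrix, introns x cells.

    Rows are keyed by (gene_id, intron_index); values are
    intron / (up_exon + down_exon + pseudocount), NaN where the denominator
    is nonpositive.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    _check_long_table(table, INTRON_COLUMNS)
    denom = (
        table["up_exon_reads"] + table["down_exon_reads"] + pseudocount
    ).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, table["intron_reads"] / denom, np.nan)
    out = (
        table.assign(r=r)
        .pivot_table(
            index=["gene_id", "intron_index"], columns="cell_id", values="r",
            aggfunc="first", dropna=False,
        )
    )
    out.columns.name = None
    return out


def _paired_matrix_cv_comparison(
    mat_a: pd.DataFrame,
    mat_b: pd.DataFrame,
    min_detect_frac: float,
    sidedness: str,
    what: str,
) -> PairedCVComparison:
    """Shared detection filter + per-row CV + paired test for IR/junctions."""
    common = mat_a.index.intersection(mat_b.index)
    a = mat_a.loc[common]
    b = mat_b.loc[common]
    present = pd.concat([a.notna() & (a > 0), b.notna() & (b > 0)], axis=1)
    frac = present.mean(axis=1)
    in_both = (a.notna() & (a > 0)).any(axis=1) & (b.notna() & (b > 0)).any(axis=1)
    keep = (frac > min_detect_frac) & in_both
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise InsufficientDataError(
            f"fewer than 3 {what} survive the detection filter"
        )

    def row_cv(frame: pd.DataFrame) -> pd.Series:
        means = frame.mean(axis=1, skipna=True)
        sds = frame.std(axis=1, ddof=1, skipna=True)
        n_obs = frame.notna().sum(axis=1)
        cv = sds / means
        cv[(means <= 0) | (n_obs < 2)] = np.nan
        return cv

    cv_a, cv_b = row_cv(a), row_cv(b)
    ok = cv_a.notna() & cv_b.notna()
    if int(ok.sum()) < 3:
        raise InsufficientDataError(f"fewer than 3 {what} with defined CVs")
    ids = ["|".join(map(str, k)) if isinstance(k, tuple) else str(k)
           for k in a.index[ok]]
    result = paired_cv_comparison(cv_a[ok], cv_b[ok], feature_ids=ids,
                                  sidedness=sidedness)
    result.metadata.update(
        {"feature_kind": what, "min_detect_frac": min_detect_frac,
         "n_tested": int(ok.sum())}
    )
    return result


def ir_cv_comparison(
    ir_a: pd.DataFrame,
    ir_b: pd.DataFrame,
    min_detect_frac: float = 0.25,
) -> PairedCVComparison:
    """One-sided (b greater) paired comparison of per-intron retention CVs.

    Introns are kept when their ratio is defined and positive in more than
    ``min_detect_frac`` of all cells and present in both populations.
    """
    return _paired_matrix_cv_comparison(
        ir_a, ir_b, min_detect_frac, "one_sided_b_greater", "introns"
    )


def _per_million(table_wide: pd.DataFrame) -> pd.DataFrame:
    totals = table_wide.sum(axis=0).replace(0, np.nan)
    return table_wide.div(totals, axis=1) * 1e6


def junction_table_to_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Long junction table -> junctions x cells count matrix."""
    _check_long_table(table, JUNCTION_COLUMNS)
    out = table.pivot_table(
        index=["gene_id", "donor", "acceptor"], columns="cell_id",
        values="reads", aggfunc="first",
    ).fillna(0.0)
    out.columns.name = None
    return out


def junction_cv_comparison(
    ja: pd.DataFrame,
    jb: pd.DataFrame,
    min_detect_frac: float = 0.25,
    normalize: str = "per_million",
) -> PairedCVComparison:
    """One-sided (b greater) comparison of per-junction count CVs.

    Long tables are pivoted if needed; per-cell per-million normalization
    is applied by default so library size drops out.
    """
    if "reads" in ja.columns:
        ja = junction_table_to_matrix(ja)
    if "reads" in jb.columns:
        jb = junction_table_to_matrix(jb)
    if normalize == "per_million":
        ja, jb = _per_million(ja), _per_million(jb)
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    return _paired_matrix_cv_comparison(
        ja, jb, min_detect_frac, "one_sided_b_greater", "junctions"
    )


def knockdown_ir_shift(ir_kd: pd.Series, ir_ctrl: pd.Series) -> KnockdownIRShift:
    """Shift in retention between knockdown and control bulk samples.

    Inputs are per-transcript retention ratios (a pseudocount upstream is
    recommended so every transcript has a defined ratio). The statistic is
    a two-sided one-sample t-test of log2(r_kd / r_ctrl) against zero.
    """
    common = ir_kd.index.intersection(ir_ctrl.index)
    kd = ir_kd.loc[common].astype(float)
    ctrl = ir_ctrl.loc[common].astype(float)
    ok = kd.notna() & ctrl.notna() & (kd > 0) & (ctrl > 0)
    if int(ok.sum()) == 0:
        raise InsufficientDataError("no matched transcripts with defined ratios")
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d transcripts with undefined ratios", n_dropped)
    log_ratio = np.log2(kd[ok] / ctrl[ok])
    arr = log_ratio.to_numpy()
    if np.allclose(arr, arr[0]):
        if arr[0] == 0:
            t, p = 0.0, 1.0
        else:
            t = np.inf if arr[0] > 0 else -np.inf
            p = 0.0
    else:
        t, p = stats.ttest_1samp(arr, 0.0)
        t, p = float(t), float(p)
    return KnockdownIRShift(
        log_ratio=log_ratio,
        mean_log_ratio=float(arr.mean()),
        t_stat=t,
        p_value=p,
        frac_above_zero=float(np.mean(arr > 0)),
        frac_below_zero=float(np.mean(arr < 0)),
        metadata={"n_transcripts": int(ok.sum()), "n_dropped": n_dropped},
    )
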