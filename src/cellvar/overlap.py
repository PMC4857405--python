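"""Knockdown-dependence versus transcript-variability overlap statistics.

Thresholded set construction (|mean log2 FC| and CV-ratio cutoffs, strict
inequalities), the upper-tail hypergeometric overlap test, and a binned
deregulation-versus-variability trend with rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, pearsonr, spearmanr

__all__ = [
    "TranscriptSetPair",
    "TrendResult",
    "threshold_sets",
    "hypergeometric_overlap",
    "deregulation_variability_trend",
]


@dataclass
class TranscriptSetPair:
    dependent_set: set
    variable_set: set
    universe: set
    fc_threshold: float
    cv_threshold: float
    metadata: dict = field(default_factory=dict)


@dataclass
class TrendResult:
    per_bin: pd.DataFrame  # index bin; columns mean_abs_log2fc, mean_cv_ratio, n
    spearman_rho: float
    spearman_p: float
    pearson_r: float
    pearson_p: float


def threshold_sets(
    fc: pd.DataFrame,
    cv_ratio: pd.Series,
    fc_threshold: float = 1.0,
    cv_threshold: float = 1.5,
) -> TranscriptSetPair:
    """Dependent (|mean log2 FC| > cutoff) and variable (CV ratio > cutoff)
    transcript sets over the universe measured in both experiments.

    Inequalities are strict; transcripts exactly at a threshold are
    excluded from the corresponding set.
    """
    if "mean_log2fc" not in fc.columns:
        raise ValueError("fold-change table needs a mean_log2fc column")
    universe = fc.index.intersection(cv_ratio.dropna().index)
    if len(universe) == 0:
        raise ValueError("empty universe: no transcripts in both experiments")
    mean_fc = fc.loc[universe, "mean_log2fc"].astype(float)
    cv = cv_ratio.loc[universe].astype(float)
    dependent = set(universe[mean_fc.abs() > fc_threshold])
    variable = set(universe[cv > cv_threshold])
    return TranscriptSetPair(
        dependent_set=dependent,
        variable_set=variable,
        universe=set(universe),
        fc_threshold=fc_threshold,
        cv_threshold=cv_threshold,
        metadata={
            "universe_definition": "transcripts quantified in both experiments"
        },
    )


def hypergeometric_overlap(set_a, set_b, universe) -> tuple[int, float]:
    """Upper-tail probability of the observed overlap of two sets.

    p = P(X >= overlap) for X ~ Hypergeometric(|U|, |a|, |b|); symmetric in
    the two sets.
    """
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    overlap = len(a & b)
    p = float(hypergeom.sf(overlap - 1, len(universe), len(a), len(b)))
    return overlap, min(p, 1.0)


def deregulation_variability_trend(
    fc: pd.DataFrame,
    cv_ratio: pd.Series,
    n_bins: int = 10,
) -> TrendResult:
    """Mean CV ratio per |log2 FC|-quantile bin plus rank correlation.

    Spearman is the headline statistic (the display form of the source
    analysis is unspecified); Pearson is reported alongside.
    """
    universe = fc.index.intersection(cv_ratio.dropna().index)
    if len(universe) < n_bins * 3:
        raise ValueError(
            f"need at least {n_bins * 3} transcripts for {n_bins} bins"
        )
    abs_fc = fc.loc[universe, "mean_log2fc"].abs().astype(float)
    cv = cv_ratio.loc[universe].astype(float)
    bins = pd.qcut(abs_fc.rank(method="first"), n_bins, labels=False)
    per_bin = pd.DataFrame(
        {
            "mean_abs_log2fc": abs_fc.groupby(bins).mean(),
            "mean_cv_ratio": cv.groupby(bins).mean(),
            "n": abs_fc.groupby(bins).size(),
        }
    )
    per_bin.index.name = "bin"
    rho, sp = spearmanr(abs_fc, cv)
    r, pp = pearsonr(abs_fc, cv)
    return TrendResult(
        per_bin=per_bin,
        spearman_rho=float(rho),
        spearman_p=float(sp),
        pearson_r=float(r),
        pearson_p=float(pp),
    )
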