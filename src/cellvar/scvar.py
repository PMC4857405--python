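"""Single-cell transcript-expression variability between two cell populations.

Stages: cell QC, spike-in technical check, cell-number equalization,
transcript filtering, per-transcript CV comparison, subsample stability
across set sizes, and leave-one-out robustness.

The fixed pipeline order is: QC -> equalize -> filter -> compare. CVs are
computed on counts-per-million by default (``normalize="cpm"``); a raw
mode is available (``normalize="none"``).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    InsufficientDataError,
    PairedCVComparison,
    paired_cv_comparison,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "CellQCReport",
    "SubsampleStabilityTable",
    "LeaveOneOutResult",
    "qc_filter_cells",
    "spikein_qc",
    "equalize_populations",
    "filter_transcripts",
    "transcript_cv_comparison",
    "subsample_stability",
    "leave_one_out",
]

QC_REASONS = ("empty", "low_total_reads", "low_mapped_fraction", "high_spikein_fraction")


@dataclass
class ExpressionMatrix:
    """Features x cells nonnegative expression with per-cell metadata.

    ``values``: DataFrame indexed by feature_id with cell_id columns.
    ``cells``: DataFrame indexed by cell_id with columns ``population``,
    ``total_reads``, ``mapped_reads``, ``spikein_reads``.
    ``features``: DataFrame indexed by feature_id with boolean ``is_spikein``.
    """

    values: pd.DataFrame
    cells: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate cell ids")
        if not self.values.columns.equals(self.cells.index):
            self.cells = self.cells.loc[self.values.columns]
        if not self.values.index.equals(self.features.index):
            self.features = self.features.loc[self.values.index]
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError("expression values must be finite and nonnegative")

    @property
    def populations(self) -> list[str]:
        return sorted(self.cells["population"].unique())

    def cells_of(self, population: str) -> list[str]:
        mask = self.cells["population"] == population
        return list(self.cells.index[mask])

    def population_pair(self) -> tuple[str, str]:
        """Default (a, b) population ordering for comparisons.

        The HV/LV labelling convention puts the low-variability population
        first; otherwise lexicographic order is used.
        """
        pops = self.populations
        if len(pops) != 2:
            raise ValueError(f"expected exactly 2 populations, found {pops}")
        if set(pops) == {"HV", "LV"}:
            return "LV", "HV"
        return pops[0], pops[1]

    def subset_cells(self, cell_ids) -> "ExpressionMatrix":
        cell_ids = list(cell_ids)
        return ExpressionMatrix(
            values=self.values[cell_ids],
            cells=self.cells.loc[cell_ids],
            features=self.features,
        )

    def normalized(self, mode: str = "cpm") -> pd.DataFrame:
        """Expression values on the requested scale ('cpm' or 'none')."""
        if mode == "none":
            return self.values
        if mode == "cpm":
            totals = self.values.sum(axis=0)
            totals = totals.replace(0, np.nan)
            return self.values.div(totals, axis=1) * 1e6
        raise ValueError(f"unknown normalization mode {mode!r}")


@dataclass
class CellQCReport:
    """Pass/fail per cell with failure reasons."""

    passed: list
    excluded: dict  # cell_id -> list of reasons

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


@dataclass
class SubsampleStabilityTable:
    """Mean CV log-ratio and one-sided paired-t p-value per set size."""

    table: pd.DataFrame  # index set_size; columns mean_log_ratio, p_value, n_replicates
    pop_a: str
    pop_b: str


@dataclass
class LeaveOneOutResult:
    """Mean-CV distributions over all fixed-size subsets, per excluded cell."""

    per_excluded: dict  # cell_id -> np.ndarray of mean CVs, one per subset
    reference: np.ndarray  # all-cells distribution over C(n, subset_size) subsets
    subset_size: int
    population: str
    metadata: dict = field(default_factory=dict)


def qc_filter_cells(
    matrix: ExpressionMatrix,
    min_total: int = 10_000,
    min_mapped_frac: float = 0.3,
    max_spikein_frac: float = 0.5,
) -> tuple[ExpressionMatrix, CellQCReport]:
    """Remove cells failing read-count and spike-in quality rules.

    A cell fails with reason ``empty`` (zero total reads),
    ``low_total_reads``, ``low_mapped_fraction``, or
    ``high_spikein_fraction``; a cell may fail several rules at once.
    """
    if not (0 <= min_mapped_frac <= 1 and 0 <= max_spikein_frac <= 1):
        raise ValueError("fraction thresholds must be in [0, 1]")
    excluded: dict[str, list[str]] = {}
    for cell_id, row in matrix.cells.iterrows():
        reasons = []
        total = row["total_reads"]
        if total == 0:
            reasons.append("empty")
        else:
            if total < min_total:
                reasons.append("low_total_reads")
            if row["mapped_reads"] / total < min_mapped_frac:
                reasons.append("low_mapped_fraction")
            if row["mapped_reads"] > 0 and (
                row["spikein_reads"] / row["mapped_reads"] > max_spikein_frac
            ):
                reasons.append("high_spikein_fraction")
        if reasons:
            excluded[cell_id] = reasons
    kept = [c for c in matrix.values.columns if c not in excluded]
    for pop in matrix.populations:
        if not any(matrix.cells.loc[c, "population"] == pop for c in kept):
            raise InsufficientDataError(
                f"QC removed every cell of population {pop!r}"
            )
    report = CellQCReport(passed=kept, excluded=excluded)
    logger.info("cell QC: %d kept, %d excluded", len(kept), len(excluded))
    return matrix.subset_cells(kept), report


def spikein_qc(matrix: ExpressionMatrix) -> PairedCVComparison:
    """Two-sided paired CV comparison restricted to spike-in features.

    Spike-ins are added at fixed amounts per well, so a non-significant
    result is the pass condition. Raw values are used (spike-ins are not
    library-size normalized).
    """
    spike_ids = list(matrix.features.index[matrix.features["is_spikein"]])
    if not spike_ids:
        raise InsufficientDataError("no spike-in features present")
    if len(spike_ids) < 3:
        raise InsufficientDataError("need at least 3 spike-in features")
    pop_a, pop_b = matrix.population_pair()
    sub = matrix.values.loc[spike_ids]
    cv_a = _feature_cvs(sub[matrix.cells_of(pop_a)])
    cv_b = _feature_cvs(sub[matrix.cells_of(pop_b)])
    ok = cv_a.notna() & cv_b.notna()
    result = paired_cv_comparison(
        cv_a[ok], cv_b[ok], feature_ids=list(sub.index[ok]), sidedness="two_sided"
    )
    result.metadata.update({"pop_a": pop_a, "pop_b": pop_b, "spikein_only": True})
    return result


def equalize_populations(matrix: ExpressionMatrix, seed: int = 0) -> ExpressionMatrix:
    """Randomly down-sample the larger population to the smaller one's size."""
    pops = matrix.populations
    if len(pops) != 2:
        raise ValueError(f"expected exactly 2 populations, found {pops}")
    cells_by_pop = {p: matrix.cells_of(p) for p in pops}
    sizes = {p: len(c) for p, c in cells_by_pop.items()}
    if min(sizes.values()) < 2:
        raise InsufficientDataError("both populations need at least 2 cells")
    target = min(sizes.values())
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    for pop in pops:
        cells = cells_by_pop[pop]
        if len(cells) > target:
            cells = sorted(rng.choice(cells, size=target, replace=False))
        keep.extend(cells)
    keep = [c for c in matrix.values.columns if c in set(keep)]
    return matrix.subset_cells(keep)


def _fit_upper_mixture_component(log_means: np.ndarray) -> np.ndarray:
    """Boolean mask of features in the upper component of a 2-Gaussian mixture.

    Falls back to a single-Gaussian mean - 2 sd threshold when the mixture
    fit does not converge.
    """
    from sklearn.mixture import GaussianMixture

    x = log_means.reshape(-1, 1)
    try:
        gm = GaussianMixture(n_components=2, random_state=0, n_init=2, max_iter=500)
        gm.fit(x)
        converged = bool(gm.converged_)
    except Exception:  # pragma: no cover - sklearn failure path
        converged = False
    if not converged:
        logger.warning(
            "Gaussian mixture on log means did not converge; "
            "falling back to mean - 2 sd threshold"
        )
        thresh = log_means.mean() - 2 * log_means.std(ddof=1)
        return log_means > thresh
    upper = int(np.argmax(gm.means_.ravel()))
    post = gm.predict_proba(x)[:, upper]
    return post > 0.5


def filter_transcripts(
    matrix: ExpressionMatrix,
    min_detect_frac: float = 0.25,
    normalize: str = "cpm",
    mean_threshold: bool = True,
) -> list[str]:
    """Transcripts retained for CV analysis.

    Keeps non-spike-in features that are (i) detected (> 0) in at least one
    cell of each population, (ii) detected in more than ``min_detect_frac``
    of all cells, and (iii) assigned to the upper component of a
    two-component Gaussian mixture fitted to all features' log mean
    expression (skipped when ``mean_threshold`` is false).
    """
    if not 0 <= min_detect_frac < 1:
        raise ValueError("min_detect_frac must be in [0, 1)")
    pops = matrix.populations
    vals = matrix.normalized(normalize)
    not_spike = ~matrix.features["is_spikein"]
    detected = vals > 0
    in_both = pd.Series(True, index=vals.index)
    for pop in pops:
        in_both &= detected[matrix.cells_of(pop)].any(axis=1)
    frac = detected.mean(axis=1)
    keep = not_spike & in_both & (frac > min_detect_frac)
    n_before = int(keep.sum())
    if mean_threshold and n_before >= 4:
        sub = vals.loc[keep]
        log_means = np.log(sub.mean(axis=1).to_numpy())
        upper = _fit_upper_mixture_component(log_means)
        keep_ids = list(sub.index[upper])
    else:
        keep_ids = list(vals.index[keep])
    logger.info(
        "transcript filter: %d of %d features retained (%d passed detection)",
        len(keep_ids), len(vals.index), n_before,
    )
    return keep_ids


def _feature_cvs(frame: pd.DataFrame) -> pd.Series:
    """Per-row CV across columns; NaN where the mean is nonpositive."""
    arr = frame.to_numpy(dtype=float)
    means = arr.mean(axis=1)
    sds = arr.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means > 0, sds / means, np.nan)
    return pd.Series(cvs, index=frame.index)


def transcript_cv_comparison(
    matrix: ExpressionMatrix,
    features: list[str],
    normalize: str = "cpm",
    sidedness: str = "two_sided",
) -> PairedCVComparison:
    """Per-transcript CV across cells within each population, paired test.

    Features with zero mean in either population are dropped (the count is
    logged and recorded in the result metadata).
    """
    if len(features) < 3:
        raise InsufficientDataError("need at least 3 features")
    pop_a, pop_b = matrix.population_pair()
    vals = matrix.normalized(normalize).loc[features]
    cv_a = _feature_cvs(vals[matrix.cells_of(pop_a)])
    cv_b = _feature_cvs(vals[matrix.cells_of(pop_b)])
    ok = cv_a.notna() & cv_b.notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d features with nonpositive mean", n_dropped)
    if int(ok.sum()) < 3:
        raise InsufficientDataError("fewer than 3 features with defined CVs")
    result = paired_cv_comparison(
        cv_a[ok], cv_b[ok], feature_ids=list(vals.index[ok]), sidedness=sidedness
    )
    result.metadata.update(
        {
            "pop_a": pop_a,
            "pop_b": pop_b,
            "normalize": normalize,
            "n_dropped_zero_mean": n_dropped,
        }
    )
    return result


def subsample_stability(
    matrix: ExpressionMatrix,
    features: list[str],
    set_sizes: list[int],
    n_rep: int = 10,
    seed: int = 0,
    normalize: str = "cpm",
) -> SubsampleStabilityTable:
    """CV log-ratio stability across cell set sizes.

    For each set size, ``n_rep`` seeded subsets are drawn per population;
    per-transcript CVs are averaged across subsets within each population,
    and a single one-sided paired t-test (b > a) is run on the averaged
    per-transcript CVs.
    """
    pop_a, pop_b = matrix.population_pair()
    cells = {p: matrix.cells_of(p) for p in (pop_a, pop_b)}
    n_min = min(len(c) for c in cells.values())
    if min(set_sizes) < 3:
        raise ValueError("set sizes must be at least 3")
    if max(set_sizes) > n_min:
        raise ValueError(
            f"set size {max(set_sizes)} exceeds smallest population ({n_min} cells)"
        )
    vals = matrix.normalized(normalize).loc[features]
    rng = np.random.default_rng(seed)
    rows = []
    for size in set_sizes:
        avg_cv = {}
        for pop in (pop_a, pop_b):
            pool = cells[pop]
            reps = n_rep if size < len(pool) else 1
            acc = np.zeros(len(features))
            cnt = np.zeros(len(features))
            for _ in range(reps):
                chosen = list(rng.choice(pool, size=size, replace=False))
                cvs = _feature_cvs(vals[chosen]).to_numpy()
                good = np.isfinite(cvs)
                acc[good] += cvs[good]
                cnt[good] += 1
            with np.errstate(invalid="ignore"):
                avg_cv[pop] = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
        ok = np.isfinite(avg_cv[pop_a]) & np.isfinite(avg_cv[pop_b])
        cmp = paired_cv_comparison(
            avg_cv[pop_a][ok],
            avg_cv[pop_b][ok],
            feature_ids=[f for f, o in zip(features, ok) if o],
            sidedness="one_sided_b_greater",
        )
        finite_lr = cmp.log_ratio[np.isfinite(cmp.log_ratio)]
        rows.append(
            {
                "set_size": size,
                "mean_log_ratio": float(finite_lr.mean()),
                "p_value": cmp.p_value,
                "n_replicates": n_rep if size < n_min else 1,
            }
        )
    table = pd.DataFrame(rows).set_index("set_size")
    return SubsampleStabilityTable(table=table, pop_a=pop_a, pop_b=pop_b)


def _mean_cv_over_subsets(
    vals: np.ndarray, subsets: list[tuple[int, ...]]
) -> np.ndarray:
    out = np.empty(len(subsets))
    for i, cols in enumerate(subsets):
        sub = vals[:, cols]
        means = sub.mean(axis=1)
        sds = sub.std(axis=1, ddof=1)
        good = means > 0
        out[i] = (sds[good] / means[good]).mean()
    return out


def leave_one_out(
    matrix: ExpressionMatrix,
    features: list[str],
    subset_size: int = 6,
    population: str | None = None,
    normalize: str = "cpm",
    max_subsets: int = 10**6,
) -> LeaveOneOutResult:
    """Mean-CV distributions when each cell is excluded in turn.

    For every cell of the chosen population, all C(n-1, subset_size)
    subsets excluding that cell are enumerated and the mean transcript CV
    computed per subset. The reference distribution uses all C(n,
    subset_size) subsets of the full population.
    """
    if population is None:
        pops = matrix.populations
        population = "HV" if "HV" in pops else pops[0]
    cells = matrix.cells_of(population)
    n = len(cells)
    if n < subset_size + 1:
        raise InsufficientDataError(
            f"population {population!r} has {n} cells; need > subset_size ({subset_size})"
        )
    total = math.comb(n, subset_size)
    if total > max_subsets:
        raise ValueError(
            f"C({n},{subset_size}) = {total} exceeds the cap ({max_subsets}); "
            "consider a sampled analysis instead"
        )
    vals = matrix.normalized(normalize).loc[features, cells].to_numpy(dtype=float)
    all_subsets = list(itertools.combinations(range(n), subset_size))
    reference = _mean_cv_over_subsets(vals, all_subsets)
    per_excluded = {}
    for i, cell in enumerate(cells):
        subsets = [s for s in all_subsets if i not in s]
        per_excluded[cell] = _mean_cv_over_subsets(vals, subsets)
    return LeaveOneOutResult(
        per_excluded=per_excluded,
        reference=reference,
        subset_size=subset_size,
        population=population,
        metadata={"n_cells": n, "normalize": normalize},
    )
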