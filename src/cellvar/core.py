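"""Coefficient-of-variation statistics shared by all analysis stages.

Implements the CV (sample s.d. / mean), resampling-based sample-size
equalization, matched paired CV comparisons between two populations, and
the Levene variance-equality test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CVRecord",
    "PairedCVComparison",
    "InsufficientDataError",
    "NonPositiveMeanError",
    "compute_cv",
    "equalized_cv",
    "paired_cv_comparison",
    "levene_test",
]


class InsufficientDataError(ValueError):
    """Fewer observations than the statistic requires."""


class NonPositiveMeanError(ValueError):
    """CV is undefined for a vector whose mean is not strictly positive."""


@dataclass(frozen=True)
class CVRecord:
    """Per-feature coefficient of variation (sample s.d. / mean)."""

    feature_id: str
    n: int
    mean: float
    sd: float
    cv: float


@dataclass
class PairedCVComparison:
    """Matched per-feature CV comparison between populations a and b.

    ``log_ratio`` is log2(cv_b / cv_a); ``frac_higher_b`` counts strict
    inequalities (ties are not higher).
    """

    feature_ids: list
    cv_a: np.ndarray
    cv_b: np.ndarray
    log_ratio: np.ndarray
    frac_higher_b: float
    t_stat: float
    p_value: float
    sidedness: str
    mean_cv_a: float = float("nan")
    mean_cv_b: float = float("nan")
    metadata: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


def _as_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a one-dimensional vector of measurements")
    if not np.all(np.isfinite(arr)):
        raise ValueError("measurements must be finite")
    return arr


def compute_cv(values, feature_id: str = "", unit: str = "") -> CVRecord:
    """Sample CV (s.d./mean) with the n-1 standard-deviation denominator.

    Raises
    ------
    InsufficientDataError
        If fewer than two observations are supplied.
    NonPositiveMeanError
        If the mean is not strictly positive.
    """
    arr = _as_array(values)
    if arr.size < 2:
        raise InsufficientDataError(
            f"need at least 2 observations for a CV, got {arr.size}"
        )
    mean = float(arr.mean())
    if mean <= 0:
        raise NonPositiveMeanError(f"mean must be positive to form a CV, got {mean}")
    sd = float(arr.std(ddof=1))
    return CVRecord(feature_id=feature_id, n=arr.size, mean=mean, sd=sd, cv=sd / mean)


def equalized_cv(
    groups: Mapping[str, Sequence[float]],
    n_resamples: int = 100,
    seed: int = 0,
) -> dict[str, CVRecord]:
    """CV per group after equalizing sample sizes by repeated subsampling.

    The sampling size ``m`` is the size of the smallest group. Groups of
    exactly ``m`` observations get a direct CV; larger groups are sampled
    ``n_resamples`` times without replacement to ``m`` observations and the
    CVs averaged. One seeded generator drives all draws, so results are
    reproducible given (groups, n_resamples, seed); groups are processed in
    their mapping order.
    """
    if not groups:
        raise InsufficientDataError("no groups supplied")
    arrays = {gid: _as_array(v) for gid, v in groups.items()}
    for gid, arr in arrays.items():
        if arr.size < 2:
            raise InsufficientDataError(f"group {gid!r} has fewer than 2 observations")
    m = min(arr.size for arr in arrays.values())
    rng = np.random.default_rng(seed)
    out: dict[str, CVRecord] = {}
    for gid, arr in arrays.items():
        if arr.size == m:
            out[gid] = compute_cv(arr, feature_id=gid)
            continue
        means = np.empty(n_resamples)
        sds = np.empty(n_resamples)
        cvs = np.empty(n_resamples)
        for i in range(n_resamples):
            draw = rng.choice(arr, size=m, replace=False)
            mu = draw.mean()
            if mu <= 0:
                raise NonPositiveMeanError(
                    f"resample of group {gid!r} has nonpositive mean"
                )
            sd = draw.std(ddof=1)
            means[i], sds[i], cvs[i] = mu, sd, sd / mu
        out[gid] = CVRecord(
            feature_id=gid,
            n=m,
            mean=float(means.mean()),
            sd=float(sds.mean()),
            cv=float(cvs.mean()),
        )
    return out


def _paired_t(diff: np.ndarray, sidedness: str) -> tuple[float, float]:
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            return 0.0, 1.0
        # nonzero constant difference: infinitely strong evidence
        t = math.inf if diff[0] > 0 else -math.inf
        if sidedness == "two_sided":
            return t, 0.0
        return t, 0.0 if t > 0 else 1.0
    t = float(diff.mean() / (sd / math.sqrt(diff.size)))
    df = diff.size - 1
    if sidedness == "two_sided":
        p = 2.0 * float(stats.t.sf(abs(t), df))
    elif sidedness == "one_sided_b_greater":
        p = float(stats.t.sf(t, df))
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return t, min(p, 1.0)


def paired_cv_comparison(
    cv_a,
    cv_b,
    feature_ids: Sequence[str] | None = None,
    sidedness: str = "two_sided",
) -> PairedCVComparison:
    """Paired comparison of matched per-feature CVs (b versus a).

    The t statistic is computed on the differences (cv_b - cv_a); the
    one-sided option tests b > a. Degenerate all-zero differences yield
    t=0, p=1 rather than an error.
    """
    a = _as_array(cv_a)
    b = _as_array(cv_b)
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 3:
        raise InsufficientDataError("need at least 3 matched features")
    if feature_ids is None:
        ids = [str(i) for i in range(a.size)]
    else:
        ids = list(feature_ids)
        if len(ids) != a.size:
            raise ValueError("feature_ids length mismatch")
        if len(set(ids)) != len(ids):
            raise ValueError("feature_ids must be unique")
    if sidedness not in ("two_sided", "one_sided_b_greater"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log2(b / a)
    t, p = _paired_t(b - a, sidedness)
    return PairedCVComparison(
        feature_ids=ids,
        cv_a=a,
        cv_b=b,
        log_ratio=log_ratio,
        frac_higher_b=float(np.mean(b > a)),
        t_stat=t,
        p_value=p,
        sidedness=sidedness,
        mean_cv_a=float(a.mean()),
        mean_cv_b=float(b.mean()),
        metadata={"log_ratio_base": 2, "cv_scale": "raw"},
    )


def levene_test(values_a, values_b, center: str = "mean") -> tuple[float, float]:
    """Levene's variance-equality test on absolute deviations from the center.

    ``center`` selects the classic mean-centered statistic or the
    Brown-Forsythe median-centered variant. Degenerate inputs with zero
    spread in both groups return (0.0, 1.0).
    """
    a = _as_array(values_a)
    b = _as_array(values_b)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("both groups need at least 2 observations")
    if center not in ("mean", "median"):
        raise ValueError(f"center must be 'mean' or 'median', got {center!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = stats.levene(a, b, center=center)
    if math.isnan(stat):
        return 0.0, 1.0
    return float(stat), float(p)
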