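"""Four-bin CV-log-ratio categorization and per-bin gene-set enrichment.

Transcripts are partitioned by the sign of their CV log-ratio in two
independent comparisons (bin 1: non-positive in both; bin 2: positive in
comparison 1 only; bin 3: positive in comparison 2 only; bin 4: positive
in both). Enrichment per (set, bin) is scored with hypergeometric over-
and under-representation tails; a set is flagged relevant when its signed
score is highest in bin 4, lowest in bin 1, and the bin-4 over-
representation p-value passes the cap.

This per-bin hypergeometric scoring is a deliberate, documented
substitution for mutual-information-based pathway scoring; the relevance
rule itself is unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = ["BinAssignment", "EnrichmentResult", "assign_bins", "bin_enrichment"]

BINS = (1, 2, 3, 4)
_TINY = 1e-300


@dataclass
class BinAssignment:
    """Transcript -> bin in {1,2,3,4}, with the input log-ratios kept."""

    bins: pd.Series  # transcript_id -> int bin
    log_ratio_1: pd.Series
    log_ratio_2: pd.Series

    def universe(self) -> list[str]:
        return list(self.bins.index)

    def bin_sizes(self) -> dict[int, int]:
        counts = self.bins.value_counts()
        return {b: int(counts.get(b, 0)) for b in BINS}


@dataclass
class EnrichmentResult:
    """Per-(set, bin) hypergeometric scores plus per-set relevance flags."""

    table: pd.DataFrame  # one row per (set, bin)
    relevant: pd.Series  # set_name -> bool
    skipped: dict = field(default_factory=dict)  # set_name -> reason


def assign_bins(log_ratio_1: pd.Series, log_ratio_2: pd.Series) -> BinAssignment:
    """Assign each transcript in the intersection of both comparisons a bin.

    Zero log-ratios count as non-positive, so the four bins partition the
    universe.
    """
    common = log_ratio_1.index.intersection(log_ratio_2.index)
    if len(common) == 0:
        raise ValueError("no transcripts shared between the two comparisons")
    r1 = log_ratio_1.loc[common].astype(float)
    r2 = log_ratio_2.loc[common].astype(float)
    pos1, pos2 = r1 > 0, r2 > 0
    bins = pd.Series(1, index=common, dtype=int)
    bins[pos1 & ~pos2] = 2
    bins[~pos1 & pos2] = 3
    bins[pos1 & pos2] = 4
    return BinAssignment(bins=bins, log_ratio_1=r1, log_ratio_2=r2)


def _signed_score(overlap: int, expected: float, p_over: float, p_under: float) -> float:
    """-log10(p) signed positive for over-representation."""
    if overlap >= expected:
        return -float(np.log10(max(p_over, _TINY)))
    return float(np.log10(max(p_under, _TINY)))


def bin_enrichment(
    bins: BinAssignment,
    sets: dict[str, list[str]],
    max_p: float = 0.05,
    max_genes: int = 200,
    min_genes: int = 3,
) -> EnrichmentResult:
    """Hypergeometric over/under-representation of each gene set in each bin.

    Sets are intersected with the binned universe first; sets larger than
    ``max_genes`` or smaller than ``min_genes`` after intersection are
    skipped. ``relevant`` requires the signed score to be maximal in bin 4,
    minimal in bin 1, and the bin-4 over-representation p <= ``max_p``.
    A Benjamini-Hochberg column over all over-representation p-values is
    emitted for information only.
    """
    universe = set(bins.universe())
    n_universe = len(universe)
    bin_members = {b: set(bins.bins.index[bins.bins == b]) for b in BINS}
    rows = []
    skipped: dict[str, str] = {}
    for name, members in sets.items():
        inset = set(members) & universe
        if len(inset) < min_genes:
            skipped[name] = f"fewer than {min_genes} members in universe"
            logger.warning("skipping set %s: %s", name, skipped[name])
            continue
        if len(inset) > max_genes:
            skipped[name] = f"more than {max_genes} members in universe"
            continue
        for b in BINS:
            bin_size = len(bin_members[b])
            overlap = len(inset & bin_members[b])
            expected = len(inset) * bin_size / n_universe
            p_over = float(
                hypergeom.sf(overlap - 1, n_universe, bin_size, len(inset))
            )
            p_under = float(
                hypergeom.cdf(overlap, n_universe, bin_size, len(inset))
            )
            rows.append(
                {
                    "set_name": name,
                    "bin": b,
                    "set_size": len(inset),
                    "bin_size": bin_size,
                    "overlap": overlap,
                    "expected": expected,
                    "p_over": p_over,
                    "p_under": p_under,
                    "score": _signed_score(overlap, expected, p_over, p_under),
                }
            )
    if not rows:
        raise ValueError("no gene set passed the size filters")
    table = pd.DataFrame(rows)
    # BH across all over-representation tests, informational only
    p = table["p_over"].to_numpy()
    order = np.argsort(p)
    ranked = np.empty_like(p)
    m = len(p)
    adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    ranked[order] = np.minimum(adj, 1.0)
    table["p_over_bh"] = ranked

    relevant = {}
    for name, sub in table.groupby("set_name"):
        scores = sub.set_index("bin")["score"]
        p4 = float(sub.set_index("bin").loc[4, "p_over"])
        relevant[name] = bool(
            scores.idxmax() == 4 and scores.idxmin() == 1 and p4 <= max_p
        )
    return EnrichmentResult(
        table=table,
        relevant=pd.Series(relevant, name="relevant"),
        skipped=skipped,
    )
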