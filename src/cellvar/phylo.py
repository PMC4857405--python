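"""Clone phylogeny from variant allele frequencies.

Nei's standard genetic distance between population pairs (pairwise-complete
over loci), classic Saitou-Nei neighbor-joining with deterministic
lexicographic tie-breaking, and newick serialization.
"""

from __future__ import annotations

import io
import logging

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "nei_distance",
    "neighbor_joining",
    "to_newick",
    "from_newick",
    "tree_splits",
]


def nei_distance(
    freqs: pd.DataFrame, max_distance: float = 10.0
) -> DistanceMatrix:
    """Nei's standard genetic distance between every pair of populations.

    ``freqs`` holds biallelic alternate-allele frequencies in [0, 1], one
    column per population; missing values are dropped pairwise (loci with a
    missing frequency in either member of a pair are excluded for that pair
    only). For each pair, D = -ln(J_XY / sqrt(J_X * J_Y)) with the J terms
    the mean allele-identity probabilities over shared loci. J_XY = 0 is
    clamped to ``max_distance`` with a warning.
    """
    pops = list(freqs.columns)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    vals = freqs.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("allele frequencies must lie in [0, 1]")
    n = len(pops)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x, y = vals[:, i], vals[:, j]
            ok = ~np.isnan(x) & ~np.isnan(y)
            if not ok.any():
                raise ValueError(
                    f"populations {pops[i]!r} and {pops[j]!r} share no loci"
                )
            px, py = x[ok], y[ok]
            jxy = float(np.mean(px * py + (1 - px) * (1 - py)))
            jx = float(np.mean(px**2 + (1 - px) ** 2))
            jy = float(np.mean(py**2 + (1 - py) ** 2))
            if jxy <= 0:
                logger.warning(
                    "J_XY = 0 for pair (%s, %s); clamping distance to %g",
                    pops[i], pops[j], max_distance,
                )
                dist = max_distance
            else:
                dist = -np.log(jxy / np.sqrt(jx * jy))
                dist = min(max(dist, 0.0), max_distance)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids=pops)


def _clamped_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch estimate to 0, moving the deficit to its sibling."""
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    if lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; exact on additive distance matrices.

    Ties in the Q criterion are broken by lexicographic order of the
    joined nodes' labels, so output is deterministic. Negative branch
    estimates are clamped to zero with the deficit transferred to the
    sibling branch. The result is unrooted, represented with a
    trifurcating root.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("need at least 3 populations")
    d = np.asarray(dm.data, dtype=float)
    if (d < 0).any():
        raise ValueError("distance matrix has negative entries")
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    active = sorted(labels)
    index = {lab: labels.index(lab) for lab in labels}
    dist = {
        (a, b): d[index[a], index[b]] for a in labels for b in labels if a != b
    }

    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist[(a, b)] for b in active if b != a) for a in active}
        best_key = None
        best_pair = None
        for ii in range(n):
            for jj in range(ii + 1, n):
                a, b = active[ii], active[jj]
                q = (n - 2) * dist[(a, b)] - r[a] - r[b]
                key = (q, a, b)  # active is sorted -> lexicographic tie-break
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (a, b)
        a, b = best_pair
        dab = dist[(a, b)]
        la = dab / 2 + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        la, lb = _clamped_pair(la, lb)
        parent = TreeNode()
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length, child_b.length = float(la), float(lb)
        parent.append(child_a)
        parent.append(child_b)
        new_label = f"({a}+{b})"
        nodes[new_label] = parent
        for c in active:
            if c in (a, b):
                continue
            dc = (dist[(a, c)] + dist[(b, c)] - dab) / 2
            dist[(new_label, c)] = dist[(c, new_label)] = max(dc, 0.0)
        active = sorted([c for c in active if c not in (a, b)] + [new_label])

    a, b, c = active
    la = (dist[(a, b)] + dist[(a, c)] - dist[(b, c)]) / 2
    lb = dist[(a, b)] - la
    lc = dist[(a, c)] - la
    root = TreeNode()
    for lab, length in ((a, la), (b, lb), (c, lc)):
        child = nodes.pop(lab)
        child.length = float(max(length, 0.0))
        root.append(child)
    return root


def _quote_label(name: str) -> str:
    specials = set(" ()[]:;,'\t\n")
    if any(ch in specials for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: TreeNode, precision: int = 6) -> str:
    """Standard newick string with branch lengths, ';'-terminated.

    Labels containing reserved characters are single-quoted. Round-trips
    through :func:`from_newick` up to the requested precision.
    """

    def render(node: TreeNode) -> str:
        if node.is_tip():
            if node.name is None:
                raise ValueError("unnamed leaf cannot be serialized")
            body = _quote_label(node.name)
        else:
            body = "(" + ",".join(render(ch) for ch in node.children) + ")"
            if node.name:
                body += _quote_label(node.name)
        if node.length is not None:
            body += f":{node.length:.{precision}f}"
        return body

    return render(tree) + ";"


def from_newick(text: str) -> TreeNode:
    """Parse a newick string into a tree."""
    return TreeNode.read(io.StringIO(text), format="newick")


def tree_splits(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of the leaf set, canonicalized.

    Each internal edge contributes the side not containing the
    lexicographically smallest leaf; useful for unrooted topology
    comparisons.
    """
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    all_leaves = set(leaves)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(frozenset(side))
    return splits
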