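import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from cellvar.phylo import (
    from_newick,
    nei_distance,
    neighbor_joining,
    to_newick,
    tree_splits,
)
from cellvar.simulate import gen_vaf_dataset


class TestNeiDistance:
    def test_identical_columns_zero(self):
        f = pd.DataFrame({"A": [0.2, 0.7, 0.5], "B": [0.2, 0.7, 0.5],
                          "C": [0.9, 0.1, 0.4]})
        dm = nei_distance(f)
        assert dm["A", "B"] == 0.0
        assert dm["A", "C"] > 0

    def test_hand_calculation_single_locus(self):
        f = pd.DataFrame({"X": [1.0], "Y": [0.5]})
        dm = nei_distance(f)
        # J_XY = 0.5, J_X = 1, J_Y = 0.5 -> D = -ln(0.5/sqrt(0.5))
        assert dm["X", "Y"] == pytest.approx(-np.log(0.5 / np.sqrt(0.5)), rel=1e-9)
        assert dm["X", "Y"] == pytest.approx(0.34657, abs=1e-4)

    def test_divergent_pair_clamped(self):
        f = pd.DataFrame({"X": [1.0], "Y": [0.0], "Z": [0.5]})
        dm = nei_distance(f, max_distance=10.0)
        assert dm["X", "Y"] == 10.0

    def test_pairwise_missing_handling(self):
        f = pd.DataFrame({"A": [0.2, np.nan, 0.5], "B": [0.2, 0.7, 0.5],
                          "C": [0.2, 0.7, np.nan]})
        dm = nei_distance(f)
        assert dm["A", "B"] == 0.0  # rows 0 and 2 only

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nei_distance(pd.DataFrame({"A": [1.2], "B": [0.5]}))


def quartet_least_squares_topology(dm: DistanceMatrix) -> frozenset:
    """Brute-force oracle: best-fitting quartet topology by least squares.

    For each of the 3 topologies of 4 taxa, solve for the 5 branch lengths
    minimizing squared error to the 6 pairwise distances; return the
    cherry (as a frozenset) of the winning topology.
    """
    ids = list(dm.ids)
    d = {frozenset(p): dm[p[0], p[1]] for p in itertools.combinations(ids, 2)}
    best = None
    for pair in itertools.combinations(ids, 2):
        cherry = frozenset(pair)
        other = [x for x in ids if x not in cherry]
        a, b = sorted(cherry)
        c, e = sorted(other)
        # branches: a, b, c, e, internal m; path matrix over the 6 distances
        rows, y = [], []
        for x, z in itertools.combinations(ids, 2):
            coef = np.zeros(5)
            for leaf, col in ((a, 0), (b, 1), (c, 2), (e, 3)):
                if leaf in (x, z):
                    coef[col] = 1
            same_side = {x, z} == {a, b} or {x, z} == {c, e}
            if not same_side:
                coef[4] = 1
            rows.append(coef)
            y.append(d[frozenset((x, z))])
        sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
        residual = float(res[0]) if len(res) else float(
            np.sum((np.array(rows) @ sol - np.array(y)) ** 2)
        )
        if best is None or residual < best[0]:
            best = (residual, cherry)
    return best[1]


def additive_quartet_matrix(rng):
    """Random additive 4-taxon matrix plus its generating cherry."""
    ids = list("ABCD")
    cherry = frozenset(rng.choice(ids, size=2, replace=False).tolist())
    lengths = {x: rng.uniform(0.5, 3.0) for x in ids}
    internal = rng.uniform(0.5, 3.0)
    d = np.zeros((4, 4))
    for i, j in itertools.combinations(range(4), 2):
        x, z = ids[i], ids[j]
        dist = lengths[x] + lengths[z]
        if {x, z} != cherry and {x, z} != set(ids) - cherry:
            dist += internal
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids=ids), cherry, lengths, internal


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix([[0, 2, 3], [2, 0, 4], [3, 4, 0]], ids=list("ABC"))
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_additive_quartets_recovered_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            dm, cherry, lengths, internal = additive_quartet_matrix(rng)
            tree = neighbor_joining(dm)
            splits = tree_splits(tree)
            assert len(splits) == 1
            (split,) = splits
            assert split in (cherry, frozenset(dm.ids) - cherry)
            # additive input -> exact branch lengths
            tip_lengths = {t.name: t.length for t in tree.tips()}
            for x in dm.ids:
                assert tip_lengths[x] == pytest.approx(lengths[x], abs=1e-9)
            assert quartet_least_squares_topology(dm) in (
                cherry, frozenset(dm.ids) - cherry
            )

    def test_tie_breaking_deterministic(self):
        d = np.ones((5, 5)) - np.eye(5)
        dm = DistanceMatrix(d, ids=list("ABCDE"))
        t1 = to_newick(neighbor_joining(dm))
        t2 = to_newick(neighbor_joining(dm))
        assert t1 == t2

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix([[0, 2], [2, 0]], ids=list("AB")))

    def test_total_length_matches_additive_distances(self):
        rng = np.random.default_rng(1)
        dm, *_ = additive_quartet_matrix(rng)
        tree = neighbor_joining(dm)
        for x, z in itertools.combinations(dm.ids, 2):
            tx = tree.find(x)
            tz = tree.find(z)
            assert tx.distance(tz) == pytest.approx(dm[x, z], abs=1e-9)

    def test_vaf_topology_recovery(self):
        guide = from_newick("(((A:1,B:1):0.6,(C:1,D:1):0.6):0.4,E:2);")
        true_splits = tree_splits(guide)
        hits = 0
        for s in range(10):
            vaf = gen_vaf_dataset(guide, 10_000, drift_sd=0.05, seed=s)
            tree = neighbor_joining(nei_distance(vaf))
            hits += tree_splits(tree) == true_splits
        assert hits >= 9


class TestNewick:
    def test_three_leaf_render(self):
        dm = DistanceMatrix([[0, 2, 3], [2, 0, 4], [3, 4, 0]], ids=list("ABC"))
        newick = to_newick(neighbor_joining(dm), precision=1)
        assert newick.endswith(";")
        for part in ("A:0.5", "B:1.5", "C:2.5"):
            assert part in newick

    def test_round_trip(self):
        rng = np.random.default_rng(2)
        dm, *_ = additive_quartet_matrix(rng)
        tree = neighbor_joining(dm)
        parsed = from_newick(to_newick(tree, precision=9))
        assert tree_splits(parsed) == tree_splits(tree)
        for tip in tree.tips():
            assert parsed.find(tip.name).length == pytest.approx(tip.length, abs=1e-8)

    def test_label_quoting(self):
        tree = from_newick("(A:1,B:1,C:1);")
        tree.find("A").name = "HV M42"
        out = to_newick(tree)
        assert "'HV M42'" in out
        parsed = from_newick(out)
        assert {t.name for t in parsed.tips()} == {"HV M42", "B", "C"}
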