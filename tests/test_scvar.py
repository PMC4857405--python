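import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cellvar import scvar
from cellvar.core import InsufficientDataError
from cellvar.simulate import SimConfig, gen_sc_dataset

from conftest import make_expression


def small_matrix():
    rng = np.random.default_rng(0)
    vals = rng.lognormal(2, 0.5, size=(20, 12))
    return make_expression(vals, ["A"] * 6 + ["B"] * 6)


class TestQCFilter:
    def _matrix_with_meta(self):
        m = small_matrix()
        m.cells["total_reads"] = 1000
        m.cells["mapped_reads"] = 900
        m.cells["spikein_reads"] = 10
        return m

    def test_empty_cell_excluded(self):
        m = self._matrix_with_meta()
        m.cells.loc["c0", ["total_reads", "mapped_reads", "spikein_reads"]] = 0
        out, report = scvar.qc_filter_cells(m, min_total=0, min_mapped_frac=0,
                                            max_spikein_frac=1)
        assert report.excluded == {"c0": ["empty"]}
        assert "c0" not in out.values.columns

    def test_vacuous_thresholds_keep_all(self):
        m = self._matrix_with_meta()
        out, report = scvar.qc_filter_cells(m, min_total=0, min_mapped_frac=0,
                                            max_spikein_frac=1)
        assert report.n_excluded == 0
        assert out.values.shape == m.values.shape

    def test_one_violation_each(self):
        m = self._matrix_with_meta()
        m.cells.loc["c1", "total_reads"] = 10  # low total
        m.cells.loc["c2", "mapped_reads"] = 10  # low mapped fraction
        out, report = scvar.qc_filter_cells(m, min_total=100, min_mapped_frac=0.5,
                                            max_spikein_frac=1)
        assert set(report.excluded) == {"c1", "c2"}
        assert report.excluded["c1"] == ["low_total_reads"]
        assert report.excluded["c2"] == ["low_mapped_fraction"]
        assert out.values.shape[1] == 10

    def test_removing_whole_population_errors(self):
        m = self._matrix_with_meta()
        for c in m.cells_of("A"):
            m.cells.loc[c, "total_reads"] = 1
        with pytest.raises(InsufficientDataError):
            scvar.qc_filter_cells(m, min_total=100, min_mapped_frac=0,
                                  max_spikein_frac=1)


class TestSpikeinQC:
    def test_identical_populations_give_p_one(self):
        vals = np.tile(np.random.default_rng(1).lognormal(2, 0.5, (10, 5)), (1, 2))
        m = make_expression(vals, ["A"] * 5 + ["B"] * 5, spikein=[True] * 10)
        cmp = scvar.spikein_qc(m)
        assert cmp.p_value == 1.0

    def test_no_spikeins_errors(self):
        with pytest.raises(InsufficientDataError):
            scvar.spikein_qc(small_matrix())

    def test_power_against_inflated_dispersion(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            mu = rng.lognormal(3, 0.5, 20)
            a = rng.poisson(rng.gamma(1 / 0.1, mu[:, None] * 0.1, (20, 10)))
            b = rng.poisson(rng.gamma(1 / 0.3, mu[:, None] * 0.3, (20, 10)))
            m = make_expression(np.hstack([a, b]), ["A"] * 10 + ["B"] * 10,
                                spikein=[True] * 20)
            hits += scvar.spikein_qc(m).p_value < 0.05
        assert hits >= 8


class TestEqualize:
    def test_twelve_and_ten_become_ten(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(2, 0.5, size=(15, 22))
        m = make_expression(vals, ["A"] * 12 + ["B"] * 10)
        out = scvar.equalize_populations(m, seed=1)
        sizes = out.cells.groupby("population").size()
        assert sizes["A"] == sizes["B"] == 10

    def test_equal_sizes_unchanged(self):
        m = small_matrix()
        out = scvar.equalize_populations(m, seed=1)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(2, 0.5, size=(15, 25))
        m = make_expression(vals, ["A"] * 15 + ["B"] * 10)
        o1 = scvar.equalize_populations(m, seed=7)
        o2 = scvar.equalize_populations(m, seed=7)
        assert list(o1.values.columns) == list(o2.values.columns)


class TestFilterTranscripts:
    def test_low_detection_excluded(self):
        vals = np.ones((3, 20)) * 50
        vals[0, :] = 0
        vals[0, :2] = 50  # detected in 10% of cells only, one per population
        vals[0, 10] = 50
        m = make_expression(vals, ["A"] * 10 + ["B"] * 10)
        kept = scvar.filter_transcripts(m, mean_threshold=False)
        assert "f0" not in kept

    def test_absent_from_one_population_excluded(self):
        vals = np.ones((4, 10)) * 30
        vals[1, 5:] = 0  # absent from population B
        m = make_expression(vals, ["A"] * 5 + ["B"] * 5)
        kept = scvar.filter_transcripts(m, mean_threshold=False)
        assert "f1" not in kept

    def test_bimodal_means_keep_upper_mode(self):
        rng = np.random.default_rng(0)
        low = rng.uniform(0.05, 0.15, size=(50, 10))
        high = rng.uniform(80, 120, size=(50, 10))
        m = make_expression(np.vstack([low, high]), ["A"] * 5 + ["B"] * 5)
        kept = scvar.filter_transcripts(m, min_detect_frac=0.0, normalize="none")
        assert set(kept) == {f"f{i}" for i in range(50, 100)}

    def test_spikeins_always_excluded(self):
        vals = np.full((6, 10), 40.0)
        m = make_expression(vals, ["A"] * 5 + ["B"] * 5,
                            spikein=[True, False, False, False, False, False])
        kept = scvar.filter_transcripts(m, mean_threshold=False)
        assert "f0" not in kept


class TestTranscriptCVComparison:
    def test_identical_populations(self):
        half = np.random.default_rng(0).lognormal(2, 0.5, (10, 5))
        m = make_expression(np.hstack([half, half]), ["A"] * 5 + ["B"] * 5)
        cmp = scvar.transcript_cv_comparison(m, [f"f{i}" for i in range(10)])
        assert cmp.frac_higher_b == 0.0
        assert cmp.p_value == 1.0

    def test_brute_force_cv_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(2, 0.4, size=(20, 6))
        m = make_expression(vals, ["A"] * 3 + ["B"] * 3)
        cmp = scvar.transcript_cv_comparison(
            m, [f"f{i}" for i in range(20)], normalize="none"
        )
        for row, fid in enumerate(cmp.feature_ids):
            i = int(fid[1:])
            a = vals[i, :3]
            mean = sum(a) / 3
            sd = math.sqrt(sum((x - mean) ** 2 for x in a) / 2)
            assert cmp.cv_a[row] == pytest.approx(sd / mean, abs=1e-10)

    def test_inflated_recovery(self):
        hits = 0
        for s in range(10):
            m, _, _, _ = gen_sc_dataset(SimConfig(seed=s, inflation_factor=2.0))
            feats = scvar.filter_transcripts(m, mean_threshold=False)
            cmp = scvar.transcript_cv_comparison(
                m, feats, sidedness="one_sided_b_greater"
            )
            hits += cmp.frac_higher_b > 0.53 and cmp.p_value < 1e-6
        assert hits >= 9

    def test_per_cell_scaling_invariant_only_with_normalization(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(2, 0.4, size=(15, 8))
        m = make_expression(vals, ["A"] * 4 + ["B"] * 4)
        scaled = vals.copy()
        scaled[:, 0] *= 10
        ms = make_expression(scaled, ["A"] * 4 + ["B"] * 4)
        feats = [f"f{i}" for i in range(15)]
        c1 = scvar.transcript_cv_comparison(m, feats, normalize="cpm")
        c2 = scvar.transcript_cv_comparison(ms, feats, normalize="cpm")
        np.testing.assert_allclose(c1.cv_a, c2.cv_a, rtol=1e-9)
        r1 = scvar.transcript_cv_comparison(m, feats, normalize="none")
        r2 = scvar.transcript_cv_comparison(ms, feats, normalize="none")
        assert not np.allclose(r1.cv_a, r2.cv_a)


class TestSubsampleStability:
    def test_full_population_matches_direct_comparison(self):
        m, _, _, _ = gen_sc_dataset(SimConfig(seed=0, inflation_factor=2.0))
        feats = scvar.filter_transcripts(m, mean_threshold=False)
        direct = scvar.transcript_cv_comparison(
            m, feats, sidedness="one_sided_b_greater"
        )
        st = scvar.subsample_stability(m, feats, [10], seed=0)
        assert st.table.loc[10, "p_value"] == pytest.approx(direct.p_value, rel=1e-6)

    def test_significant_down_to_five_cells(self):
        hits = 0
        for s in range(10):
            m, _, _, _ = gen_sc_dataset(SimConfig(seed=s, inflation_factor=2.0))
            feats = scvar.filter_transcripts(m, mean_threshold=False)
            st = scvar.subsample_stability(m, feats, [5], seed=s)
            hits += st.table.loc[5, "p_value"] < 0.05
        assert hits >= 9

    def test_log_ratio_sign_stable_across_set_sizes(self):
        stable = 0
        for s in range(10):
            m, _, _, _ = gen_sc_dataset(SimConfig(seed=s, inflation_factor=2.0))
            feats = scvar.filter_transcripts(m, mean_threshold=False)
            st = scvar.subsample_stability(m, feats, [5, 7, 9], seed=s)
            stable += (st.table["mean_log_ratio"] > 0).all()
        assert stable >= 9

    def test_oversized_set_rejected(self):
        m, _, _, _ = gen_sc_dataset(SimConfig(seed=0))
        with pytest.raises(ValueError):
            scvar.subsample_stability(m, ["gene_00001"], [50], seed=0)


class TestLeaveOneOut:
    def test_counts_match_binomial_coefficients(self):
        m, _, _, _ = gen_sc_dataset(SimConfig(seed=0))
        feats = scvar.filter_transcripts(m, mean_threshold=False)
        loo = scvar.leave_one_out(m, feats, subset_size=6, population="HV")
        assert len(loo.per_excluded) == 10
        for dist in loo.per_excluded.values():
            assert len(dist) == math.comb(9, 6)  # 84
        assert len(loo.reference) == math.comb(10, 6)

    def test_boundary_single_subset(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(2, 0.4, size=(10, 14))
        m = make_expression(vals, ["A"] * 7 + ["B"] * 7)
        loo = scvar.leave_one_out(m, [f"f{i}" for i in range(10)],
                                  subset_size=6, population="A")
        assert all(len(d) == 1 for d in loo.per_excluded.values())

    def test_cap_enforced(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(2, 0.4, size=(5, 30))
        m = make_expression(vals, ["A"] * 30)
        with pytest.raises(ValueError, match="cap"):
            scvar.leave_one_out(m, [f"f{i}" for i in range(5)],
                                subset_size=10, population="A", max_subsets=100)

    def test_exclusions_dominate_lv_reference(self, inflated_sc_dataset):
        from scipy.stats import mannwhitneyu

        m, _, _, _ = inflated_sc_dataset
        feats = scvar.filter_transcripts(m, mean_threshold=False)
        hv = scvar.leave_one_out(m, feats, subset_size=6, population="HV")
        lv = scvar.leave_one_out(m, feats, subset_size=6, population="LV")
        for cell, dist in hv.per_excluded.items():
            p = mannwhitneyu(dist, lv.reference, alternative="greater").pvalue
            assert p < 0.05, cell
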