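import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regnetrank import specificity as gs
from regnetrank.synthetic import make_null_matrix, make_planted_matrix

from oracles import fisher_two_sided, welch_reference


class TestZnormalizeRows:
    def test_constant_row_zeros(self):
        m = pd.DataFrame([[2.0, 2.0, 2.0]], index=["t"], columns=list("abc"))
        assert (gs.znormalize_rows(m).loc["t"] == 0).all()

    def test_two_point_row(self):
        m = pd.DataFrame([[1.0, 3.0]], index=["t"], columns=list("ab"))
        z = gs.znormalize_rows(m)
        assert z.loc["t", "a"] == pytest.approx(-np.sqrt(0.5))
        assert z.loc["t", "b"] == pytest.approx(np.sqrt(0.5))

    def test_row_means_zero(self, rng):
        m = pd.DataFrame(rng.uniform(size=(20, 6)))
        assert np.abs(gs.znormalize_rows(m).mean(axis=1)).max() < 1e-12


class TestActiveTfs:
    def test_constant_top_row_selected(self):
        m = pd.DataFrame(
            np.vstack([np.full(5, 10.0)] + [np.arange(1, 6) * 0.1 * i for i in range(1, 10)]),
            index=[f"T{i}" for i in range(10)],
        )
        assert "T0" in gs.find_active_tfs(m)

    def test_high_cv_excluded(self):
        rows = [np.full(5, 1.0) for _ in range(9)]
        spiky = np.array([0.0001, 0.0001, 0.0001, 0.0001, 60.0])  # highest mean, CV >> 0.5
        m = pd.DataFrame(rows + [spiky], index=[f"T{i}" for i in range(10)])
        assert "T9" not in gs.find_active_tfs(m)

    def test_matches_brute_force(self, rng):
        m = pd.DataFrame(
            10.0 ** rng.normal(-3, 1, size=(20, 8)), index=[f"T{i}" for i in range(20)]
        )
        got = set(gs.find_active_tfs(m, top_fraction=0.10, cv_max=0.5))
        means = m.mean(axis=1)
        expected = set()
        n_top = int(np.ceil(0.10 * 20))
        top = means.sort_values(ascending=False).index[:n_top]
        for tf in m.index:
            cv = m.loc[tf].std(ddof=1) / means[tf]
            if tf in top and cv < 0.5:
                expected.add(tf)
        assert got == expected


class TestLognormality:
    def test_lognormal_scores_mostly_pass(self):
        """Log-normal data passes Shapiro-Wilk in ~the nominal fraction."""
        fractions = []
        for seed in range(20):
            m = make_null_matrix(n_tfs=40, n_cols=40, seed=seed)
            design = gs.GroupDesign(
                target=set(m.columns[:20]), background=set(m.columns[20:])
            )
            fractions.append(gs.lognormality_fraction(m, design))
        assert np.mean(fractions) >= 0.9

    def test_identical_values_count_as_fail(self):
        m = pd.DataFrame(np.ones((1, 8)), index=["t"], columns=[f"c{i}" for i in range(8)])
        design = gs.GroupDesign(target={"c0", "c1", "c2", "c3"}, background={"c4", "c5", "c6", "c7"})
        assert gs.lognormality_fraction(m, design) == 0.0

    def test_contaminated_rows_rejected_more(self):
        rng = np.random.default_rng(5)
        clean = 10.0 ** rng.normal(0, 0.5, size=(60, 24))
        heavy = 10.0 ** np.clip(rng.standard_t(df=1, size=(60, 24)) * 0.5, -5, 5)
        cols = [f"c{i}" for i in range(24)]
        design = gs.GroupDesign(target=set(cols[:12]), background=set(cols[12:]))
        f_clean = gs.lognormality_fraction(pd.DataFrame(clean, columns=cols), design)
        f_heavy = gs.lognormality_fraction(pd.DataFrame(heavy, columns=cols), design)
        assert f_heavy < f_clean


class TestSpecificTfs:
    def test_null_type_i_rate_calibrated(self):
        m = make_null_matrix(n_tfs=1000, n_cols=20, seed=3)
        design = gs.GroupDesign(target=set(m.columns[:6]), background=set(m.columns[6:]))
        calls = gs.specific_tfs(m, design, p_cut=0.05)
        rate = calls["passed"].mean()
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rate - 0.05) < 3 * se

    def test_exact_twofold_zero_variance(self):
        m = pd.DataFrame(
            [np.concatenate([np.full(4, 2e-3), np.full(8, 1e-3)])],
            index=["t"],
            columns=[f"c{i}" for i in range(12)],
        )
        design = gs.GroupDesign(target=set(m.columns[:4]), background=set(m.columns[4:]))
        calls = gs.specific_tfs(m, design, *gs.CUTOFF_TIERS["lineage"])
        assert calls.loc["t", "pvalue"] == 0.0
        assert calls.loc["t", "log2_fc"] == pytest.approx(1.0)
        assert not calls.loc["t", "passed"]  # strict inequality at the boundary

    def test_small_target_uses_one_sample_test(self):
        m = make_null_matrix(n_tfs=5, n_cols=10, seed=0)
        design = gs.GroupDesign(target=set(m.columns[:2]), background=set(m.columns[2:]))
        calls = gs.specific_tfs(m, design, 0.1)
        assert (calls["test"] == "one_sample").all()

    def test_scale_invariance(self):
        m = make_null_matrix(n_tfs=50, n_cols=12, seed=9)
        design = gs.GroupDesign(target=set(m.columns[:4]), background=set(m.columns[4:]))
        a = gs.specific_tfs(m, design, 0.01, 0.5)
        b = gs.specific_tfs(m * 37.5, design, 0.01, 0.5)
        assert np.allclose(a["pvalue"], b["pvalue"])
        assert np.allclose(a["log2_fc"], b["log2_fc"])

    def test_welch_matches_independent_reference(self, rng):
        m = make_null_matrix(n_tfs=200, n_cols=15, seed=2)
        design = gs.GroupDesign(target=set(m.columns[:5]), background=set(m.columns[5:]))
        calls = gs.specific_tfs(m, design, 0.05)
        t_cols = sorted(design.target)
        b_cols = sorted(design.background)
        for tf in m.index[:: 10]:
            _, p_ref = welch_reference(
                np.log10(m.loc[tf, t_cols].to_numpy()), np.log10(m.loc[tf, b_cols].to_numpy())
            )
            assert calls.loc[tf, "pvalue"] == pytest.approx(p_ref, abs=1e-10)

    def test_excluded_samples_left_out_of_background(self):
        m = make_null_matrix(n_tfs=20, n_cols=10, seed=4)
        design_all = gs.GroupDesign(target=set(m.columns[:3]), background=set(m.columns[3:]))
        design_excl = gs.GroupDesign(
            target=set(m.columns[:3]),
            background=set(m.columns[3:]),
            excluded={m.columns[9]},
        )
        manual = gs.GroupDesign(target=set(m.columns[:3]), background=set(m.columns[3:9]))
        a = gs.specific_tfs(m, design_excl, 0.1)
        b = gs.specific_tfs(m, manual, 0.1)
        assert np.allclose(a["pvalue"], b["pvalue"])
        c = gs.specific_tfs(m, design_all, 0.1)
        assert not np.allclose(a["pvalue"], c["pvalue"])

    def test_nonpositive_scores_rejected(self):
        m = pd.DataFrame([[0.0, 1.0, 1.0, 1.0]], index=["t"], columns=list("abcd"))
        design = gs.GroupDesign(target={"a"}, background={"b", "c", "d"})
        with pytest.raises(ValueError, match="log undefined"):
            gs.specific_tfs(m, design, 0.1)


class TestFilterGeneList:
    def test_empty_list_is_identity(self):
        calls = pd.DataFrame({"passed": [True]}, index=["A"])
        pd.testing.assert_frame_equal(gs.filter_gene_list(calls, []), calls)

    def test_full_overlap_empties(self):
        calls = pd.DataFrame({"passed": [True, False]}, index=["A", "B"])
        assert gs.filter_gene_list(calls, ["A", "B"]).empty

    def test_unknown_symbol_noop_with_warning(self, caplog):
        calls = pd.DataFrame({"passed": [True]}, index=["A"])
        with caplog.at_level("WARNING"):
            out = gs.filter_gene_list(calls, ["Zzz"])
        assert len(out) == 1


class TestBalancedResampling:
    def test_deterministic_under_seed(self):
        m, _ = make_planted_matrix(seed=1)
        target = [c for c in m.columns if c.startswith("mem")]
        pool = [c for c in m.columns if c.startswith("bg")]
        a = gs.balanced_resampling(m, target, pool, n_reps=100, seed=42)
        b = gs.balanced_resampling(m, target, pool, n_reps=100, seed=42)
        pd.testing.assert_series_equal(a, b)

    def test_constant_tf_has_zero_frequency(self):
        m, _ = make_planted_matrix(seed=2)
        m.loc["TF0100"] = 1e-3
        target = [c for c in m.columns if c.startswith("mem")]
        pool = [c for c in m.columns if c.startswith("bg")]
        freq = gs.balanced_resampling(m, target, pool, n_reps=50, seed=0)
        assert freq["TF0100"] == 0.0

    def test_planted_memory_drivers_rank_top(self):
        hits = 0
        n_seeds = 4
        for seed in range(n_seeds):
            m, drivers = make_planted_matrix(seed=seed)
            target = [c for c in m.columns if c.startswith("mem")]
            pool = [c for c in m.columns if c.startswith("bg")]
            freq = gs.balanced_resampling(m, target, pool, n_reps=200, seed=seed)
            top = set(freq.index[: 2 * len(drivers)])
            hits += len(top & set(drivers)) / len(drivers)
        assert hits / n_seeds >= 0.8

    def test_small_pool_rejected(self):
        m, _ = make_planted_matrix(background_cols=2, seed=0)
        with pytest.raises(ValueError, match="pool"):
            gs.balanced_resampling(m, ["mem1", "mem2", "mem3"], ["bg1", "bg2"])


class TestFisherOverlap:
    def test_identical_lists_match_enumeration(self):
        a = [f"T{i}" for i in range(5)]
        odds, p = gs.fisher_overlap(a, a, universe_size=100)
        p_ref = fisher_two_sided(5, 0, 0, 95)
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_disjoint_lists_not_significant(self):
        a = [f"A{i}" for i in range(3)]
        b = [f"B{i}" for i in range(3)]
        _, p = gs.fisher_overlap(a, b, universe_size=1000)
        assert p > 0.5

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(25):
            universe = int(rng.integers(20, 120))
            na, nb = int(rng.integers(1, 12)), int(rng.integers(1, 12))
            pool = [f"T{i}" for i in range(universe)]
            a = list(rng.choice(pool, size=na, replace=False))
            b = list(rng.choice(pool, size=nb, replace=False))
            _, p = gs.fisher_overlap(a, b, universe)
            inter = len(set(a) & set(b))
            p_ref = fisher_two_sided(inter, na - inter, nb - inter, universe - na - nb + inter)
            assert p == pytest.approx(p_ref, rel=1e-9)

    def test_impossible_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            gs.fisher_overlap(["a", "b"], ["c"], universe_size=2)
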