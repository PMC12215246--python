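"""Paired moderated tests, BH, DMP bookkeeping, enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methrhythm import generate_methylation
from methrhythm.differential_methylation import (
    EBayesHyperparams,
    HEADLINE_THRESHOLD,
    THRESHOLD_GRID,
    bh_adjust,
    count_dmps,
    fit_ebayes,
    map_to_genes,
    moderated_f,
    moderated_t,
    overrepresentation_test,
    paired_differences,
    paired_moderated_tests,
    read_gmt,
    select_top_dmps,
)
from methrhythm.synthetic_data import PlantedTruthConfig


class TestPairedDifferences:
    def test_default_design_gives_eight_pairs_with_time_awake(self,
                                                              default_dataset):
        _, info = paired_differences(
            default_dataset.m_values, default_dataset.sample_sheet
        )
        assert list(info.index) == list(range(1, 9))
        np.testing.assert_allclose(
            info["time_awake"].values, [8, 11, 14, 17, 20, 23, 26, 29]
        )

    def test_differences_equal_direct_subtraction(self, default_dataset):
        m = default_dataset.m_values
        sheet = default_dataset.sample_sheet
        diffs, _ = paired_differences(m, sheet)
        subj, pair = "s05", 3
        a = m.values[sheet.index[(sheet["subject"] == subj)
                                 & (sheet["sampling_index"] == 11)][0]]
        b = m.values[sheet.index[(sheet["subject"] == subj)
                                 & (sheet["sampling_index"] == 3)][0]]
        np.testing.assert_allclose(diffs[pair][subj].values, (a - b).values)

    def test_identical_windows_give_zero_differences(self, default_dataset):
        m = default_dataset.m_values
        sheet = default_dataset.sample_sheet.copy()
        half = m.values.copy()
        # overwrite the sleep-deprivation half with the baseline half
        for subj, block in sheet.groupby("subject"):
            b = block.sort_values("sampling_index")
            half[b.index[8:]] = half[b.index[:8]].values
        from conftest import toy_matrix

        diffs, _ = paired_differences(
            type(m)(half, m.scale, sheet), sheet
        )
        for d in diffs.values():
            np.testing.assert_allclose(d.values, 0.0, atol=1e-15)

    def test_missing_member_drops_subject_with_warning(self, default_dataset):
        m = default_dataset.m_values
        sheet = default_dataset.sample_sheet
        drop = sheet.index[(sheet["subject"] == "s02")
                           & (sheet["sampling_index"] == 9)]
        sub = m.subset_samples([c for c in m.values.columns if c not in drop])
        with pytest.warns(UserWarning, match="s02"):
            diffs, _ = paired_differences(sub, sub.sheet)
        assert "s02" not in diffs[1].columns
        assert "s02" in diffs[2].columns


class TestEmpiricalBayes:
    def test_matches_reference_limma_values(self):
        """Frozen oracle: hyperparameters and moderated t computed with
        the Bioconductor limma eBayes implementation on this exact
        seeded fixture."""
        rng = np.random.default_rng(42)
        sd = rng.lognormal(-1.0, 0.5, size=30)
        D = rng.normal(0, 1, size=(30, 8)) * sd[:, None]
        D[:5] += 0.8
        hyper = fit_ebayes(np.var(D, axis=1, ddof=1), df=7)
        assert hyper.d0 == pytest.approx(2.95920060356, rel=1e-9)
        assert hyper.s0_sq == pytest.approx(0.0813698348067, rel=1e-9)
        res = moderated_t(pd.DataFrame(D), hyper)
        np.testing.assert_allclose(
            res["t"].values[:6],
            [5.942684656, 12.40665622, 6.658366185, 3.608039991,
             14.10248708, -0.7765854485],
            rtol=1e-8,
        )
        np.testing.assert_allclose(
            res["p"].values[:6],
            [1.450006778e-4, 2.220659899e-7, 5.761223185e-5,
             4.815171348e-3, 6.603472386e-8, 4.554516494e-1],
            rtol=1e-8,
        )

    def test_zero_prior_df_is_ordinary_paired_t(self):
        rng = np.random.default_rng(1)
        D = rng.normal(size=(1000, 15))
        res = moderated_t(pd.DataFrame(D), EBayesHyperparams(0.0, 1.0))
        t_ref, p_ref = stats.ttest_1samp(D, 0.0, axis=1)
        np.testing.assert_allclose(res["t"].values, t_ref, atol=1e-10)
        np.testing.assert_allclose(res["p"].values, p_ref, atol=1e-10)

    def test_infinite_prior_df_pools_every_probe(self):
        rng = np.random.default_rng(2)
        D = rng.normal(size=(50, 10))
        hyper = EBayesHyperparams(np.inf, 0.5)
        res = moderated_t(pd.DataFrame(D), hyper)
        np.testing.assert_allclose(res["posterior_s_sq"].values, 0.5)

    def test_type_one_error_calibrated_under_null(self):
        """5000 heteroscedastic null probes, 15 subjects: type-I error at
        alpha = 0.05 within [0.045, 0.055], p-values KS-uniform."""
        rng = np.random.default_rng(3)
        sd = rng.lognormal(0.0, 0.4, size=5000)
        D = rng.normal(size=(5000, 15)) * sd[:, None]
        res = moderated_t(pd.DataFrame(D))
        rate = (res["p"] < 0.05).mean()
        assert 0.045 <= rate <= 0.055
        assert stats.kstest(res["p"].values, "uniform").pvalue > 0.01

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            fit_ebayes(np.zeros(20), df=7)


class TestModeratedF:
    def test_single_contrast_reduces_to_t_squared(self):
        rng = np.random.default_rng(4)
        D = pd.DataFrame(rng.normal(size=(200, 12)))
        hyper = fit_ebayes(D.var(axis=1, ddof=1).values, 11)
        f = moderated_f({1: D}, hyper)
        t = moderated_t(D, hyper)
        np.testing.assert_allclose(f["F"].values, t["t"].values ** 2,
                                   rtol=1e-10)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        diffs = {j: pd.DataFrame(rng.normal(size=(2000, 10)))
                 for j in range(1, 9)}
        res = moderated_f(diffs)
        assert stats.kstest(res["p"].values, "uniform").pvalue > 0.01

    def test_joint_test_beats_single_pair_on_late_effects(self):
        """An effect present only at the last two pairs: the joint F picks
        it up more often than a single early-pair t at matched alpha."""
        rng = np.random.default_rng(6)
        n_probes = 600
        diffs = {}
        for j in range(1, 9):
            D = rng.normal(size=(n_probes, 12))
            if j >= 7:
                D += 0.8
            diffs[j] = pd.DataFrame(D)
        f_res = moderated_f(diffs)
        t_res = moderated_t(diffs[1])
        alpha = 0.01
        assert (f_res["p"] < alpha).mean() > (t_res["p"] < alpha).mean()


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.03])), [0.03])

    def test_equal_ps_stay_equal(self):
        q = bh_adjust(np.full(7, 0.02))
        np.testing.assert_allclose(q, 0.02)

    def test_small_vector_against_step_up_enumeration(self):
        p = np.array([0.01, 0.02, 0.04, 0.05])
        # direct step-up: q_i = min over j>=i of m*p_(j)/j
        m = 4
        expect = [min(m * pj / (j + 1) for j, pj in enumerate(p) if pj >= pi)
                  for pi in p]
        np.testing.assert_allclose(bh_adjust(p), expect)

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(2, 400))
            _, q_ref, *_ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_adjust(p), q_ref, atol=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0),
                    min_size=1, max_size=50))
    def test_order_invariant_and_monotone(self, p_list):
        p = np.array(p_list)
        q = bh_adjust(p)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p[perm]), q[perm], atol=1e-12)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.1, 1.5]))


class TestDmpBookkeeping:
    def _records(self):
        return pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(10)],
                "pair": 8,
                "time_awake": 29.0,
                "p": [1e-9, 1e-6, 2e-5, 4e-4, 4e-4, 3e-3, 0.02, 0.2, 0.6, 0.9],
                "delta": [-1, -1, -1, 1, -2, 1, -1, 1, -1, 1],
                "direction": ["hypo", "hypo", "hypo", "hyper", "hypo",
                              "hyper", "hypo", "hyper", "hypo", "hyper"],
            }
        )

    def test_counts_match_manual_tally(self):
        grid = count_dmps(self._records())
        row = grid.loc[8]
        assert row["n_p_lt_5e-08"] == 1
        assert row["n_p_lt_5e-06"] == 2
        assert row["n_p_lt_0.0005"] == 5
        assert row["n_p_lt_0.05"] == 7
        # monotone along the grid
        counts = [row[f"n_p_lt_{t:g}"] for t in THRESHOLD_GRID]
        assert counts == sorted(counts)

    def test_direction_split_at_headline_threshold(self):
        row = count_dmps(self._records()).loc[8]
        assert row["n_hypo"] == 4 and row["n_hyper"] == 1
        assert row["hypo_share"] == pytest.approx(0.8)

    def test_empty_records_give_zero_grid(self):
        grid = count_dmps(self._records().iloc[:0])
        assert grid.empty

    def test_expected_null_line(self):
        row = count_dmps(self._records()).loc[8]
        assert row["expected_p_lt_0.05"] == pytest.approx(0.5)

    def test_grid_monotone_on_simulated_study(self, default_dataset):
        records, _ = paired_moderated_tests(
            default_dataset.m_values, default_dataset.sample_sheet
        )
        grid = count_dmps(records)
        for _, row in grid.iterrows():
            counts = [row[f"n_p_lt_{t:g}"] for t in THRESHOLD_GRID]
            assert counts == sorted(counts)

    def test_planted_hypomethylation_share_recovered(self):
        """70% of drift-affected probes planted negative: the hypo share
        among significant final-pair DMPs lands near 0.70."""
        cfg = PlantedTruthConfig(
            class_proportions={"arrhy": 1.0},
            drift_fraction=1.0,
            drift_magnitude=0.8,
            hypo_fraction=0.70,
            noise_sd=0.25,
            noise_sd_spread=0.0,
        )
        ds = generate_methylation(truth_config=cfg, n_probes=1500, seed=77,
                                  cellcounts=False)
        records, _ = paired_moderated_tests(ds.m_values, ds.sample_sheet)
        final = records[records["pair"] == 8]
        sig = final[final["p"] < HEADLINE_THRESHOLD]
        assert len(sig) > 300
        share = (sig["direction"] == "hypo").mean()
        assert abs(share - 0.70) < 3 * np.sqrt(0.7 * 0.3 / len(sig)) + 0.02


class TestTopSelection:
    def test_zero_n_empty(self):
        recs = pd.DataFrame({"probe_id": ["a"], "p": [0.1], "delta": [1.0]})
        assert len(select_top_dmps(recs, 0)) == 0

    def test_p_ties_broken_by_abs_delta_then_id(self):
        recs = pd.DataFrame(
            {
                "probe_id": ["b", "a", "c", "d"],
                "p": [0.01, 0.01, 0.01, 0.001],
                "delta": [0.5, -2.0, 0.5, 0.1],
            }
        )
        top = select_top_dmps(recs, 3)
        assert list(top["probe_id"]) == ["d", "a", "b"]

    def test_overlong_request_warns_and_returns_all(self):
        recs = pd.DataFrame({"probe_id": ["a"], "p": [0.1], "delta": [1.0]})
        with pytest.warns(UserWarning):
            assert len(select_top_dmps(recs, 5)) == 1

    def test_many_to_one_gene_mapping(self):
        manifest = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(6)],
                "gene": ["G1", "G1", "G2", "G3", "G3", "G3"],
            }
        )
        genes, report = map_to_genes([f"p{i}" for i in range(6)], manifest)
        assert genes == ["G1", "G2", "G3"]
        assert report.loc["G3", "n_probes"] == 3


class TestOverrepresentation:
    def test_perfect_overlap_is_most_significant(self):
        universe = [f"g{i}" for i in range(100)]
        sets = {"hit": universe[:10], "other": universe[50:80]}
        res = overrepresentation_test(universe[:10], sets, universe)
        assert res.index[0] == "hit"
        assert res.loc["hit", "p"] < res.loc["other", "p"]

    def test_p_equals_hypergeometric_tail(self):
        universe = [f"g{i}" for i in range(755)]
        gene_list = universe[:100]
        gene_set = universe[80:130]  # overlap 20
        res = overrepresentation_test(gene_list, {"s": gene_set}, universe)
        oracle = stats.hypergeom.sf(19, 755, 50, 100)
        assert res.loc["s", "p"] == pytest.approx(oracle, rel=1e-12)
        assert res.loc["s", "n_overlap"] == 20

    def test_random_lists_give_uniformish_p(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(400)]
        gene_set = list(rng.choice(universe, size=60, replace=False))
        ps = []
        for _ in range(300):
            gl = list(rng.choice(universe, size=50, replace=False))
            res = overrepresentation_test(gl, {"s": gene_set}, universe)
            ps.append(res.loc["s", "p"])
        # discrete p-values are super-uniform: check the rejection rate
        assert (np.array(ps) < 0.05).mean() <= 0.08

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text(
            "FAS_signalling\tapoptosis\tMAPK10\tDFFB\tJUN\tSCIN\tPARP4\tLMNA\n"
            "tiny\tdesc\tG1\tG2\n"
        )
        sets = read_gmt(path)
        assert sets["FAS_signalling"] == ["MAPK10", "DFFB", "JUN", "SCIN",
                                          "PARP4", "LMNA"]
        assert len(sets) == 2

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation_test(["g1"], {"s": ["g1"]}, [])
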