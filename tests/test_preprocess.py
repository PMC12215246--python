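"""I/O round trips, probe filtering accounting, window split, scaling."""

import numpy as np
import pandas as pd
import pytest

from methrhythm import preprocess as pp
from methrhythm.preprocess import (
    MethylationMatrix,
    ProbeMask,
    apply_probe_filters,
    read_matrix,
    residualize_covariates,
    split_conditions,
    window_length,
    write_matrix,
    zscore_per_probe,
)

from conftest import toy_matrix


class TestMatrixIO:
    def test_round_trip_preserves_values_and_order(self, tmp_path):
        rng = np.random.default_rng(0)
        m = toy_matrix(rng.uniform(0, 1, size=(3, 4)), scale=pp.BETA)
        path = tmp_path / "m.tsv"
        write_matrix(m, path)
        back = read_matrix(path, scale=pp.BETA)
        pd.testing.assert_frame_equal(
            m.values, back.values, check_names=False
        )

    def test_duplicate_probe_id_named_in_error(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("probe_id\ts1\ts2\ncgX\t0.1\t0.2\ncgX\t0.3\t0.4\n")
        with pytest.raises(ValueError, match="cgX"):
            read_matrix(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("probe_id\ts1\ts2\ncgA\t0.1\toops\n")
        with pytest.raises(ValueError):
            read_matrix(path)

    def test_chunked_read_streams_array_scale_file(self, tmp_path):
        """A file at full EPIC-array row count streams through the chunked
        reader; values on a sampled subset match the written source."""
        n_rows, n_cols = 818_027, 4
        path = tmp_path / "big.tsv"
        rng = np.random.default_rng(1)
        probe = np.arange(n_rows)
        cols = rng.uniform(size=(4, n_cols))  # 4 distinct rows, tiled
        with open(path, "w") as fh:
            fh.write("probe_id\t" + "\t".join(f"s{j}" for j in range(n_cols)) + "\n")
            for i in probe:
                row = cols[i % 4]
                fh.write(f"cg{i:07d}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
        m = read_matrix(path, chunksize=100_000)
        assert m.n_probes == n_rows
        for i in rng.integers(0, n_rows, size=20):
            np.testing.assert_allclose(
                m.values.iloc[int(i)].values, np.round(cols[int(i) % 4], 6)
            )

    def test_scale_tag_validated(self):
        with pytest.raises(ValueError, match="scale"):
            toy_matrix([[0.5, 0.5]], scale="banana")


class TestProbeFilters:
    def test_array_scale_removal_percentage(self):
        """Removing 48,064 of 864,935 probes is 5.557% of the array:
        5.56 to two decimals (a printed 5.55 reflects coarser rounding)."""
        rep = pp.FilterReport(n_input=864_935, n_removed=48_064,
                              n_surviving=816_871)
        assert rep.pct_removed == pytest.approx(100 * 48_064 / 864_935)
        assert rep.pct_removed_2dp == 5.56
        assert round(rep.pct_removed, 1) == 5.6

    def test_empty_mask_is_identity(self):
        m = toy_matrix(np.arange(12.0).reshape(3, 4))
        mask = ProbeMask(pd.Series(dtype=str))
        out, rep = apply_probe_filters(m, mask)
        pd.testing.assert_frame_equal(out.values, m.values)
        assert rep.n_removed == 0

    def test_counts_conserved_per_reason(self):
        m = toy_matrix(np.arange(40.0).reshape(10, 4))
        mask = ProbeMask(pd.Series(
            {"p0": "detection", "p3": "snp", "p7": "detection"}
        ))
        out, rep = apply_probe_filters(m, mask)
        assert out.n_probes == 7
        assert rep.per_reason == {"detection": 2, "snp": 1}
        assert rep.n_input == rep.n_surviving + sum(rep.per_reason.values())

    def test_unknown_mask_ids_warn_and_are_ignored(self):
        m = toy_matrix(np.arange(8.0).reshape(2, 4))
        mask = ProbeMask(pd.Series({"p0": "snp", "nope": "snp"}))
        with pytest.warns(UserWarning, match="not present"):
            out, rep = apply_probe_filters(m, mask)
        assert rep.n_removed == 1

    def test_removing_everything_errors(self):
        m = toy_matrix(np.arange(8.0).reshape(2, 4))
        mask = ProbeMask(pd.Series({"p0": "snp", "p1": "snp"}))
        with pytest.raises(ValueError, match="every probe"):
            apply_probe_filters(m, mask)


class TestSplitConditions:
    def test_default_design_gives_nine_sample_windows(self, default_dataset):
        base, sd = split_conditions(
            default_dataset.methylation, default_dataset.sample_sheet
        )
        sheet = default_dataset.sample_sheet
        n_subj = sheet["subject"].nunique()
        assert base.n_samples == 9 * n_subj
        assert sd.n_samples == 9 * n_subj
        overlap = base.values.columns.intersection(sd.values.columns)
        idx = sheet.loc[overlap, "sampling_index"].unique()
        assert sorted(idx) == [8, 9]
        # each window spans a full inclusive 24 h
        for win in (base, sd):
            per_subj = win.sheet.groupby("subject")["sampling_index"].count()
            assert (per_subj == 9).all()

    @pytest.mark.parametrize("n,interval", [(16, 3.0), (10, 3.0), (26, 2.0)])
    def test_overlap_size_follows_index_arithmetic(self, n, interval):
        """Overlap between the two windows is 2w - n samples when positive."""
        w = window_length(n, interval)
        overlap = max(2 * w - n, 0)
        assert overlap == w - (n - w)

    def test_incomplete_subject_listed_in_error(self, default_dataset):
        m = default_dataset.methylation
        drop = m.sheet.index[
            (m.sheet["subject"] == "s03") & (m.sheet["sampling_index"] == 5)
        ]
        sub = m.subset_samples([c for c in m.values.columns if c not in drop])
        with pytest.raises(ValueError, match="s03"):
            split_conditions(sub, sub.sheet)


class TestZscore:
    def test_row_mean_zero_sd_one(self):
        m = toy_matrix([[1.0, 2.0, 3.0]])
        z, flags = zscore_per_probe(m)
        assert z.values.values.mean() == pytest.approx(0.0)
        assert z.values.values.std(ddof=1) == pytest.approx(1.0)
        assert not flags.any()

    def test_constant_row_flagged_and_zeroed(self):
        m = toy_matrix([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        z, flags = zscore_per_probe(m)
        assert flags["p0"] and not flags["p1"]
        assert np.all(z.values.loc["p0"] == 0.0)

    def test_idempotent(self, default_dataset):
        z1, _ = zscore_per_probe(default_dataset.m_values)
        z2, _ = zscore_per_probe(z1)
        np.testing.assert_allclose(
            z1.values.values, z2.values.values, atol=1e-12
        )

    def test_zscore_not_invariant_to_subject_subsetting(self, default_dataset):
        """Pooled scaling depends on which subjects are present: z-scoring
        then subsetting differs from subsetting then z-scoring."""
        m = default_dataset.m_values
        keep = m.sheet.index[m.sheet["subject"] != "s01"]
        z_then_sub, _ = zscore_per_probe(m)
        z_then_sub = z_then_sub.subset_samples(keep)
        sub_then_z, _ = zscore_per_probe(m.subset_samples(keep))
        assert not np.allclose(
            z_then_sub.values.values, sub_then_z.values.values
        )


class TestResidualize:
    def _sheet(self, n=12):
        return pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(n)],
                "condition": ["baseline"] * n,
                "sampling_index": 1,
                "clock_time": 0.0,
                "batch": ["b1"] * (n // 2) + ["b2"] * (n // 2),
                "age": np.linspace(20, 30, n),
            },
            index=pd.Index([f"x{i}" for i in range(n)], name="sample_id"),
        )

    def test_planted_batch_offset_removed(self):
        sheet = self._sheet()
        rng = np.random.default_rng(2)
        base = rng.normal(size=(5, 12))
        shifted = base + 0.3 * (sheet["batch"] == "b2").values
        m = toy_matrix(shifted, sheet=sheet)
        clean = residualize_covariates(m, ["batch"])
        expect = base - base.mean(axis=1, keepdims=True) + \
            shifted.mean(axis=1, keepdims=True)
        # batch offset gone; within-batch structure intact up to centering
        got = clean.values.values
        b2 = (sheet["batch"] == "b2").values
        assert abs(got[:, b2].mean() - got[:, ~b2].mean()) < 1e-10

    def test_residuals_orthogonal_to_design(self):
        sheet = self._sheet()
        rng = np.random.default_rng(3)
        m = toy_matrix(rng.normal(size=(4, 12)), sheet=sheet)
        out = residualize_covariates(m, ["batch", "age"])
        resid = out.values.values - out.values.values.mean(axis=1, keepdims=True)
        age = sheet["age"].values - sheet["age"].mean()
        assert np.allclose(resid @ age, 0.0, atol=1e-8)

    def test_aliased_covariates_rejected(self):
        sheet = self._sheet()
        sheet["copy"] = sheet["age"]
        m = toy_matrix(np.zeros((2, 12)), sheet=sheet)
        with pytest.raises(ValueError, match="rank-deficient"):
            residualize_covariates(m, ["age", "copy"])
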