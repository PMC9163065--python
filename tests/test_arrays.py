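"""IO, validation, QC filtering and beta summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methretain import (
    BetaMatrix,
    apply_detection_filter,
    read_beta_matrix,
    read_manifest,
    read_sample_sheet,
    summarize_beta,
    write_beta_matrix,
)
from methretain.errors import (
    EmptyDataError,
    FormatError,
    SampleLookupError,
    ValidationError,
)

from conftest import make_betas


class TestManifest:
    def test_round_trip_fields_and_promoter_flag(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(
            "probe_id,chromosome,position,genomic_context,strand\n"
            "cg0001,chrX,1000,TSS200,+\n"
            "cg0002,chr2,500,body,-\n"
        )
        m = read_manifest(p)
        assert m.loc["cg0001", "chromosome"] == "chrX"
        assert m.loc["cg0001", "position"] == 1000
        assert bool(m.loc["cg0001", "is_promoter"])
        assert not bool(m.loc["cg0002", "is_promoter"])

    @pytest.mark.parametrize(
        "row",
        [
            "cg0001,chr23,1000,TSS200,+",   # unknown chromosome
            "cg0001,chr1,0,TSS200,+",        # 0-based position
            "cg0001,chr1,1000,exon,+",       # unknown context
        ],
    )
    def test_bad_rows_rejected(self, tmp_path, row):
        p = tmp_path / "m.csv"
        p.write_text("probe_id,chromosome,position,genomic_context,strand\n" + row + "\n")
        with pytest.raises(ValidationError):
            read_manifest(p)

    def test_duplicate_probe_id_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(
            "probe_id,chromosome,position,genomic_context\n"
            "cg0001,chr1,10,body\ncg0001,chr1,20,body\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_manifest(p)

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("probe_id,chromosome,position\ncg0001,chr1,10\n")
        with pytest.raises(FormatError, match="genomic_context"):
            read_manifest(p)


class TestBetaMatrixIO:
    def test_parse_shape_and_values(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("probe_id\ts1\ts2\ncg1\t0.1\t0.9\ncg2\t0.9\t0.1\n")
        b = read_beta_matrix(p)
        assert (b.n_probes, b.n_samples) == (2, 2)
        assert b.sample("s1")["cg1"] == 0.1

    def test_out_of_range_cell_locates_probe_and_sample(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("probe_id\ts1\ncg1\t1.2\n")
        with pytest.raises(ValidationError, match="cg1.*s1"):
            read_beta_matrix(p)

    def test_na_cells_become_missing_and_are_excluded(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("probe_id\ts1\ncg1\tNA\ncg2\t0.5\n")
        b = read_beta_matrix(p)
        assert np.isnan(b.sample("s1")["cg1"])
        assert summarize_beta(b, "s1").n_probes_used == 1

    def test_write_read_round_trip(self, tmp_path):
        vals = np.array([[0.123456, np.nan], [0.9, 0.0]])
        b = make_betas(vals)
        path = tmp_path / "out.tsv"
        write_beta_matrix(b, path)
        b2 = read_beta_matrix(path)
        assert b2.probe_ids.equals(b.probe_ids)
        np.testing.assert_allclose(
            b2.values.to_numpy(), b.values.to_numpy(), rtol=1e-5
        )

    def test_unknown_sample_lookup(self):
        with pytest.raises(SampleLookupError):
            make_betas([[0.5]]).sample("nope")


class TestDetectionFilter:
    def test_probe_failing_in_one_sample_removed(self):
        b = make_betas([[0.1, 0.2], [0.3, 0.4], [0.5, 0.6]])
        p = make_betas([[0.01, 0.06], [0.01, 0.01], [0.02, 0.05]])
        filtered, n_removed = apply_detection_filter(b, p, 0.05)
        assert n_removed == 1
        assert list(filtered.probe_ids) == ["cg0001", "cg0002"]

    def test_all_passing_is_identity(self):
        b = make_betas([[0.1], [0.9]])
        p = make_betas([[0.01], [0.01]])
        filtered, n_removed = apply_detection_filter(b, p, 0.05)
        assert n_removed == 0
        assert filtered.values.equals(b.values)

    def test_matches_brute_force_scan_and_is_idempotent(self):
        rng = np.random.default_rng(42)
        n = 50
        b = make_betas(rng.random((n, 4)))
        pvals = rng.random((n, 4)) * 0.1
        p = make_betas(pvals)
        filtered, n_removed = apply_detection_filter(b, p, 0.05)
        # independent per-probe scan oracle
        expect_keep = [i for i in range(n) if all(pvals[i, j] <= 0.05 for j in range(4))]
        assert filtered.n_probes == len(expect_keep)
        assert n_removed == n - len(expect_keep)
        assert list(filtered.probe_ids) == [f"cg{i:04d}" for i in expect_keep]
        # idempotence: filtering again removes nothing
        p2 = BetaMatrix(p.values.loc[filtered.probe_ids], validate=False)
        again, removed_again = apply_detection_filter(filtered, p2, 0.05)
        assert removed_again == 0
        assert again.values.equals(filtered.values)

    def test_shape_mismatch_rejected(self):
        b = make_betas([[0.1], [0.2]])
        p = make_betas([[0.01]])
        with pytest.raises(ValidationError):
            apply_detection_filter(b, p, 0.05)


class TestBetaSummary:
    def test_symmetric_and_constant_cases(self):
        b = make_betas(np.array([[0.0], [0.5], [1.0]]))
        s = summarize_beta(b, "s0")
        assert s.mean == pytest.approx(0.5)
        assert s.median == pytest.approx(0.5)
        c = make_betas(np.full((10, 1), 0.7))
        sc = summarize_beta(c, "s0")
        assert (sc.p5, sc.q25, sc.median, sc.q75, sc.p95) == (0.7,) * 5

    def test_matches_sort_based_oracle_on_mixture(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.beta(2, 18, 500), rng.beta(18, 2, 500)])
        s = summarize_beta(make_betas(vals[:, None]), "s0")
        srt = np.sort(vals)

        def quantile_sorted(q):  # linear interpolation between order statistics
            pos = q * (len(srt) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            return srt[lo] + (pos - lo) * (srt[hi] - srt[lo])

        assert s.median == pytest.approx(quantile_sorted(0.5), abs=1e-12)
        assert s.q25 == pytest.approx(quantile_sorted(0.25), abs=1e-12)
        assert s.p95 == pytest.approx(quantile_sorted(0.95), abs=1e-12)
        assert s.mean == pytest.approx(vals.mean())

    def test_all_missing_column_is_empty_data_error(self):
        b = make_betas(np.array([[np.nan], [np.nan]]))
        with pytest.raises(EmptyDataError):
            summarize_beta(b, "s0")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=200))
    def test_order_statistic_chain_invariant(self, values):
        s = summarize_beta(make_betas(np.array(values)[:, None]), "s0")
        assert s.p5 <= s.q25 <= s.median <= s.q75 <= s.p95
        assert 0.0 <= s.p5 and s.p95 <= 1.0


class TestSampleSheet:
    def test_read_and_validate(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(
            "sample_id,group,sex,tissue\nA,parental,male,cell_line\n"
            "B,normal_tissue,female,colon\n"
        )
        s = read_sample_sheet(p)
        assert s.loc["B", "sex"] == "female"

    def test_bad_group_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,group,sex,tissue\nA,weird,male,colon\n")
        with pytest.raises(ValidationError):
            read_sample_sheet(p)
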