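"""Sex-aware classification of retained promoter probes."""

import numpy as np
import pandas as pd
import pytest

from methretain import (
    classification_summary,
    classify_probe,
    classify_probes,
    de_novo_chromosome_share,
    locus_profile,
    select_retained_promoter_probes,
)
from methretain import SimulationConfig, simulate_dataset
from methretain.classify import DE_NOVO, METHYLATED_NORMAL, UNCLASSIFIED
from methretain.errors import EmptyDataError
from methretain.simulate import config_with

from conftest import make_betas, make_manifest


class TestSelection:
    def test_promoter_and_both_high_required(self):
        manifest = make_manifest(
            [
                ("p1", "chr1", 10, "TSS200"),   # promoter, both high -> in
                ("p2", "chr1", 20, "TSS1500"),  # promoter, lost -> out
                ("p3", "chr1", 30, "body"),     # both high, not promoter -> out
            ]
        )
        betas = make_betas(
            [[0.9, 0.75], [0.9, 0.3], [0.9, 0.9]],
            ["p1", "p2", "p3"], ["par", "res"],
        )
        sel = select_retained_promoter_probes(betas, manifest, "par", "res", 0.7)
        assert list(sel) == ["p1"]


class TestClassifyProbe:
    @pytest.mark.parametrize(
        "male,female,chrom,expected",
        [
            (0.05, 0.50, "chrX", DE_NOVO),          # XCI pattern in tissue
            (0.05, 0.05, "chrX", DE_NOVO),          # escapes XCI, both unmethylated
            (0.92, 0.88, "chrX", METHYLATED_NORMAL),
            (0.40, 0.40, "chrX", UNCLASSIFIED),     # fits neither rule
            (0.05, 0.05, "chr2", DE_NOVO),          # autosomal symmetric rule
            (0.05, 0.50, "chr2", UNCLASSIFIED),     # monoallelic band is chrX-only
            (0.85, 0.90, "chr2", METHYLATED_NORMAL),
        ],
    )
    def test_category_rules(self, male, female, chrom, expected):
        assert classify_probe(male, female, 0.90, 0.85, chrom) == expected

    def test_cell_line_cutoff_gates_every_category(self):
        # losing methylation in the resistant line -> unclassified regardless
        assert classify_probe(0.05, 0.5, 0.90, 0.30, "chrX") == UNCLASSIFIED
        assert classify_probe(0.9, 0.9, 0.60, 0.90, "chr1") == UNCLASSIFIED


class TestClassifyProbes:
    def test_requires_both_sexes(self, small_dataset):
        samples = small_dataset.samples
        males_only = samples[
            (samples["group"] != "normal_tissue") | (samples["sex"] == "male")
        ]
        with pytest.raises(EmptyDataError):
            classify_probes(
                small_dataset.betas, small_dataset.manifest, males_only,
                "parental_1", "resistant_1",
            )

    def test_recovers_ground_truth_normal_state(self, small_dataset):
        calls = classify_probes(
            small_dataset.betas, small_dataset.manifest, small_dataset.samples,
            "parental_1", "resistant_1",
        )
        assert len(calls) > 20
        truth = small_dataset.truth.loc[calls.index, "normal_state"]
        expected = truth.map(
            {
                "normal_unmethylated": DE_NOVO,
                "x_inactivation_pattern": DE_NOVO,
                "normal_methylated": METHYLATED_NORMAL,
            }
        )
        accuracy = (calls["category"] == expected).mean()
        assert accuracy >= 0.99

    def test_accuracy_degrades_as_components_merge(self, small_config):
        accuracies = []
        # push the unmethylated and methylated components toward each other
        for low, high in [((2, 18), (18, 2)), ((3, 6), (6, 3)), ((3, 4), (4, 3))]:
            cfg = config_with(
                small_config, beta_shape_low=low, beta_shape_high=high
            )
            ds = simulate_dataset(cfg)
            calls = classify_probes(
                ds.betas, ds.manifest, ds.samples, "parental_1", "resistant_1"
            )
            if calls.empty:
                accuracies.append(0.0)
                continue
            truth = ds.truth.loc[calls.index, "normal_state"]
            expected = truth.map(
                {
                    "normal_unmethylated": DE_NOVO,
                    "x_inactivation_pattern": DE_NOVO,
                    "normal_methylated": METHYLATED_NORMAL,
                }
            )
            accuracies.append((calls["category"] == expected).mean())
        assert accuracies[0] > accuracies[1] > accuracies[2]

    def test_invariant_to_sample_order_within_sex(self, small_dataset):
        samples = small_dataset.samples
        shuffled = pd.concat([samples.iloc[::-1]])
        a = classify_probes(
            small_dataset.betas, small_dataset.manifest, samples,
            "parental_1", "resistant_1",
        )
        b = classify_probes(
            small_dataset.betas, small_dataset.manifest, shuffled,
            "parental_1", "resistant_1",
        )
        assert a["category"].equals(b["category"])


def build_calls(n_de_novo, n_meth, n_chrx_de_novo, n_chrx_meth):
    """Synthetic call table with the given category/chromosome counts."""
    rows = []
    for i in range(n_de_novo):
        chrom = "chrX" if i < n_chrx_de_novo else "chr1"
        rows.append((f"d{i}", chrom, DE_NOVO))
    for i in range(n_meth):
        chrom = "chrX" if i < n_chrx_meth else "chr1"
        rows.append((f"m{i}", chrom, METHYLATED_NORMAL))
    df = pd.DataFrame(rows, columns=["probe_id", "chromosome", "category"])
    return df.set_index("probe_id")


class TestSummary:
    def test_published_count_arithmetic(self):
        # 1257 retained promoter probes, 112 de novo of which 31 on chrX;
        # chrX alone holds 119 probes with 31 de novo
        calls = build_calls(112, 1145, 31, 88)
        genome = classification_summary(calls, "genome_wide")
        assert genome.n_total == 1257
        assert round(genome.pct_de_novo) == 9
        chrx = classification_summary(calls, "chrX_only")
        assert chrx.n_total == 119
        assert round(chrx.pct_de_novo) == 26
        assert round(de_novo_chromosome_share(calls)) == 28

    def test_boundary_single_category(self):
        calls = build_calls(5, 0, 0, 0)
        assert classification_summary(calls).pct_de_novo == 100.0
        calls = build_calls(0, 5, 0, 0)
        assert classification_summary(calls).pct_de_novo == 0.0

    def test_counts_always_sum_to_total(self, small_dataset):
        calls = classify_probes(
            small_dataset.betas, small_dataset.manifest, small_dataset.samples,
            "parental_1", "resistant_1",
        )
        s = classification_summary(calls)
        assert s.n_de_novo + s.n_methylated_normal + s.n_unclassified == s.n_total


class TestLocusProfile:
    def test_extraction_ordered_by_position(self, small_dataset):
        m = small_dataset.manifest
        chrx = m[m["chromosome"] == "chrX"].sort_values("position")
        window = chrx.iloc[10:14]
        lo, hi = int(window["position"].min()), int(window["position"].max())
        prof = locus_profile(small_dataset.betas, m, "chrX", lo, hi)
        assert list(prof.index) == list(window.index)
        assert prof["position"].is_monotonic_increasing

    def test_reversed_interval_normalized(self, small_dataset):
        m = small_dataset.manifest
        a = locus_profile(small_dataset.betas, m, "chr1", 1, 50000)
        b = locus_profile(small_dataset.betas, m, "chr1", 50000, 1)
        assert a.equals(b)

    def test_matches_linear_scan_on_random_regions(self, small_dataset):
        m = small_dataset.manifest
        rng = np.random.default_rng(2)
        for _ in range(20):
            chrom = rng.choice(["chr1", "chr7", "chrX"])
            lo = int(rng.integers(1, 200000))
            hi = lo + int(rng.integers(1, 100000))
            prof = locus_profile(small_dataset.betas, m, chrom, lo, hi)
            scan = [
                pid
                for pid, row in m.iterrows()
                if row["chromosome"] == chrom and lo <= row["position"] <= hi
            ]
            scan.sort(key=lambda pid: m.loc[pid, "position"])
            assert list(prof.index) == scan

    def test_empty_region_gives_empty_table(self, small_dataset):
        prof = locus_profile(
            small_dataset.betas, small_dataset.manifest, "chr2", 1, 2
        )
        assert prof.index.empty

    def test_group_means_appended(self, small_dataset):
        samples = small_dataset.samples
        groups = {
            "normal_female": list(
                samples.index[
                    (samples["group"] == "normal_tissue") & (samples["sex"] == "female")
                ]
            )
        }
        m = small_dataset.manifest
        prof = locus_profile(small_dataset.betas, m, "chrX", 1, 10**9, groups)
        assert "mean_normal_female" in prof.columns
        assert prof["mean_normal_female"].between(0, 1).all()
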