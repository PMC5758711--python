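"""Region filtering, nearest-TSS search, feature/state labels, metaprofiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import regions_frame
from emtlink import annotate
from emtlink.annotate import (
    AnnotationInputError,
    annotate_chromatin_state,
    classify_feature,
    distance_bin_proportions,
    filter_regions,
    gene_min_region_distance,
    nearest_tss,
    tss_metaprofile,
)
from oracles import nearest_tss_allpairs


class TestFilter:
    def test_inclusive_boundary(self):
        regions = regions_frame(
            [
                ("chr1", 0, 100, "r1", 12.2),
                ("chr1", 200, 300, "r2", 12.1),
                ("chr1", 400, 500, "r3", 30.0),
            ]
        )
        kept = filter_regions(regions)
        assert kept["region_id"].tolist() == ["r1", "r3"]

    def test_zero_threshold_is_identity(self):
        regions = regions_frame([("chr1", 0, 100, "r1", 0.0)])
        assert len(filter_regions(regions, min_tags=0)) == 1

    def test_all_below_threshold_empty(self):
        regions = regions_frame([("chr1", 0, 100, "r1", 1.0)])
        assert len(filter_regions(regions, min_tags=50)) == 0


class TestNearestTss:
    def test_basic_assignment_and_sign(self, toy_genes):
        regions = regions_frame([("chr1", 1200, 1500, "r1", 20.0)])  # centre 1350
        out = nearest_tss(regions, toy_genes)
        assert out["nearest_gene_id"].iloc[0] == "g1"
        assert out["signed_distance"].iloc[0] == 350.0

    def test_equidistant_tie_breaks_to_smaller_gene_id(self):
        genes = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "tss": [1000, 2000],
                "strand": ["+", "+"],
                "gene_id": ["g1", "g2"],
            }
        )
        regions = regions_frame([("chr1", 1400, 1601, "r1", 20.0)])  # centre 1500
        out = nearest_tss(regions, genes)
        assert out["nearest_gene_id"].iloc[0] == "g1"

    def test_upstream_of_plus_strand_is_negative(self, toy_genes):
        regions = regions_frame([("chr1", 850, 951, "r1", 20.0)])  # centre 900
        out = nearest_tss(regions, toy_genes)
        assert out["signed_distance"].iloc[0] == -100.0

    def test_upstream_of_minus_strand_is_negative(self, toy_genes):
        # g4 on chr2 at 2000, minus strand; centre 2100 is upstream on gene strand
        regions = regions_frame([("chr2", 2050, 2151, "r1", 20.0)])
        out = nearest_tss(regions, toy_genes)
        assert out["nearest_gene_id"].iloc[0] == "g4"
        assert out["signed_distance"].iloc[0] == -100.0

    def test_chromosome_without_genes_gets_sentinel(self, toy_genes):
        regions = regions_frame([("chrX", 0, 100, "r1", 20.0)])
        out = nearest_tss(regions, toy_genes)
        assert out["nearest_gene_id"].iloc[0] == "no_gene"
        assert np.isnan(out["abs_distance"].iloc[0])

    def test_matches_all_pairs_oracle_on_random_instances(self, rng):
        """Exact agreement with a brute-force all-pairs scan, tie-breaks included."""
        for _ in range(10):
            n_g, n_r = 300, 300
            chroms = rng.choice(["chr1", "chr2", "chr3"], n_g)
            genes = pd.DataFrame(
                {
                    "chrom": chroms,
                    "tss": rng.integers(0, 50_000, n_g),
                    "strand": rng.choice(["+", "-"], n_g),
                    "gene_id": [f"g{i:04d}" for i in rng.permutation(n_g)],
                }
            )
            starts = rng.integers(0, 50_000, n_r)
            regions = regions_frame(
                [
                    (c, s, s + w, f"r{i}", 20.0)
                    for i, (c, s, w) in enumerate(
                        zip(rng.choice(["chr1", "chr2", "chr3"], n_r), starts,
                            rng.integers(50, 500, n_r))
                    )
                ]
            )
            out = nearest_tss(regions, genes)
            centers = (regions["start"] + regions["end"]) // 2
            expected = nearest_tss_allpairs(
                centers, regions["chrom"], genes["tss"], genes["chrom"], genes["gene_id"]
            )
            assert out["nearest_gene_id"].tolist() == [e[0] for e in expected]
            got = out["abs_distance"].tolist()
            want = [e[1] for e in expected]
            assert all(
                (np.isnan(a) and np.isnan(b)) or a == b for a, b in zip(got, want)
            )


class TestFeatures:
    def test_promoter_outranks_track_features(self, toy_genes):
        track = pd.DataFrame(
            [("chr1", 0, 5000, "exon")], columns=["chrom", "start", "end", "feature"]
        )
        regions = regions_frame([("chr1", 1400, 1601, "r1", 20.0)])  # 500 bp from g1
        assert classify_feature(regions, toy_genes, track)[0] == "promoter"

    def test_exactly_1kb_from_tss_is_not_promoter(self, toy_genes):
        regions = regions_frame([("chr1", 5950, 6051, "r1", 20.0)])  # centre 6000
        # g2 TSS 3000 is 3000 away; g1 is 5000 away; no promoter
        assert classify_feature(regions, toy_genes)[0] == "intergenic"
        exact = regions_frame([("chr1", 1950, 2051, "r1", 20.0)])  # centre 2000: 1000 from g1
        assert classify_feature(exact, toy_genes)[0] == "intergenic"
        inside = regions_frame([("chr1", 1949, 2050, "r1", 20.0)])  # centre 1999
        assert classify_feature(inside, toy_genes)[0] == "promoter"

    def test_center_in_no_interval_is_intergenic(self, toy_genes):
        regions = regions_frame([("chr2", 900_000, 900_100, "r1", 20.0)])
        assert classify_feature(regions, toy_genes)[0] == "intergenic"

    def test_priority_order_on_stacked_track(self, toy_genes):
        track = pd.DataFrame(
            [
                ("chr1", 5000, 9000, "intron"),
                ("chr1", 5500, 6500, "exon"),
                ("chr1", 5900, 6100, "5utr"),
            ],
            columns=["chrom", "start", "end", "feature"],
        )
        regions = regions_frame([("chr1", 5950, 6051, "r1", 20.0)])
        assert classify_feature(regions, toy_genes, track)[0] == "5utr"

    def test_labels_partition_regions(self, small_cfg):
        from emtlink import simulate

        genes = simulate.generate_genome(small_cfg)
        _, truth = simulate.generate_expression(genes, small_cfg)
        regions, _, _ = simulate.generate_peaks(genes, truth, small_cfg)
        labels = classify_feature(regions["A"], genes)
        assert labels.value_counts().sum() == len(regions["A"])


class TestStates:
    STATES = pd.DataFrame(
        [
            ("chr1", 0, 1000, "active_promoter"),
            ("chr1", 1000, 2000, "repressed"),
        ],
        columns=["chrom", "start", "end", "state"],
    )

    def test_max_overlap_wins(self):
        regions = regions_frame([("chr1", 400, 1400, "r1", 20.0)])  # 600 vs 400 bp
        assert annotate_chromatin_state(regions, self.STATES)[0] == "active_promoter"

    def test_no_overlap_is_none(self):
        regions = regions_frame([("chr1", 5000, 5100, "r1", 20.0)])
        assert annotate_chromatin_state(regions, self.STATES)[0] == "none"

    def test_even_split_takes_left_segment(self):
        regions = regions_frame([("chr1", 500, 1500, "r1", 20.0)])  # 500/500
        assert annotate_chromatin_state(regions, self.STATES)[0] == "active_promoter"

    def test_overlapping_segments_rejected(self):
        bad = pd.DataFrame(
            [("chr1", 0, 1000, "a"), ("chr1", 900, 2000, "b")],
            columns=["chrom", "start", "end", "state"],
        )
        regions = regions_frame([("chr1", 0, 100, "r1", 20.0)])
        with pytest.raises(AnnotationInputError):
            annotate_chromatin_state(regions, bad)


class TestDistanceBins:
    def test_worked_example(self, toy_genes):
        # region 200 bp from g1 (tss 1000 -> centre 1200), 8 kb from g3
        regions = regions_frame(
            [("chr1", 1150, 1251, "r1", 20.0), ("chr1", 17_950, 18_051, "r2", 20.0)]
        )
        out = distance_bin_proportions(
            regions,
            toy_genes,
            {"all": {"g1", "g2", "g3", "g4"}},
            bins=[1000, 10_000, 100_000],
        )
        assert out["proportion"].tolist() == [0.25, 0.75, 0.75]

    def test_no_regions_all_zero(self, toy_genes):
        regions = regions_frame([])
        out = distance_bin_proportions(
            regions, toy_genes, {"all": {"g1", "g2"}}, bins=[1000, 10_000]
        )
        assert (out["proportion"] == 0).all()

    def test_empty_subset_is_undefined(self, toy_genes):
        regions = regions_frame([("chr1", 0, 100, "r1", 20.0)])
        out = distance_bin_proportions(regions, toy_genes, {"empty": set()}, bins=[1000])
        assert np.isnan(out["proportion"]).all()

    def test_matches_exhaustive_pairwise_scan(self, rng):
        """Agreement with a brute-force gene x region scan on random instances."""
        for _ in range(50):
            n_g, n_r = 30, 20
            genes = pd.DataFrame(
                {
                    "chrom": rng.choice(["chr1", "chr2"], n_g),
                    "tss": rng.integers(0, 100_000, n_g),
                    "strand": "+",
                    "gene_id": [f"g{i}" for i in range(n_g)],
                }
            )
            regions = regions_frame(
                [
                    (c, s, s + 100, f"r{i}", 20.0)
                    for i, (c, s) in enumerate(
                        zip(rng.choice(["chr1", "chr2"], n_r), rng.integers(0, 100_000, n_r))
                    )
                ]
            )
            bins = [1000, 10_000, 50_000]
            subset = set(rng.choice([f"g{i}" for i in range(n_g)], 15, replace=False))
            out = distance_bin_proportions(regions, genes, {"s": subset}, bins)
            centers = ((regions["start"] + regions["end"]) // 2).to_numpy()
            for b, got in zip(bins, out["proportion"]):
                hits = 0
                for _, g in genes.iterrows():
                    if g["gene_id"] not in subset:
                        continue
                    same = regions["chrom"].to_numpy() == g["chrom"]
                    if same.any() and np.abs(centers[same] - g["tss"]).min() <= b:
                        hits += 1
                assert got == hits / len(subset)

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.integers(1, 100_000), min_size=2, max_size=6, unique=True))
    def test_proportions_monotone_in_bin_size(self, bins):
        genes = pd.DataFrame(
            {
                "chrom": ["chr1"] * 5,
                "tss": [100, 5000, 20_000, 44_000, 90_000],
                "strand": "+",
                "gene_id": [f"g{i}" for i in range(5)],
            }
        )
        regions = regions_frame(
            [("chr1", 1000, 1100, "r1", 20.0), ("chr1", 60_000, 60_100, "r2", 20.0)]
        )
        out = distance_bin_proportions(
            regions, genes, {"all": set(genes["gene_id"])}, sorted(bins)
        )
        props = out["proportion"].to_numpy()
        assert (np.diff(props) >= 0).all()


class TestMetaprofile:
    GENES = pd.DataFrame(
        {
            "chrom": ["chr1"],
            "tss": [10_000],
            "strand": ["+"],
            "gene_id": ["g1"],
        }
    )

    def test_uniform_coverage_gives_flat_profile(self):
        cov = pd.DataFrame(
            [("chr1", 0, 100_000, 2.0)], columns=["chrom", "start", "end", "value"]
        )
        prof = tss_metaprofile(cov, self.GENES)
        assert prof.shape == (30,)
        assert np.allclose(prof, 200.0)

    def test_block_at_tss_peaks_at_center_bin(self):
        cov = pd.DataFrame(
            [("chr1", 10_000, 10_100, 5.0)], columns=["chrom", "start", "end", "value"]
        )
        prof = tss_metaprofile(cov, self.GENES)
        assert int(np.argmax(prof)) == 15  # first bin downstream of the TSS

    def test_minus_strand_profile_is_mirrored(self):
        cov = pd.DataFrame(
            [("chr1", 10_200, 10_400, 3.0)], columns=["chrom", "start", "end", "value"]
        )
        plus = tss_metaprofile(cov, self.GENES)
        minus_genes = self.GENES.assign(strand="-")
        minus = tss_metaprofile(cov, minus_genes)
        assert np.allclose(minus, plus[::-1])

    def test_out_of_bounds_window_skipped(self):
        genes = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "tss": [500, 10_000], "strand": "+",
             "gene_id": ["edge", "ok"]}
        )
        cov = pd.DataFrame(
            [("chr1", 0, 100_000, 1.0)], columns=["chrom", "start", "end", "value"]
        )
        prof = tss_metaprofile(cov, genes)
        assert np.allclose(prof, 100.0)  # only the interior gene contributes


def test_gene_min_region_distance_matches_direct_scan(toy_genes):
    regions = regions_frame(
        [("chr1", 1150, 1251, "r1", 20.0), ("chr2", 0, 101, "r2", 20.0)]
    )
    out = gene_min_region_distance(regions, toy_genes)
    assert out["g1"] == 200
    assert out["g2"] == 1800
    assert out["g3"] == 8800
    assert out["g4"] == 1950
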