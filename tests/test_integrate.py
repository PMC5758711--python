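"""Target classification, exact tests, and CSC contingency statistics."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emtlink import simulate
from emtlink.integrate import (
    IntegrationInputError,
    classify_targets,
    csc_proximity_bias,
    csc_sensitivity_bias,
    fisher_exact_2x2,
    hypergeom_enrichment,
)
from oracles import fisher_two_sided_enum, hypergeom_upper_enum


class TestClassifyTargets:
    def _run(self, sens, dist, **kw):
        return classify_targets(
            pd.Series(sens, index=list("abc")[: len(sens)]),
            pd.Series(dist, index=list("abc")[: len(dist)]),
            **kw,
        )

    def test_sensitive_near_gene_is_direct(self):
        out = self._run([True], [4000.0])
        assert out["directness"].iloc[0] == "direct"

    def test_sensitive_far_gene_is_indirect(self):
        out = self._run([True], [6000.0])
        assert out["directness"].iloc[0] == "indirect"

    def test_insensitive_gene_is_untargeted_even_with_binding(self):
        out = self._run([False], [100.0])
        assert out["directness"].iloc[0] == "untargeted"

    def test_threshold_inclusive_at_5000(self):
        out = self._run([True], [5000.0])
        assert out["directness"].iloc[0] == "direct"

    def test_counts_partition_universe(self):
        out = self._run([True, True, False], [1000.0, np.inf, 10.0])
        assert out["directness"].value_counts().sum() == 3
        assert set(out["directness"]) == {"direct", "indirect", "untargeted"}

    def test_missing_gene_treated_as_no_region(self, caplog):
        sens = pd.Series([True, True], index=["a", "zzz"])
        dist = pd.Series([100.0], index=["a"])
        out = classify_targets(sens, dist)
        assert out.set_index("gene_id").loc["zzz", "directness"] == "indirect"


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[1, 1], [1, 1]], 1.0),
            ([[2, 3], [4, 1]], 132 / 252),
            ([[5, 0], [0, 5]], 2 / 252),
        ],
    )
    def test_known_tables(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, abs=1e-12)

    def test_zero_margin_returns_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_matches_enumeration_oracle_on_sample(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 10, 4)
            if 0 in (a + b, c + d, a + c, b + d):
                continue
            got = fisher_exact_2x2([[a, b], [c, d]])
            want = float(fisher_two_sided_enum(int(a), int(b), int(c), int(d)))
            assert got == pytest.approx(want, abs=1e-12)

    def test_matches_scipy_away_from_ties(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(1, 12, 4)
            got = fisher_exact_2x2([[a, b], [c, d]])
            want = stats.fisher_exact([[a, b], [c, d]])[1]
            assert got == pytest.approx(want, rel=1e-6)

    def test_rejects_negative_or_fractional_entries(self):
        with pytest.raises(IntegrationInputError):
            fisher_exact_2x2([[1, -1], [2, 3]])
        with pytest.raises(IntegrationInputError):
            fisher_exact_2x2([[0.5, 1], [2, 3]])


class TestHypergeomEnrichment:
    def test_perfect_overlap_small_universe(self):
        universe = set(range(10))
        query = set(range(5))
        out = hypergeom_enrichment(query, {"cat": set(range(5))}, universe)
        assert out["p_upper"].iloc[0] == pytest.approx(1 / 252, abs=1e-12)
        assert out["expected"].iloc[0] == pytest.approx(2.5)

    def test_empty_category_p_one(self):
        out = hypergeom_enrichment({1, 2}, {"cat": set()}, set(range(10)))
        assert out["p_upper"].iloc[0] == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(IntegrationInputError):
            hypergeom_enrichment(set(), {"cat": set()}, set())

    def test_matches_exhaustive_draw_oracle(self):
        """Closed form equals brute-force enumeration over all draws, N <= 12."""
        universe = set(range(10))
        for n_cat in (0, 3, 7):
            for n_query in (2, 5):
                query = set(range(n_query))
                cat = set(range(10 - n_cat, 10))
                out = hypergeom_enrichment(query, {"c": cat}, universe)
                k = len(query & cat)
                want = hypergeom_upper_enum(10, n_cat, n_query, k)
                # oracle enumerates category as the *first* n_cat elements;
                # relabel: overlap distribution depends only on sizes
                want = hypergeom_upper_enum(10, n_cat, n_query, k)
                assert out["p_upper"].iloc[0] == pytest.approx(float(want), abs=1e-12)

    def test_bh_adjustment_reported_alongside_raw(self):
        universe = set(range(100))
        query = set(range(10))
        cats = {f"c{i}": set(range(i, i + 20)) for i in range(5)}
        out = hypergeom_enrichment(query, cats, universe)
        assert {"p_upper", "p_bh"} <= set(out.columns)
        assert (out["p_bh"] >= out["p_upper"] - 1e-15).all()


class TestCscBias:
    def test_proximity_bias_planted_near_csc(self):
        rng = np.random.default_rng(5)
        n = 500
        csc = {f"c{i}" for i in range(n)}
        ncsc = {f"n{i}" for i in range(n)}
        dist = {}
        for g in csc:
            dist[g] = 100.0 if rng.random() < 0.5 else 1e7
        for g in ncsc:
            dist[g] = 100.0 if rng.random() < 0.05 else 1e7
        out = csc_proximity_bias(pd.Series(dist), csc, ncsc, bins=[1000, 10_000])
        assert (out["prop_csc"] > out["prop_ncsc"]).all()
        assert (out["fisher_p"] < 0.01).all()

    def test_proximity_null_calibration(self):
        """Equal placement rates: p should rarely be small."""
        big = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            csc = {f"c{i}" for i in range(80)}
            ncsc = {f"n{i}" for i in range(80)}
            dist = {g: (100.0 if rng.random() < 0.3 else 1e7) for g in csc | ncsc}
            out = csc_proximity_bias(pd.Series(dist), csc, ncsc, bins=[1000])
            if out["fisher_p"].iloc[0] > 0.01:
                big += 1
        assert big >= 90

    def test_no_peaks_p_one(self):
        csc, ncsc = {"c1", "c2"}, {"n1", "n2"}
        dist = pd.Series({g: np.inf for g in csc | ncsc})
        with pytest.warns(UserWarning):  # zero margin
            out = csc_proximity_bias(dist, csc, ncsc, bins=[1000])
        assert out["prop_csc"].iloc[0] == 0
        assert out["prop_ncsc"].iloc[0] == 0
        assert out["fisher_p"].iloc[0] == 1.0

    def test_overlapping_sets_rejected(self):
        with pytest.raises(IntegrationInputError):
            csc_proximity_bias(pd.Series(dtype=float), {"a"}, {"a"}, [1000])

    def test_sensitivity_bias_extreme_table(self):
        calls = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(20)],
                "emt_direction": ["induced"] * 20,
                "lsd1_sensitive": [True] * 10 + [False] * 10,
                "csc_bias": ["csc"] * 10 + ["ncsc"] * 10,
            }
        )
        out = csc_sensitivity_bias(calls)
        assert out["induced_table"] == [[10, 0], [0, 10]]
        assert out["p_induced"] == pytest.approx(2 / 184_756, abs=1e-15)
        assert out["repressed_table"] is None

    def test_sensitivity_bias_null_calibration(self):
        ps = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            calls = pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(1000)],
                    "emt_direction": "induced",
                    "lsd1_sensitive": rng.random(1000) < 0.4,
                    "csc_bias": rng.choice(["csc", "ncsc"], 1000),
                }
            )
            ps.append(csc_sensitivity_bias(calls)["p_induced"])
        assert 0.2 <= float(np.median(ps)) <= 0.8

    def test_no_biased_genes_undefined(self):
        calls = pd.DataFrame(
            {
                "gene_id": ["g1"],
                "emt_direction": ["induced"],
                "lsd1_sensitive": [True],
                "csc_bias": ["none"],
            }
        )
        out = csc_sensitivity_bias(calls)
        assert out["p_induced"] is None

    def test_zero_sensitive_genes_undefined_not_zero(self):
        calls = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "emt_direction": ["induced", "induced"],
                "lsd1_sensitive": [False, False],
                "csc_bias": ["csc", "ncsc"],
            }
        )
        assert csc_sensitivity_bias(calls)["p_induced"] is None


def test_zero_noise_target_recovery(zero_noise_cfg):
    """Planted direct-target flags recovered exactly on noise-free data."""
    from emtlink import annotate, expression

    cfg = zero_noise_cfg
    genes = simulate.generate_genome(cfg)
    table, truth = simulate.generate_expression(genes, cfg)
    regions, _, truth = simulate.generate_peaks(genes, truth, cfg)
    calls = expression.make_calls(table).set_index("gene_id")
    kept = annotate.filter_regions(regions["A"])
    mindist = annotate.gene_min_region_distance(kept, genes)
    targets = classify_targets(calls["lsd1_sensitive"], mindist).set_index("gene_id")
    truth_idx = truth.genes.set_index("gene_id")
    got_direct = set(targets.index[targets["directness"] == "direct"])
    want_direct = set(truth_idx.index[truth_idx["direct"]])
    assert got_direct == want_direct
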