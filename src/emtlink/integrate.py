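"""Direct/indirect target classification and enrichment statistics.

A knockdown-sensitive gene with a binding-region centre within 5 kb of its
TSS is a direct target; a sensitive gene without such a region is an
indirect target; insensitive genes are untargeted. Enrichment uses the
upper-tail hypergeometric test and 2x2 contingencies use the conventional
two-sided Fisher exact test ordered by point probability.
"""

from __future__ import annotations

import logging
import math
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DIRECTNESS = ("direct", "indirect", "untargeted")

# relative tolerance when comparing point probabilities in the two-sided sum
_TIE_REL_TOL = Fraction(1, 10_000_000)


class IntegrationInputError(ValueError):
    pass


def classify_targets(
    sensitivity: pd.Series,
    min_abs_distance: pd.Series,
    direct_threshold_bp: int = 5000,
) -> pd.DataFrame:
    """Classify genes as direct / indirect / untargeted.

    ``sensitivity`` is a boolean Series indexed by gene id;
    ``min_abs_distance`` the minimal |region centre - TSS| per gene
    (inf or NaN when the gene has no region on its chromosome). The
    distance threshold is inclusive. Genes absent from the distance
    universe are classified from sensitivity alone with a warning.
    """
    missing = sensitivity.index.difference(min_abs_distance.index)
    if len(missing):
        logger.warning(
            "classify_targets: %d genes absent from the region-annotation "
            "universe; treated as having no nearby region",
            len(missing),
        )
    dist = min_abs_distance.reindex(sensitivity.index).fillna(np.inf)
    near = dist <= direct_threshold_bp
    directness = np.where(
        ~sensitivity.to_numpy(bool),
        "untargeted",
        np.where(near.to_numpy(bool), "direct", "indirect"),
    )
    return pd.DataFrame(
        {
            "gene_id": sensitivity.index,
            "directness": directness,
            "min_abs_distance_bp": dist.to_numpy(),
        }
    ).reset_index(drop=True)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value by point-probability ordering.

    The p-value sums the hypergeometric probabilities of every table with
    the observed margins whose point probability is at most that of the
    observed table, with a 1e-7 relative tolerance on the comparison.
    Computed in exact integer arithmetic. A zero margin returns p = 1 by
    convention, with a warning.
    """
    (a, b), (c, d) = np.asarray(table, dtype=object)
    for x in (a, b, c, d):
        if int(x) != x or x < 0:
            raise IntegrationInputError(f"table entries must be non-negative integers: {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        raise IntegrationInputError("contingency table is all zero")
    if 0 in (r1, r2, c1, b + d):
        warnings.warn("fisher_exact_2x2: a zero margin; p = 1 by convention")
        return 1.0
    kmin, kmax = max(0, c1 - r2), min(c1, r1)
    weights = {
        k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(kmin, kmax + 1)
    }
    w_obs = weights[a]
    cutoff = Fraction(w_obs) * (1 + _TIE_REL_TOL)
    numer = sum(w for w in weights.values() if w <= cutoff)
    return float(Fraction(numer, math.comb(n, c1)))


def hypergeom_enrichment(
    query: set,
    categories: dict[str, set],
    universe: set,
    bh_adjust: bool = True,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene set in named categories.

    For each category K (intersected with the universe) the p-value is
    P[X >= overlap] with X ~ Hypergeometric(N=|universe|, K=|K|,
    n=|query|); ``expected`` is n*K/N. Raw p-values are reported, with an
    optional Benjamini-Hochberg adjusted column alongside (never silently
    substituted for the raw values).
    """
    if not universe:
        raise IntegrationInputError("empty universe")
    if not query <= universe:
        raise IntegrationInputError("query must be a subset of the universe")
    big_n = len(universe)
    n = len(query)
    rows = []
    for name, members in categories.items():
        cat = members & universe
        overlap = len(query & cat)
        big_k = len(cat)
        p = float(stats.hypergeom.sf(overlap - 1, big_n, big_k, n))
        p = min(1.0, p)
        rows.append((name, big_k, overlap, n * big_k / big_n, p))
    out = pd.DataFrame(
        rows, columns=["category", "category_size", "overlap", "expected", "p_upper"]
    )
    if bh_adjust and len(out):
        out["p_bh"] = _benjamini_hochberg(out["p_upper"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, capped at 1)."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def csc_proximity_bias(
    min_abs_distance: pd.Series,
    csc_genes: set,
    ncsc_genes: set,
    bins: list[int],
) -> pd.DataFrame:
    """Per distance bin, region-proximity proportions of CSC vs NCSC genes.

    For each bin b the 2x2 table crosses [gene has a region centre within
    b] x [csc / ncsc] and is tested with the two-sided Fisher exact test.
    The gene sets must be disjoint; an empty set reports NaN proportions.
    """
    if csc_genes & ncsc_genes:
        raise IntegrationInputError("csc and ncsc gene sets must be disjoint")
    rows = []
    for b in bins:
        cells = {}
        props = {}
        for label, genes in (("csc", csc_genes), ("ncsc", ncsc_genes)):
            dist = min_abs_distance.reindex(list(genes)).fillna(np.inf)
            within = int((dist <= b).sum())
            cells[label] = (within, len(genes) - within)
            props[label] = within / len(genes) if genes else np.nan
        table = [list(cells["csc"]), list(cells["ncsc"])]
        p = fisher_exact_2x2(table) if csc_genes and ncsc_genes else np.nan
        rows.append((b, props["csc"], props["ncsc"], p))
    return pd.DataFrame(rows, columns=["bin_bp", "prop_csc", "prop_ncsc", "fisher_p"])


def csc_sensitivity_bias(calls: pd.DataFrame) -> dict:
    """Sensitivity x compartment contingencies among induced and repressed genes.

    For each direction, the 2x2 table crosses [sensitive / insensitive] x
    [csc / ncsc] over genes with a compartment bias, tested two-sided
    Fisher. Directions with no biased genes (or no sensitive genes) report
    None rather than a spurious p-value.
    """
    required = {"emt_direction", "lsd1_sensitive", "csc_bias"}
    if not required <= set(calls.columns):
        raise IntegrationInputError(f"calls table must contain {sorted(required)}")
    biased = calls[calls["csc_bias"] != "none"]
    if len(biased) == 0:
        return {
            "induced_table": None,
            "repressed_table": None,
            "p_induced": None,
            "p_repressed": None,
        }
    out: dict = {}
    for direction in ("induced", "repressed"):
        sub = biased[biased["emt_direction"] == direction]
        key_t, key_p = f"{direction}_table", f"p_{direction}"
        if len(sub) == 0 or not sub["lsd1_sensitive"].any():
            out[key_t] = None
            out[key_p] = None
            continue
        table = [
            [
                int(((sub["lsd1_sensitive"]) & (sub["csc_bias"] == "csc")).sum()),
                int(((sub["lsd1_sensitive"]) & (sub["csc_bias"] == "ncsc")).sum()),
            ],
            [
                int(((~sub["lsd1_sensitive"]) & (sub["csc_bias"] == "csc")).sum()),
                int(((~sub["lsd1_sensitive"]) & (sub["csc_bias"] == "ncsc")).sum()),
            ],
        ]
        out[key_t] = table
        out[key_p] = fisher_exact_2x2(table)
    return out
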