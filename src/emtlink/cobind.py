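"""Two-factor co-binding: overlaps, merged 300 bp regions, tag correlation.

Overlap is any shared base pair under half-open coordinates. Chains of
transitively overlapping regions from either factor collapse into one
merged region, which is standardized to a fixed width (default 300 bp)
around the floor of the merged midpoint before tag counting, so the
Pearson correlation of the two factors' tag counts compares like-for-like
windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


class CobindInputError(ValueError):
    pass


@dataclass
class OverlapResult:
    pairs: pd.DataFrame          # columns a_id, b_id
    a_cobound: set
    b_cobound: set
    a_only: set
    b_only: set


def _validate(regions: pd.DataFrame, name: str) -> None:
    if (regions["start"] >= regions["end"]).any():
        raise CobindInputError(f"{name}: intervals must satisfy start < end")
    if regions["region_id"].duplicated().any():
        raise CobindInputError(f"{name}: duplicate region ids")


def overlap_regions(set_a: pd.DataFrame, set_b: pd.DataFrame) -> OverlapResult:
    """All co-bound (a, b) pairs plus per-set co-bound/only partitions.

    Two half-open intervals overlap iff a.end > b.start and b.end >
    a.start (any overlap, 1 bp suffices). A region may appear in several
    pairs; the partitions are at region level, so |A-only| + |co-bound A|
    = |A|.
    """
    _validate(set_a, "set A")
    _validate(set_b, "set B")
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in set_b.groupby("chrom", sort=False):
        tree = IntervalTree()
        for start, end, rid in zip(sub["start"], sub["end"], sub["region_id"]):
            tree.addi(int(start), int(end), rid)
        trees[chrom] = tree
    pairs = []
    for chrom, start, end, rid in zip(
        set_a["chrom"], set_a["start"], set_a["end"], set_a["region_id"]
    ):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(int(start), int(end)), key=lambda h: (h.begin, h.data)):
            pairs.append((rid, hit.data))
    pairs_df = pd.DataFrame(pairs, columns=["a_id", "b_id"])
    a_cobound = set(pairs_df["a_id"])
    b_cobound = set(pairs_df["b_id"])
    return OverlapResult(
        pairs=pairs_df,
        a_cobound=a_cobound,
        b_cobound=b_cobound,
        a_only=set(set_a["region_id"]) - a_cobound,
        b_only=set(set_b["region_id"]) - b_cobound,
    )


def merge_and_standardize(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    pairs: pd.DataFrame,
    width_bp: int = 300,
) -> pd.DataFrame:
    """Collapse overlap chains into merged regions standardized to one width.

    Transitively overlapping regions (via the co-bound pairs) form one
    merged region spanning their union. The standardized interval is
    centred on the floor of the merged midpoint with exactly ``width_bp``
    base pairs; windows that would extend below zero are clipped with a
    warning.
    """
    lookup = pd.concat([set_a, set_b]).set_index("region_id")
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for a_id, b_id in zip(pairs["a_id"], pairs["b_id"]):
        union(a_id, b_id)
    components: dict[str, list[str]] = {}
    for rid in parent:
        components.setdefault(find(rid), []).append(rid)

    rows = []
    clipped = 0
    for i, members in enumerate(sorted(components.values(), key=lambda m: sorted(m)[0])):
        sub = lookup.loc[sorted(members)]
        chrom = sub["chrom"].iloc[0]
        m_start, m_end = int(sub["start"].min()), int(sub["end"].max())
        center = (m_start + m_end) // 2
        s_start = center - width_bp // 2
        s_end = s_start + width_bp
        if s_start < 0:
            clipped += 1
            s_end -= s_start
            s_start = 0
        rows.append(
            (
                f"M{i:05d}",
                chrom,
                m_start,
                m_end,
                s_start,
                s_end,
                ",".join(sorted(members)),
            )
        )
    if clipped:
        logger.warning("merge_and_standardize: clipped %d windows at position 0", clipped)
    return pd.DataFrame(
        rows,
        columns=[
            "merged_id",
            "chrom",
            "merged_start",
            "merged_end",
            "std_start",
            "std_end",
            "region_ids",
        ],
    )


def count_tags(
    merged: pd.DataFrame,
    source: pd.DataFrame,
    mode: str = "regions",
    use_standardized: bool = True,
) -> pd.Series:
    """Tag count per merged region for one factor.

    ``regions`` mode apportions each source region's normalized tag count
    by its base-pair overlap fraction with the counting window (a region
    half inside contributes half its tags). ``coverage`` mode sums a
    bedGraph-like track's per-base value over the window. The counting
    window is the standardized interval by default, or the full merged
    span with ``use_standardized=False``.
    """
    if mode not in ("regions", "coverage"):
        raise CobindInputError(f"unknown tag source mode {mode!r}")
    lo_col, hi_col = ("std_start", "std_end") if use_standardized else ("merged_start", "merged_end")
    out = np.zeros(len(merged))
    by_chrom = {chrom: sub for chrom, sub in source.groupby("chrom", sort=False)}
    for i, (chrom, lo, hi) in enumerate(
        zip(merged["chrom"], merged[lo_col], merged[hi_col])
    ):
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        s = sub["start"].to_numpy(np.int64)
        e = sub["end"].to_numpy(np.int64)
        ov = np.minimum(e, int(hi)) - np.maximum(s, int(lo))
        ov = np.clip(ov, 0, None)
        if mode == "regions":
            tags = sub["tag_count"].to_numpy(float)
            out[i] = float((tags * ov / (e - s)).sum())
        else:
            vals = sub["value"].to_numpy(float)
            out[i] = float((vals * ov).sum())
    return pd.Series(out, index=merged["merged_id"].to_numpy(), name="tag_count")


def binding_correlation(
    counts_a: pd.Series | np.ndarray,
    counts_b: pd.Series | np.ndarray,
    subset: np.ndarray | None = None,
) -> float | None:
    """Pearson correlation of two factors' tag counts over a region subset.

    Returns None (undefined) for fewer than 3 regions or a constant
    vector — never a silent 0.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if subset is not None:
        a, b = a[subset], b[subset]
    if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def cobound_gene_proportions(
    cobound_annotations: pd.DataFrame,
    single_annotations: pd.DataFrame,
    calls: pd.DataFrame,
) -> dict:
    """Region-denominator proportions near induced/repressed sensitive genes.

    For the co-bound and single-bound region sets separately: the
    proportion of regions whose nearest gene is induced-and-sensitive
    (and, separately, repressed-and-sensitive), with a two-sided Fisher
    exact comparison of the two region sets per direction. Empty region
    classes report None.
    """
    from .integrate import fisher_exact_2x2

    calls_idx = calls.set_index("gene_id")

    def frac(annotations: pd.DataFrame, direction: str):
        if len(annotations) == 0:
            return None, 0, 0
        genes = annotations["nearest_gene_id"]
        ok = genes.isin(calls_idx.index)
        sub = calls_idx.loc[genes[ok]]
        hits = int(
            ((sub["emt_direction"] == direction) & sub["lsd1_sensitive"]).sum()
        )
        return hits / len(annotations), hits, len(annotations)

    out: dict = {}
    for direction in ("induced", "repressed"):
        p_co, h_co, n_co = frac(cobound_annotations, direction)
        p_si, h_si, n_si = frac(single_annotations, direction)
        if p_co is None or p_si is None:
            out[direction] = {
                "prop_cobound": p_co,
                "prop_single": p_si,
                "fisher_p": None,
            }
            continue
        p = fisher_exact_2x2([[h_co, n_co - h_co], [h_si, n_si - h_si]])
        out[direction] = {
            "prop_cobound": p_co,
            "prop_single": p_si,
            "fisher_p": p,
        }
    return out
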