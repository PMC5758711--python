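"""Region filtering and annotation against a gene/TSS universe.

A region's anchor is its centre, floor((start+end)/2). Nearest-TSS search
is restricted to the region's own chromosome; signed distance is negative
when the centre lies upstream of the TSS on the gene's strand. Feature
classification uses a fixed priority with the promoter window defined as
strictly less than 1 kb from a TSS. Chromatin-state assignment takes the
state segment with maximal base-pair overlap.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_VOCAB = (
    "rRNA",
    "5utr",
    "promoter",
    "intergenic",
    "intron",
    "exon",
    "pseudo",
    "tts",
    "ncRNA",
    "3utr",
)

# promoter handled separately (distance rule); remaining track features by
# decreasing priority, centre in no interval -> intergenic
_TRACK_PRIORITY = ("5utr", "3utr", "exon", "intron", "tts", "ncRNA", "pseudo", "rRNA")

NO_GENE = "no_gene"


class AnnotationInputError(ValueError):
    pass


def region_center(regions: pd.DataFrame) -> pd.Series:
    """Integer region centre: floor of the interval midpoint."""
    return (regions["start"] + regions["end"]) // 2


def filter_regions(regions: pd.DataFrame, min_tags: float = 12.2) -> pd.DataFrame:
    """Keep regions with at least ``min_tags`` normalized reads (inclusive)."""
    if "tag_count" not in regions.columns:
        raise AnnotationInputError("regions lack a tag_count column")
    kept = regions[regions["tag_count"] >= min_tags].copy()
    logger.info("filter_regions: kept %d of %d regions", len(kept), len(regions))
    return kept


class _ChromTSSIndex:
    """Sorted per-chromosome TSS index with deterministic tie-breaking."""

    def __init__(self, genes: pd.DataFrame):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in genes.groupby("chrom", sort=False):
            sub = sub.sort_values(["tss", "gene_id"], kind="mergesort")
            tss = sub["tss"].to_numpy(np.int64)
            gid = sub["gene_id"].to_numpy(object)
            strand = sub["strand"].to_numpy(object)
            # first occurrence per unique tss holds the lexicographically
            # smallest gene id at that position
            utss, first = np.unique(tss, return_index=True)
            self.by_chrom[chrom] = (utss, gid[first], strand[first], )

    def nearest(self, chrom: str, center: int):
        """Return (gene_id, strand, tss, distance) or None if no genes."""
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return None
        utss, gid, strand = entry
        i = int(np.searchsorted(utss, center))
        cands = []
        if i > 0:
            cands.append(i - 1)
        if i < len(utss):
            cands.append(i)
        dists = [abs(int(utss[j]) - center) for j in cands]
        dmin = min(dists)
        best = [j for j, d in zip(cands, dists) if d == dmin]
        j = min(best, key=lambda j: gid[j])
        return gid[j], strand[j], int(utss[j]), dmin


def nearest_tss(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Annotate each region with its nearest same-chromosome TSS.

    Returns a frame with region_id, nearest_gene_id, signed_distance, and
    abs_distance. Distance ties are broken toward the lexicographically
    smallest gene id. Regions on chromosomes with no genes get the
    sentinel gene id ``no_gene`` and NaN distances (excluded from distance
    statistics downstream).
    """
    if len(genes) and genes["gene_id"].duplicated().any():
        raise AnnotationInputError("duplicate gene ids in annotation")
    index = _ChromTSSIndex(genes)
    centers = region_center(regions)
    out_gene, out_signed, out_abs = [], [], []
    for chrom, center in zip(regions["chrom"], centers):
        hit = index.nearest(chrom, int(center))
        if hit is None:
            out_gene.append(NO_GENE)
            out_signed.append(np.nan)
            out_abs.append(np.nan)
            continue
        gid, strand, tss, dmin = hit
        signed = (int(center) - tss) if strand == "+" else (tss - int(center))
        out_gene.append(gid)
        out_signed.append(float(signed))
        out_abs.append(float(dmin))
    return pd.DataFrame(
        {
            "region_id": regions["region_id"].to_numpy(),
            "chrom": regions["chrom"].to_numpy(),
            "center": centers.to_numpy(),
            "nearest_gene_id": out_gene,
            "signed_distance": out_signed,
            "abs_distance": out_abs,
        }
    )


def classify_feature(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    feature_track: pd.DataFrame | None = None,
    promoter_bp: int = 1000,
) -> pd.Series:
    """Assign each region a genomic-feature label by its centre.

    A centre strictly closer than ``promoter_bp`` to any TSS is a
    promoter, regardless of overlapping track features. Otherwise the
    highest-priority track feature containing the centre wins
    (5utr > 3utr > exon > intron > tts > ncRNA > pseudo > rRNA); a centre
    in no interval is intergenic.
    """
    if feature_track is not None:
        bad = set(feature_track["feature"]) - set(FEATURE_VOCAB)
        if bad:
            raise AnnotationInputError(f"unknown features in track: {sorted(bad)}")
        track_by_chrom = {
            chrom: sub.reset_index(drop=True)
            for chrom, sub in feature_track.groupby("chrom", sort=False)
        }
    else:
        track_by_chrom = {}
    index = _ChromTSSIndex(genes)
    centers = region_center(regions)
    labels = []
    rank = {f: i for i, f in enumerate(_TRACK_PRIORITY)}
    for chrom, center in zip(regions["chrom"], centers):
        center = int(center)
        hit = index.nearest(chrom, center)
        if hit is not None and hit[3] < promoter_bp:
            labels.append("promoter")
            continue
        sub = track_by_chrom.get(chrom)
        label = "intergenic"
        if sub is not None:
            inside = sub[(sub["start"] <= center) & (center < sub["end"])]
            if len(inside):
                label = min(inside["feature"], key=lambda f: rank[f])
        labels.append(label)
    return pd.Series(labels, index=regions.index, name="feature")


def annotate_chromatin_state(
    regions: pd.DataFrame, states: pd.DataFrame
) -> pd.Series:
    """Label each region by the state segment with maximal bp overlap.

    Zero overlap gives ``none``; equal overlap goes to the leftmost
    segment. Overlapping segments within the state track are rejected.
    """
    states_by_chrom = {}
    for chrom, sub in states.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="mergesort").reset_index(drop=True)
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise AnnotationInputError(f"overlapping state segments on {chrom}")
        states_by_chrom[chrom] = (
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            sub["state"].to_numpy(object),
        )
    labels = []
    for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
        entry = states_by_chrom.get(chrom)
        if entry is None:
            labels.append("none")
            continue
        s, e, lab = entry
        ov = np.minimum(e, int(end)) - np.maximum(s, int(start))
        ov = np.where(ov > 0, ov, 0)
        if ov.max(initial=0) == 0:
            labels.append("none")
        else:
            labels.append(lab[int(np.argmax(ov))])  # argmax -> leftmost on ties
    return pd.Series(labels, index=regions.index, name="state")


def gene_min_region_distance(
    regions: pd.DataFrame, genes: pd.DataFrame
) -> pd.Series:
    """Per gene, the minimal |centre - TSS| over all same-chromosome regions.

    Genes on chromosomes without regions get +inf.
    """
    centers = region_center(regions)
    by_chrom = {
        chrom: np.sort(centers[regions["chrom"] == chrom].to_numpy(np.int64))
        for chrom in regions["chrom"].unique()
    }
    out = np.full(len(genes), np.inf)
    for k, (chrom, tss) in enumerate(zip(genes["chrom"], genes["tss"])):
        cent = by_chrom.get(chrom)
        if cent is None or cent.size == 0:
            continue
        i = int(np.searchsorted(cent, tss))
        best = np.inf
        if i > 0:
            best = min(best, abs(int(tss) - int(cent[i - 1])))
        if i < cent.size:
            best = min(best, abs(int(cent[i]) - int(tss)))
        out[k] = best
    return pd.Series(out, index=genes["gene_id"].to_numpy(), name="min_region_distance")


def distance_bin_proportions(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    gene_subsets: dict[str, set],
    bins: list[int],
) -> pd.DataFrame:
    """Cumulative proportion of genes with a region centre within each bin.

    For each named subset S and bin b: |{g in S: min distance <= b}| / |S|.
    Bins must be strictly increasing; proportions are therefore monotone
    non-decreasing across bins. An empty subset reports NaN.
    """
    if list(bins) != sorted(set(bins)):
        raise AnnotationInputError("bins must be strictly increasing")
    mindist = gene_min_region_distance(regions, genes)
    rows = []
    for name, subset in gene_subsets.items():
        ids = [g for g in subset if g in mindist.index]
        n = len(subset)
        for b in bins:
            if n == 0:
                rows.append((name, b, np.nan))
            else:
                hit = sum(1 for g in ids if mindist[g] <= b)
                rows.append((name, b, hit / n))
    return pd.DataFrame(rows, columns=["subset", "bin_bp", "proportion"])


def tss_metaprofile(
    coverage: pd.DataFrame,
    genes: pd.DataFrame,
    chrom_sizes: dict[str, int] | None = None,
    bin_bp: int = 100,
    half_window_bp: int = 1500,
) -> np.ndarray:
    """Mean strand-oriented coverage profile around TSSs.

    For each gene the window [TSS - half_window, TSS + half_window) is cut
    into ``2*half_window/bin_bp`` bins; per-base coverage from the
    bedGraph-like track (chrom, start, end, value) is summed within each
    bin and the profile is averaged over genes. Minus-strand windows are
    reversed so bin 0 is always the most upstream. Genes whose window
    leaves the chromosome are skipped with a warning.
    """
    if (coverage["value"] < 0).any():
        raise AnnotationInputError("coverage values must be non-negative")
    if (2 * half_window_bp) % bin_bp != 0:
        raise AnnotationInputError("window must be a whole number of bins")
    n_bins = 2 * half_window_bp // bin_bp
    cov_by_chrom = {
        chrom: sub.sort_values("start").reset_index(drop=True)
        for chrom, sub in coverage.groupby("chrom", sort=False)
    }
    total = np.zeros(n_bins)
    used = 0
    skipped = 0
    for chrom, tss, strand in zip(genes["chrom"], genes["tss"], genes["strand"]):
        lo = int(tss) - half_window_bp
        hi = int(tss) + half_window_bp
        size = None if chrom_sizes is None else int(chrom_sizes.get(chrom, 0))
        if lo < 0 or (size is not None and hi > size):
            skipped += 1
            continue
        base = np.zeros(2 * half_window_bp)
        sub = cov_by_chrom.get(chrom)
        if sub is not None:
            s = sub["start"].to_numpy(np.int64)
            e = sub["end"].to_numpy(np.int64)
            v = sub["value"].to_numpy(float)
            sel = (e > lo) & (s < hi)
            for ss, ee, vv in zip(s[sel], e[sel], v[sel]):
                base[max(ss, lo) - lo : min(ee, hi) - lo] += vv
        prof = base.reshape(n_bins, bin_bp).sum(axis=1)
        if strand == "-":
            prof = prof[::-1]
        total += prof
        used += 1
    if skipped:
        logger.warning("tss_metaprofile: skipped %d genes with out-of-bounds windows", skipped)
    if used == 0:
        return np.full(n_bins, np.nan)
    return total / used
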