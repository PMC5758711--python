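"""Synthetic data generators with planted, recorded ground truth.

Every generator draws from a named substream of one root seed, so adding a
new generator never perturbs the draws of existing ones, and an identical
config + seed always reproduces byte-identical outputs.

The simulated study mirrors a stimulated-EMT knockdown design: expression
is measured in four arms (baseline/stimulated x mock/knockdown siRNA),
factor-A binding regions are enriched near the TSSs of knockdown-reversible
induced genes, a second factor co-binds factor A preferentially at
promoters with correlated tag counts, reversible genes carry a CSC-biased
expression signature, a peptide array holds a few strong kinase substrates,
and paired fluorescence channels share a planted pixel correlation.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig
from .signals import CellImage

STATE_VOCAB = (
    "active_promoter",
    "enhancer",
    "transcribed",
    "repressed",
    "heterochromatin",
    "ctcf",
    "none",
)

_STATE_WEIGHTS = np.array([0.10, 0.15, 0.20, 0.20, 0.20, 0.05, 0.10])

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream of a root seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass
class TruthBundle:
    """Planted ground truth for one simulated study."""

    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    cobound_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    peptides: pd.DataFrame = field(default_factory=pd.DataFrame)
    images: pd.DataFrame = field(default_factory=pd.DataFrame)


def generate_genome(cfg: SimConfig) -> pd.DataFrame:
    """Simulate a gene annotation: chrom, tss, strand, gene_id.

    TSS positions are uniform within each chromosome (chromosomes weighted
    by length) and strands are balanced half '+' / half '-'.
    """
    cfg.validate()
    rng = substream(cfg.seed, "genome")
    chroms = list(cfg.chrom_sizes)
    sizes = np.array([int(cfg.chrom_sizes[c]) for c in chroms], dtype=np.int64)
    n = cfg.n_genes
    which = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    tss = np.array([rng.integers(0, sizes[w]) for w in which], dtype=np.int64)
    strand = np.array(["+"] * ((n + 1) // 2) + ["-"] * (n // 2))
    rng.shuffle(strand)
    width = max(4, len(str(max(n, 1))))
    return pd.DataFrame(
        {
            "chrom": [chroms[w] for w in which],
            "tss": tss,
            "strand": strand,
            "gene_id": [f"g{i:0{width}d}" for i in range(n)],
        }
    )


def generate_expression(
    genes: pd.DataFrame, cfg: SimConfig
) -> tuple[pd.DataFrame, TruthBundle]:
    """Simulate the four-arm expression table and plant per-gene truth.

    Induced genes gain ``effect`` log2 units on stimulation, repressed
    genes lose it; knockdown-sensitive genes have the change reversed in
    the stimulated siRNA arm. Gaussian ``noise_sd`` is added independently
    to every arm. One probe per gene.
    """
    cfg.validate()
    if len(genes) == 0:
        raise ConfigError("generate_expression requires a non-empty gene list")
    if cfg.frac_induced + cfg.frac_repressed > 1.0:
        raise ConfigError("frac_induced + frac_repressed exceeds 1")
    rng = substream(cfg.seed, "expression")
    n = len(genes)

    u = rng.random(n)
    direction = np.where(
        u < cfg.frac_induced,
        "induced",
        np.where(u < cfg.frac_induced + cfg.frac_repressed, "repressed", "unchanged"),
    )
    sens_p = np.where(
        direction == "induced",
        cfg.frac_sensitive_given_induced,
        np.where(direction == "repressed", cfg.frac_sensitive_given_repressed, 0.0),
    )
    sensitive = rng.random(n) < sens_p

    informative = rng.random(n) < cfg.frac_csc_informative
    biased = rng.random(n) < cfg.csc_bias_rate
    coin = rng.random(n) < 0.5
    csc = np.full(n, "none", dtype=object)
    ind_s = informative & sensitive & (direction == "induced")
    rep_s = informative & sensitive & (direction == "repressed")
    other = informative & ~(ind_s | rep_s)
    csc[ind_s] = np.where(biased[ind_s], "csc", "ncsc")
    csc[rep_s] = np.where(biased[rep_s], "ncsc", "csc")
    csc[other] = np.where(coin[other], "csc", "ncsc")

    base = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, n)
    effect = rng.normal(cfg.effect_log2fc_mean, cfg.effect_log2fc_sd, n)
    delta = np.where(
        direction == "induced", effect, np.where(direction == "repressed", -effect, 0.0)
    )
    reversal = np.where(sensitive, -delta, 0.0)
    noise = rng.normal(0.0, cfg.noise_sd, (6, n)) if cfg.noise_sd > 0 else np.zeros((6, n))

    bias = np.where(csc == "csc", effect, np.where(csc == "ncsc", -effect, 0.0))
    table = pd.DataFrame(
        {
            "probe_id": "p_" + genes["gene_id"],
            "gene_id": genes["gene_id"],
            "baseline_mock": base + noise[0],
            "baseline_sirna": base + noise[1],
            "stim_mock": base + delta + noise[2],
            "stim_sirna": base + delta + reversal + noise[3],
            "csc_log2": base + bias / 2 + noise[4],
            "ncsc_log2": base - bias / 2 + noise[5],
        }
    )
    truth_genes = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "direction": direction,
            "sensitive": sensitive,
            "csc": csc,
            "effect": effect,
        }
    )
    return table, TruthBundle(genes=truth_genes)


def _uniform_centers(rng: np.random.Generator, cfg: SimConfig, n: int):
    chroms = list(cfg.chrom_sizes)
    sizes = np.array([int(cfg.chrom_sizes[c]) for c in chroms], dtype=np.int64)
    half = cfg.peak_width // 2
    which = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    centers = np.array(
        [rng.integers(half, max(half + 1, sizes[w] - half)) for w in which],
        dtype=np.int64,
    )
    return np.array([chroms[w] for w in which]), centers


def _regions_frame(prefix, chroms, centers, width, factor, tags):
    half = width // 2
    start = centers - half
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": start,
            "end": start + width,
            "region_id": [f"{prefix}{i:05d}" for i in range(len(centers))],
            "tag_count": tags,
            "factor": factor,
        }
    )


def generate_peaks(
    genes: pd.DataFrame, truth: TruthBundle, cfg: SimConfig
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, TruthBundle]:
    """Simulate two factors' binding regions and a chromatin-state tiling.

    A ``frac_peaks_near_direct`` fraction of factor-A regions is centred
    Normal(0, near_distance_sd) around the TSSs of a sampled subset of
    knockdown-sensitive genes; the remainder is uniform. Factor-B regions
    overlap factor-A regions at a zone-dependent co-binding rate (promoter
    vs background), with tag counts of co-bound pairs drawn from a
    bivariate normal whose correlation is highest at promoters of
    sensitive genes. Background factor-B regions are rejected against any
    overlap with factor A, so co-binding occurs only where planted.

    A small fraction of uniform factor-A regions are sub-threshold decoys
    with tag counts strictly below 12.2 normalized reads; the planted
    direct-target flags are computed from the remaining (filter-passing)
    regions: a gene is truth-direct iff it is sensitive and some kept
    factor-A centre lies within 5 kb of its TSS.
    """
    cfg.validate()
    rng = substream(cfg.seed, "peaks")
    w = cfg.peak_width
    half = w // 2
    tg = truth.genes.set_index("gene_id")
    genes_idx = genes.set_index("gene_id")

    if cfg.n_peaks == 0:
        warnings.warn("n_peaks=0: generating empty region sets")
        empty = _regions_frame("A", np.array([], dtype=object), np.array([], dtype=np.int64), w, "A", np.array([]))
        states = generate_states(genes, truth, cfg)
        truth.genes = truth.genes.assign(direct=False, min_a_distance=np.inf)
        truth.cobound_pairs = pd.DataFrame(
            columns=["a_id", "b_id", "zone"]
        )
        return {"A": empty, "B": empty.assign(factor="B")}, states, truth

    sens_ids = tg.index[tg["sensitive"]].to_numpy()
    n_near = int(round(cfg.frac_peaks_near_direct * cfg.n_peaks))
    n_near = min(n_near, cfg.n_peaks)
    if len(sens_ids) == 0:
        n_near = 0

    # --- factor A placement ---
    chroms_a: list[str] = []
    centers_a: list[int] = []
    if n_near > 0:
        n_direct = max(1, int(round(cfg.frac_direct_given_sensitive * len(sens_ids))))
        n_direct = min(n_direct, len(sens_ids), n_near)
        direct_ids = rng.choice(sens_ids, size=n_direct, replace=False)
        assigned = list(direct_ids)
        if n_near > n_direct:
            assigned += list(rng.choice(direct_ids, size=n_near - n_direct, replace=True))
        for gid in assigned:
            chrom = genes_idx.at[gid, "chrom"]
            tss = int(genes_idx.at[gid, "tss"])
            size = int(cfg.chrom_sizes[chrom])
            c = tss + int(round(rng.normal(0.0, cfg.near_distance_sd)))
            c = int(np.clip(c, half, max(half, size - half)))
            chroms_a.append(chrom)
            centers_a.append(c)
    n_unif = cfg.n_peaks - n_near
    uc, ucent = _uniform_centers(rng, cfg, n_unif)
    chroms_a = np.array(chroms_a + list(uc), dtype=object)
    centers_a = np.array(centers_a + list(ucent), dtype=np.int64)

    tags_a = np.maximum(cfg.tag_floor, rng.normal(cfg.tag_mean, cfg.tag_sd, cfg.n_peaks))
    # sub-threshold decoys among the uniform remainder only
    if n_unif > 0 and cfg.frac_low_tag > 0:
        decoy = np.zeros(cfg.n_peaks, dtype=bool)
        decoy[n_near:] = rng.random(n_unif) < cfg.frac_low_tag
        tags_a[decoy] = rng.uniform(1.0, 12.0, decoy.sum())
    else:
        decoy = np.zeros(cfg.n_peaks, dtype=bool)

    # --- zones for factor-A regions ---
    zone = np.full(cfg.n_peaks, "distal", dtype=object)
    for chrom in cfg.chrom_sizes:
        g_mask = (genes["chrom"] == chrom).to_numpy()
        if not g_mask.any():
            continue
        tss = genes.loc[g_mask, "tss"].to_numpy(np.int64)
        sens = tg.loc[genes.loc[g_mask, "gene_id"], "sensitive"].to_numpy()
        order = np.argsort(tss)
        tss_s, sens_s = tss[order], sens[order]
        r_mask = chroms_a == chrom
        for i in np.nonzero(r_mask)[0]:
            d = np.abs(tss_s - centers_a[i])
            if d.min() < cfg.promoter_bp:
                # any sensitive TSS within the promoter window wins
                within = d < cfg.promoter_bp
                zone[i] = (
                    "sensitive_promoter" if sens_s[within].any() else "promoter"
                )

    # --- factor B: co-bound partners + background ---
    rho_by_zone = {
        "sensitive_promoter": cfg.tag_rho_sensitive_promoter,
        "promoter": cfg.tag_rho_promoter,
        "distal": cfg.tag_rho_distal,
    }
    rate_by_zone = {
        "sensitive_promoter": cfg.cobind_rate_at_promoters,
        "promoter": cfg.cobind_rate_at_promoters,
        "distal": cfg.cobind_rate_background,
    }
    cobound = rng.random(cfg.n_peaks) < np.array([rate_by_zone[z] for z in zone])
    pairs = []
    b_chroms: list[str] = []
    b_centers: list[int] = []
    b_tags: list[float] = []
    for i in np.nonzero(cobound)[0]:
        rho = rho_by_zone[zone[i]]
        z1, z2 = rng.standard_normal(2)
        ta = cfg.tag_mean + cfg.tag_sd * z1
        tb = cfg.tag_mean + cfg.tag_sd * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        if not decoy[i]:
            tags_a[i] = max(cfg.tag_floor, ta)
        jitter = int(rng.integers(-w // 3, w // 3 + 1))
        size = int(cfg.chrom_sizes[chroms_a[i]])
        c = int(np.clip(centers_a[i] + jitter, half, max(half, size - half)))
        b_chroms.append(chroms_a[i])
        b_centers.append(c)
        b_tags.append(max(cfg.tag_floor, tb))
        pairs.append((f"A{i:05d}", f"B{len(b_centers) - 1:05d}", zone[i]))

    n_b = cfg.n_peaks if cfg.n_peaks_b is None else cfg.n_peaks_b
    n_b_only = max(0, n_b - len(b_centers))
    a_by_chrom = {
        chrom: np.sort(centers_a[chroms_a == chrom]) for chrom in cfg.chrom_sizes
    }
    placed = 0
    attempts = 0
    while placed < n_b_only and attempts < 200 * max(1, n_b_only):
        attempts += 1
        uc, ucent = _uniform_centers(rng, cfg, 1)
        near_a = a_by_chrom.get(uc[0], np.array([], dtype=np.int64))
        # reject any overlap with a factor-A region (same width w)
        if near_a.size and np.min(np.abs(near_a - ucent[0])) < w:
            continue
        b_chroms.append(uc[0])
        b_centers.append(int(ucent[0]))
        b_tags.append(max(cfg.tag_floor, rng.normal(cfg.tag_mean, cfg.tag_sd)))
        placed += 1

    regions_a = _regions_frame("A", chroms_a, centers_a, w, "A", tags_a)
    regions_b = _regions_frame(
        "B",
        np.array(b_chroms, dtype=object),
        np.array(b_centers, dtype=np.int64),
        w,
        "B",
        np.array(b_tags),
    )

    # --- realized truth: direct flags from kept factor-A placement ---
    kept = ~decoy
    min_dist = np.full(len(genes), np.inf)
    for chrom in cfg.chrom_sizes:
        g_mask = (genes["chrom"] == chrom).to_numpy()
        r_mask = (chroms_a == chrom) & kept
        if not g_mask.any() or not r_mask.any():
            continue
        tssv = genes.loc[g_mask, "tss"].to_numpy(np.int64)
        cent = centers_a[r_mask]
        min_dist[g_mask] = np.min(
            np.abs(tssv[:, None] - cent[None, :]), axis=1
        )
    order = truth.genes["gene_id"].to_numpy()
    gmap = {g: i for i, g in enumerate(genes["gene_id"].to_numpy())}
    md = np.array([min_dist[gmap[g]] for g in order])
    truth.genes = truth.genes.assign(
        min_a_distance=md,
        direct=truth.genes["sensitive"].to_numpy() & (md <= 5000),
    )
    truth.cobound_pairs = pd.DataFrame(pairs, columns=["a_id", "b_id", "zone"])

    states = generate_states(genes, truth, cfg)
    return {"A": regions_a, "B": regions_b}, states, truth


def generate_cobound_tag_study(
    groups: list[tuple[int, float, str]],
    cfg: SimConfig,
    spacing: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Isolated co-bound pairs with planted per-group tag correlation.

    ``groups`` is a list of (n_pairs, rho, zone_label). Each pair places
    factor-A and factor-B regions on *identical* intervals spaced
    ``spacing`` bp apart along one synthetic chromosome, so merging and
    standardizing to the region width reproduces each factor's normalized
    tag count exactly and the sample correlation of the counted tags
    estimates the planted rho. Returns (regions_a, regions_b, truth)
    where truth carries pair index, zone, and the planted rho.
    """
    cfg.validate()
    rng = substream(cfg.seed, "cobound_tag_study")
    w = cfg.peak_width
    rows_a, rows_b, rows_t = [], [], []
    pos = w
    k = 0
    for n_pairs, rho, zone_label in groups:
        if not -1.0 <= rho <= 1.0:
            raise ConfigError(f"planted rho {rho} outside [-1, 1]")
        z1 = rng.standard_normal(n_pairs)
        z2 = rng.standard_normal(n_pairs)
        ta = cfg.tag_mean + cfg.tag_sd * z1
        tb = cfg.tag_mean + cfg.tag_sd * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        for j in range(n_pairs):
            rows_a.append(("chrS", pos, pos + w, f"A{k:05d}", max(0.1, ta[j]), "A"))
            rows_b.append(("chrS", pos, pos + w, f"B{k:05d}", max(0.1, tb[j]), "B"))
            rows_t.append((k, zone_label, rho))
            pos += w + spacing
            k += 1
    cols = ["chrom", "start", "end", "region_id", "tag_count", "factor"]
    return (
        pd.DataFrame(rows_a, columns=cols),
        pd.DataFrame(rows_b, columns=cols),
        pd.DataFrame(rows_t, columns=["pair", "zone", "rho"]),
    )


def generate_states(
    genes: pd.DataFrame, truth: TruthBundle, cfg: SimConfig
) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping chromatin-state segments.

    Segments covering a sensitive gene's TSS are biased toward the
    active_promoter label, emulating promoter marks at regulated genes.
    """
    rng = substream(cfg.seed, "states")
    tg = truth.genes.set_index("gene_id") if len(truth.genes) else None
    rows = []
    for chrom, size in cfg.chrom_sizes.items():
        size = int(size)
        g = genes[genes["chrom"] == chrom]
        sens_tss = np.array([], dtype=np.int64)
        if tg is not None and len(g):
            sens = tg.loc[g["gene_id"], "sensitive"].to_numpy()
            sens_tss = g["tss"].to_numpy(np.int64)[sens]
        pos = 0
        while pos < size:
            seg = int(rng.integers(cfg.state_seg_min, cfg.state_seg_max + 1))
            end = min(pos + seg, size)
            label = rng.choice(STATE_VOCAB, p=_STATE_WEIGHTS)
            if sens_tss.size and ((sens_tss >= pos) & (sens_tss < end)).any():
                if rng.random() < 0.8:
                    label = "active_promoter"
            rows.append((chrom, pos, end, label))
            pos = end
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def generate_peptide_array(cfg: SimConfig) -> tuple[pd.DataFrame, TruthBundle]:
    """Simulate an overlapping-peptide kinase array with planted hits.

    Peptides of fixed length tile an abstract protein with a constant
    overlap step. ``n_hits`` randomly chosen peptides receive exactly
    ``hit_signal``; all others draw from Normal(background_mean,
    background_sd) clipped at zero.
    """
    cfg.validate()
    rng = substream(cfg.seed, "peptides")
    n = cfg.n_peptides
    protein_len = cfg.peptide_length + (n - 1) * cfg.peptide_step
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=protein_len))
    offsets = 1 + cfg.peptide_step * np.arange(n)
    hit = np.zeros(n, dtype=bool)
    if cfg.n_hits > 0:
        hit[rng.choice(n, size=cfg.n_hits, replace=False)] = True
    signals = np.clip(rng.normal(cfg.background_mean, cfg.background_sd, n), 0.0, None)
    signals[hit] = cfg.hit_signal
    table = pd.DataFrame(
        {
            "peptide_id": [f"pep{i:04d}" for i in range(n)],
            "protein_offset": offsets,
            "sequence": [
                seq[o - 1 : o - 1 + cfg.peptide_length] for o in offsets
            ],
            "mean_signal": signals,
        }
    )
    truth = TruthBundle(
        peptides=pd.DataFrame({"peptide_id": table["peptide_id"], "hit": hit})
    )
    return table, truth


def generate_cell_images(cfg: SimConfig) -> tuple[list[CellImage], TruthBundle]:
    """Simulate two-channel cell images with a planted pixel correlation.

    Within the circular cell mask, pixel pairs draw from a bivariate
    normal with correlation ``img_rho``; outside the mask both channels
    are a constant background. The nuclear mask is a concentric smaller
    disk. rho = 1 makes channel B an exact affine function of channel A.
    """
    cfg.validate()
    rng = substream(cfg.seed, "images")
    g = cfg.img_grid
    yy, xx = np.mgrid[0:g, 0:g]
    center = (g - 1) / 2.0
    dist = np.sqrt((yy - center) ** 2 + (xx - center) ** 2)
    cell_mask = dist <= cfg.img_cell_radius_frac * g
    nuclear_mask = dist <= cfg.img_nuclear_radius_frac * g
    (m1, m2), (s1, s2), rho = cfg.img_channel_means, cfg.img_channel_sds, cfg.img_rho
    images, rows = [], []
    for i in range(cfg.img_n_cells):
        npix = int(cell_mask.sum())
        z1 = rng.standard_normal(npix)
        z2 = rng.standard_normal(npix)
        a = np.full((g, g), cfg.img_background, dtype=float)
        b = np.full((g, g), cfg.img_background, dtype=float)
        a[cell_mask] = m1 + s1 * z1
        b[cell_mask] = m2 + s2 * (rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * z2)
        images.append(
            CellImage(
                channels={"A": a, "B": b},
                nuclear_mask=nuclear_mask.copy(),
                cell_mask=cell_mask.copy(),
                background_value=cfg.img_background,
                image_id=f"cell{i:03d}",
            )
        )
        rows.append((f"cell{i:03d}", rho))
    truth = TruthBundle(images=pd.DataFrame(rows, columns=["image_id", "rho"]))
    return images, truth
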