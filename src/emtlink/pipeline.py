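"""End-to-end orchestration: simulate/load -> call -> annotate -> integrate.

``run_pipeline`` executes the stages in dependency order, writes every
intermediate table under the configured output directory, and returns a
machine-readable report. With a fixed seed and config the run is fully
deterministic, and every number in the report can be reproduced by calling
the owning module's operation directly on the written intermediates.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotate, cobind, expression, integrate, io, signals, simulate
from .config import RunConfig
from .signals import CellImage

logger = logging.getLogger(__name__)


def _simulate_all(cfg, outdir: Path):
    genes = simulate.generate_genome(cfg)
    expr, truth = simulate.generate_expression(genes, cfg)
    regions, states, truth = simulate.generate_peaks(genes, truth, cfg)
    peptides, pep_truth = simulate.generate_peptide_array(cfg)
    images, img_truth = simulate.generate_cell_images(cfg)
    truth.peptides = pep_truth.peptides
    truth.images = img_truth.images

    io.write_genes_tsv(genes, outdir / "genes.tsv")
    io.write_expression_tsv(expr, outdir / "expression.tsv")
    io.write_regions_bed(regions["A"], outdir / "peaks_A.bed")
    io.write_regions_bed(regions["B"], outdir / "peaks_B.bed")
    io.write_states_bed(states, outdir / "states.bed")
    io.write_peptides_tsv(peptides, outdir / "peptides.tsv")
    for image in images:
        io.write_cell_image(image, outdir / "images" / image.image_id)
    io.write_json(
        {
            "genes": truth.genes,
            "cobound_pairs": truth.cobound_pairs,
            "peptides": truth.peptides,
            "images": truth.images,
        },
        outdir / "truth.json",
    )
    return genes, expr, regions, states, peptides, images, truth


def _load_all(inputs: dict[str, str]):
    genes = io.read_genes_tsv(inputs["genes"]) if "genes" in inputs else None
    expr = io.read_expression_tsv(inputs["expression"]) if "expression" in inputs else None
    regions = {}
    if "peaks_a" in inputs:
        regions["A"] = io.read_regions_bed(inputs["peaks_a"], factor="A")
    if "peaks_b" in inputs:
        regions["B"] = io.read_regions_bed(inputs["peaks_b"], factor="B")
    states = io.read_states_bed(inputs["states"]) if "states" in inputs else None
    peptides = io.read_peptides_tsv(inputs["peptides"]) if "peptides" in inputs else None
    images: list[CellImage] = []
    if "images" in inputs:
        base = Path(inputs["images"])
        images = [io.read_cell_image(d) for d in sorted(base.iterdir()) if d.is_dir()]
    return genes, expr, regions, states, peptides, images, None


def run_pipeline(config: RunConfig) -> dict:
    """Run every applicable stage and return the report dictionary."""
    config.validate()
    thr = config.thresholds
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        sim_cfg = config.simulation
        sim_cfg.seed = config.seed
        genes, expr, regions, states, peptides, images, truth = _simulate_all(
            sim_cfg, outdir
        )
    else:
        genes, expr, regions, states, peptides, images, truth = _load_all(config.inputs)

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "warnings": [],
    }

    calls = None
    if expr is not None:
        calls = expression.make_calls(expr, threshold_log2=thr.de_log2)
        calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
        summary = expression.summarize_reversibility(
            calls["emt_direction"], calls["lsd1_sensitive"]
        )
        summary.to_csv(outdir / "reversibility.tsv", sep="\t", index=False)
        report["stages"]["expression"] = {
            "n_probes": len(expr),
            "reversibility": summary,
        }

    annotations = None
    regions_a = None
    if genes is not None and "A" in regions:
        regions_a = annotate.filter_regions(regions["A"], min_tags=thr.min_tags)
        annotations = annotate.nearest_tss(regions_a, genes)
        annotations["feature"] = annotate.classify_feature(
            regions_a, genes, promoter_bp=thr.promoter_bp
        )
        if states is not None:
            annotations["state"] = annotate.annotate_chromatin_state(regions_a, states)
        annotations.to_csv(outdir / "annotations_A.tsv", sep="\t", index=False)
        report["stages"]["annotation"] = {
            "n_regions_in": len(regions["A"]),
            "n_regions_kept": len(regions_a),
            "feature_counts": annotations["feature"].value_counts().to_dict(),
            "state_counts": (
                annotations["state"].value_counts().to_dict()
                if "state" in annotations
                else None
            ),
        }

    if annotations is not None and calls is not None:
        gene_calls = calls.set_index("gene_id")
        mindist = annotate.gene_min_region_distance(regions_a, genes)
        subsets = {
            "induced_sensitive": set(
                gene_calls.index[
                    (gene_calls["emt_direction"] == "induced")
                    & gene_calls["lsd1_sensitive"]
                ]
            ),
            "induced_insensitive": set(
                gene_calls.index[
                    (gene_calls["emt_direction"] == "induced")
                    & ~gene_calls["lsd1_sensitive"]
                ]
            ),
            "repressed_sensitive": set(
                gene_calls.index[
                    (gene_calls["emt_direction"] == "repressed")
                    & gene_calls["lsd1_sensitive"]
                ]
            ),
            "repressed_insensitive": set(
                gene_calls.index[
                    (gene_calls["emt_direction"] == "repressed")
                    & ~gene_calls["lsd1_sensitive"]
                ]
            ),
        }
        bin_props = annotate.distance_bin_proportions(
            regions_a, genes, subsets, config.distance_bins
        )
        bin_props.to_csv(outdir / "distance_bins.tsv", sep="\t", index=False)

        targets = integrate.classify_targets(
            gene_calls["lsd1_sensitive"], mindist, direct_threshold_bp=thr.direct_bp
        )
        targets.to_csv(outdir / "targets.tsv", sep="\t", index=False)
        bias = integrate.csc_sensitivity_bias(calls) if "csc_bias" in calls else None
        report["stages"]["integration"] = {
            "directness_counts": targets["directness"].value_counts().to_dict(),
            "distance_bins": bin_props,
            "csc_sensitivity_bias": bias,
        }

    if regions_a is not None and "B" in regions:
        regions_b = annotate.filter_regions(regions["B"], min_tags=thr.min_tags)
        ov = cobind.overlap_regions(regions_a, regions_b)
        merged = cobind.merge_and_standardize(
            regions_a, regions_b, ov.pairs, width_bp=thr.cobind_width
        )
        counts_a = cobind.count_tags(merged, regions_a)
        counts_b = cobind.count_tags(merged, regions_b)
        merged_out = merged.assign(tag_count_A=counts_a.values, tag_count_B=counts_b.values)
        merged_out.to_csv(outdir / "merged_cobound.tsv", sep="\t", index=False)

        correlations: dict[str, float | None] = {
            "all_cobound": cobind.binding_correlation(counts_a, counts_b)
        }
        if genes is not None:
            merged_regions = merged.rename(
                columns={"std_start": "start", "std_end": "end", "merged_id": "region_id"}
            )[["chrom", "start", "end", "region_id"]]
            merged_ann = annotate.nearest_tss(merged_regions, genes)
            near = (merged_ann["abs_distance"] <= thr.promoter_bp).to_numpy()
            correlations["promoter"] = cobind.binding_correlation(
                counts_a, counts_b, subset=near
            )
            if calls is not None:
                sens_genes = set(
                    calls.loc[calls["lsd1_sensitive"], "gene_id"]
                )
                sens = near & merged_ann["nearest_gene_id"].isin(sens_genes).to_numpy()
                correlations["promoter_sensitive"] = cobind.binding_correlation(
                    counts_a, counts_b, subset=sens
                )
            cobound_a_ids = ov.a_cobound
            co_ann = annotate.nearest_tss(
                regions_a[regions_a["region_id"].isin(cobound_a_ids)], genes
            )
            single_ann = annotate.nearest_tss(
                regions_a[~regions_a["region_id"].isin(cobound_a_ids)], genes
            )
            proportions = (
                cobind.cobound_gene_proportions(co_ann, single_ann, calls)
                if calls is not None
                else None
            )
        else:
            proportions = None
        report["stages"]["cobinding"] = {
            "n_cobound_pairs": len(ov.pairs),
            "n_a_only": len(ov.a_only),
            "n_b_only": len(ov.b_only),
            "n_merged": len(merged),
            "correlations": correlations,
            "gene_proportions": proportions,
        }

    if peptides is not None:
        hits = signals.call_phospho_hits(peptides)
        pd.DataFrame(
            {"peptide_id": peptides["peptide_id"], "positive": hits.positive.to_numpy()}
        ).to_csv(outdir / "peptide_hits.tsv", sep="\t", index=False)
        report["stages"]["peptides"] = {
            "n_peptides": len(peptides),
            "n_positive": int(hits.positive.sum()),
            "threshold": hits.threshold,
            "degenerate": hits.degenerate,
        }

    if images:
        tnfi = [signals.fluorescence_intensity(img, "nuclear") for img in images]
        pcc = [
            signals.pixel_colocalization(
                img.channels["A"], img.channels["B"], img.cell_mask
            )
            for img in images
        ]
        phen = signals.phenotype_partition(tnfi, thr.phenotype_hi, thr.phenotype_lo)
        report["stages"]["images"] = {
            "n_cells": len(images),
            "tnfi_mean": float(np.mean(tnfi)),
            "pcc_mean": float(np.mean([r for r in pcc if r is not None]))
            if any(r is not None for r in pcc)
            else None,
            "phenotype_counts": {
                int(k): int(v) for k, v in zip(*np.unique(phen, return_counts=True))
            },
        }

    io.write_json(report, outdir / "report.json")
    return report
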