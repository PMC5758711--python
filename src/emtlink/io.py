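"""Readers, writers, and validation for the pipeline's on-disk formats.

Genomic intervals are 0-based, half-open throughout. Regions travel as
5-column BED with the normalized tag count stored in the score field
multiplied by 100; chromatin states as 4-column BED; gene annotations,
expression tables, and peptide tables as header-named TSV; coverage as
bedGraph; truth and reports as JSON; cell images as per-cell TSV grids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import CellImage

GENE_COLUMNS = ["chrom", "tss", "strand", "gene_id"]
EXPRESSION_COLUMNS = [
    "probe_id",
    "gene_id",
    "baseline_mock",
    "baseline_sirna",
    "stim_mock",
    "stim_sirna",
]


class InputError(ValueError):
    pass


# ---------------------------------------------------------------- genes

def write_genes_tsv(genes: pd.DataFrame, path) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_genes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing gene columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise InputError(f"{path}: duplicate gene ids")
    return df


# --------------------------------------------------------------- regions

def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """5-column BED; score = round(normalized tag count * 100)."""
    out = regions[["chrom", "start", "end", "region_id"]].copy()
    out["score"] = (regions["tag_count"] * 100).round().astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_regions_bed(path, factor: str = "") -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "region_id", "score"],
    )
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0] + 1
        raise InputError(f"{path}: start >= end at line {bad}")
    df["tag_count"] = df.pop("score") / 100.0
    df["factor"] = factor
    return df


def write_states_bed(states: pd.DataFrame, path) -> None:
    states[["chrom", "start", "end", "state"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_states_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "state"]
    )
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0] + 1
        raise InputError(f"{path}: start >= end at line {bad}")
    return df


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )
    if (df["value"] < 0).any():
        raise InputError(f"{path}: negative coverage values")
    return df


def write_bedgraph(coverage: pd.DataFrame, path) -> None:
    coverage[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ------------------------------------------------------------ expression

def write_expression_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path, require_sirna: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = EXPRESSION_COLUMNS if require_sirna else EXPRESSION_COLUMNS[:3]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing expression columns {missing}")
    if df["probe_id"].duplicated().any():
        raise InputError(f"{path}: duplicate probe ids")
    return df


def write_peptides_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_peptides_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"peptide_id", "mean_signal"} - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing peptide columns {sorted(missing)}")
    return df


# ----------------------------------------------------------------- sets

def read_gmt(path) -> dict[str, set]:
    """GMT-style category sets: name <tab> description <tab> gene ids..."""
    sets: dict[str, set] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise InputError(f"{path}: line {i}: expected name, description, genes")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, set], path, description: str = ".") -> None:
    lines = [
        "\t".join([name, description, *sorted(members)])
        for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta_protein(path) -> str:
    """First record of a protein FASTA, as a plain residue string."""
    from Bio import SeqIO

    for record in SeqIO.parse(str(path), "fasta"):
        return str(record.seq).upper()
    raise InputError(f"{path}: no FASTA records")


# ---------------------------------------------------------------- images

def write_cell_image(image: CellImage, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name, grid in image.channels.items():
        np.savetxt(d / f"channel_{name}.tsv", grid, delimiter="\t", fmt="%.6g")
    np.savetxt(d / "nuclear_mask.tsv", image.nuclear_mask.astype(int), delimiter="\t", fmt="%d")
    np.savetxt(d / "cell_mask.tsv", image.cell_mask.astype(int), delimiter="\t", fmt="%d")
    (d / "meta.json").write_text(
        json.dumps({"background_value": image.background_value, "image_id": image.image_id})
    )


def read_cell_image(directory) -> CellImage:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    channels = {
        p.stem.removeprefix("channel_"): np.loadtxt(p, delimiter="\t")
        for p in sorted(d.glob("channel_*.tsv"))
    }
    return CellImage(
        channels=channels,
        nuclear_mask=np.loadtxt(d / "nuclear_mask.tsv", delimiter="\t").astype(bool),
        cell_mask=np.loadtxt(d / "cell_mask.tsv", delimiter="\t").astype(bool),
        background_value=float(meta["background_value"]),
        image_id=meta.get("image_id", d.name),
    )


# ------------------------------------------------------------ validation

@dataclass
class FileReport:
    path: str
    format: str
    n_rows: int = 0
    violations: list[str] = field(default_factory=list)


def validate_inputs(paths: dict[str, str]) -> list[FileReport]:
    """Validate a mapping of data kind -> path; report violations per file.

    Checks: readability, required columns, half-open intervals
    (start < end), duplicate ids, non-numeric values. Violations carry
    1-based line numbers where applicable.
    """
    reports = []
    for kind, path in paths.items():
        fmt = {
            "genes": "tsv",
            "expression": "tsv",
            "peptides": "tsv",
            "peaks_a": "bed",
            "peaks_b": "bed",
            "states": "bed",
            "coverage": "bedgraph",
        }.get(kind, "unknown")
        rep = FileReport(path=str(path), format=fmt)
        try:
            text = Path(path).read_text()
        except OSError as exc:
            rep.violations.append(f"unreadable: {exc}")
            reports.append(rep)
            continue
        lines = [ln for ln in text.splitlines() if ln.strip()]
        rep.n_rows = len(lines)
        if fmt in ("bed", "bedgraph"):
            for i, line in enumerate(lines, start=1):
                parts = line.split("\t")
                if len(parts) < 4:
                    rep.violations.append(f"line {i}: fewer than 4 columns")
                    continue
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError:
                    rep.violations.append(f"line {i}: non-numeric coordinates")
                    continue
                if start >= end:
                    rep.violations.append(f"line {i}: start >= end ({start} >= {end})")
        elif fmt == "tsv":
            header = lines[0].split("\t") if lines else []
            required = {
                "genes": GENE_COLUMNS,
                "expression": EXPRESSION_COLUMNS,
                "peptides": ["peptide_id", "mean_signal"],
            }[kind]
            for col in required:
                if col not in header:
                    rep.violations.append(f"missing column {col!r}")
            if "gene_id" in header or "probe_id" in header or "peptide_id" in header:
                idcol = next(
                    c for c in ("probe_id", "peptide_id", "gene_id") if c in header
                )
                idx = header.index(idcol)
                seen: dict[str, int] = {}
                for i, line in enumerate(lines[1:], start=2):
                    parts = line.split("\t")
                    if len(parts) <= idx:
                        rep.violations.append(f"line {i}: short row")
                        continue
                    v = parts[idx]
                    if v in seen:
                        rep.violations.append(
                            f"line {i}: duplicate {idcol} {v!r} (first at line {seen[v]})"
                        )
                    else:
                        seen[v] = i
        reports.append(rep)
    return reports


# ------------------------------------------------------------------ json

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
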