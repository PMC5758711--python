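"""Configuration objects for simulation and pipeline runs.

All genomic coordinates in this package are 0-based, half-open intervals.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    The defaults emulate the statistical structure of a stimulated-EMT
    knockdown experiment: a minority of probes induced or repressed on
    stimulation, roughly 42% of induced and 24% of repressed probes
    reversible on knockdown, factor-A peaks concentrated near the TSSs of
    reversible induced genes, promoter-restricted co-binding of a second
    factor, CSC-biased expression among the reversible genes, a peptide
    array with a few strong kinase substrates, and paired fluorescence
    channels with a tunable pixel correlation.
    """

    seed: int = 0
    # genome / expression
    n_genes: int = 1000
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000}
    )
    frac_induced: float = 0.18
    frac_repressed: float = 0.17
    frac_sensitive_given_induced: float = 0.417
    frac_sensitive_given_repressed: float = 0.236
    effect_log2fc_mean: float = 2.0
    effect_log2fc_sd: float = 0.3
    noise_sd: float = 0.1
    base_log2_mean: float = 7.0
    base_log2_sd: float = 1.0
    # CSC / NCSC compartment bias
    frac_csc_informative: float = 0.6
    csc_bias_rate: float = 0.85
    # peaks
    n_peaks: int = 600
    n_peaks_b: int | None = None
    peak_width: int = 300
    frac_peaks_near_direct: float = 0.6
    frac_direct_given_sensitive: float = 0.5
    near_distance_sd: float = 500.0
    tag_mean: float = 30.0
    tag_sd: float = 5.0
    tag_floor: float = 13.0
    frac_low_tag: float = 0.05
    promoter_bp: int = 1000
    cobind_rate_at_promoters: float = 0.6
    cobind_rate_background: float = 0.05
    tag_rho_distal: float = 0.05
    tag_rho_promoter: float = 0.35
    tag_rho_sensitive_promoter: float = 0.8
    state_seg_min: int = 5_000
    state_seg_max: int = 50_000
    # peptide array
    n_peptides: int = 201
    n_hits: int = 15
    hit_signal: float = 50.0
    background_mean: float = 5.0
    background_sd: float = 1.5
    peptide_length: int = 15
    peptide_step: int = 3
    # cell images
    img_n_cells: int = 8
    img_grid: int = 64
    img_channel_means: tuple[float, float] = (200.0, 150.0)
    img_channel_sds: tuple[float, float] = (40.0, 30.0)
    img_rho: float = 0.38
    img_background: float = 10.0
    img_cell_radius_frac: float = 0.45
    img_nuclear_radius_frac: float = 0.25

    def validate(self) -> "SimConfig":
        for name in (
            "frac_induced",
            "frac_repressed",
            "frac_sensitive_given_induced",
            "frac_sensitive_given_repressed",
            "frac_peaks_near_direct",
            "frac_direct_given_sensitive",
            "cobind_rate_at_promoters",
            "cobind_rate_background",
            "csc_bias_rate",
            "frac_csc_informative",
            "frac_low_tag",
        ):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name}={v} must lie in [0, 1]")
        _check(
            self.frac_induced + self.frac_repressed <= 1.0,
            "frac_induced + frac_repressed exceeds 1",
        )
        _check(self.n_genes >= 0, "n_genes must be non-negative")
        _check(len(self.chrom_sizes) > 0, "chrom_sizes must be non-empty")
        for chrom, size in self.chrom_sizes.items():
            _check(int(size) > 0, f"chromosome {chrom} has non-positive length {size}")
        _check(self.noise_sd >= 0, "noise_sd must be non-negative")
        _check(self.effect_log2fc_sd >= 0, "effect_log2fc_sd must be non-negative")
        _check(self.peak_width > 0, "peak_width must be positive")
        _check(self.n_hits <= self.n_peptides, "n_hits exceeds n_peptides")
        for name in ("hit_signal", "background_mean", "background_sd"):
            _check(getattr(self, name) >= 0, f"{name} must be non-negative")
        _check(self.img_grid >= 8, "image grid size must be at least 8")
        _check(abs(self.img_rho) <= 1.0, "img_rho must lie in [-1, 1]")
        _check(
            self.img_cell_radius_frac <= 0.5,
            "cell mask radius exceeds the image grid",
        )
        _check(
            self.img_nuclear_radius_frac <= self.img_cell_radius_frac,
            "nuclear mask must fit inside the cell mask",
        )
        return self

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["chrom_sizes"] = dict(self.chrom_sizes)
        d["img_channel_means"] = list(self.img_channel_means)
        d["img_channel_sds"] = list(self.img_channel_sds)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "img_channel_means" in kwargs:
            kwargs["img_channel_means"] = tuple(kwargs["img_channel_means"])
        if "img_channel_sds" in kwargs:
            kwargs["img_channel_sds"] = tuple(kwargs["img_channel_sds"])
        return cls(**kwargs).validate()


@dataclass
class Thresholds:
    """Calling thresholds shared across pipeline stages (log2 / bp units)."""

    de_log2: float = 0.5
    min_tags: float = 12.2
    direct_bp: int = 5000
    cobind_width: int = 300
    promoter_bp: int = 1000
    metaprofile_bin_bp: int = 100
    metaprofile_half_window_bp: int = 1500
    phenotype_hi: float = 1100.0
    phenotype_lo: float = 500.0

    def validate(self) -> "Thresholds":
        for f_ in dataclasses.fields(self):
            v = getattr(self, f_.name)
            _check(v > 0, f"threshold {f_.name}={v} must be positive")
        _check(self.phenotype_lo < self.phenotype_hi, "phenotype_lo must be < phenotype_hi")
        return self


@dataclass
class RunConfig:
    """End-to-end pipeline run configuration.

    Exactly one of ``simulation`` (a :class:`SimConfig`) or ``inputs``
    (paths to on-disk tables) supplies each data kind.
    """

    outdir: str = "emtlink_run"
    seed: int = 0
    simulation: SimConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    distance_bins: list[int] = field(
        default_factory=lambda: [1000, 5000, 10_000, 100_000]
    )

    _INPUT_KEYS = {
        "genes",
        "expression",
        "peaks_a",
        "peaks_b",
        "states",
        "peptides",
        "images",
    }

    def validate(self) -> "RunConfig":
        if self.simulation is not None and self.inputs:
            raise ConfigError(
                "config supplies both a simulation block and input paths for the "
                "same data kinds; choose one"
            )
        if self.simulation is None and not self.inputs:
            raise ConfigError("config must supply either a simulation block or inputs")
        unknown = set(self.inputs) - self._INPUT_KEYS
        if unknown:
            raise ConfigError(f"unknown input kinds: {sorted(unknown)}")
        self.thresholds.validate()
        bins = list(self.distance_bins)
        _check(bins == sorted(bins) and len(set(bins)) == len(bins) and all(b > 0 for b in bins),
               "distance_bins must be strictly increasing positive integers")
        if self.simulation is not None:
            self.simulation.validate()
        return self

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        kwargs = dict(d)
        if "simulation" in kwargs and kwargs["simulation"] is not None:
            kwargs["simulation"] = SimConfig.from_dict(kwargs["simulation"])
        if "thresholds" in kwargs:
            kwargs["thresholds"] = Thresholds(**kwargs["thresholds"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ConfigError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**kwargs).validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "outdir": self.outdir,
            "seed": self.seed,
            "inputs": dict(self.inputs),
            "thresholds": dataclasses.asdict(self.thresholds),
            "distance_bins": list(self.distance_bins),
        }
        d["simulation"] = None if self.simulation is None else self.simulation.to_dict()
        return d
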