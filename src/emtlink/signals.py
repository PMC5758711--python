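"""Peptide-array hit calling, motif scanning, and fluorescence quantification.

Covers the non-genomic quantification used alongside the genomic pipeline:
calling kinase-substrate positives on an overlapping-peptide array
(mean + k*SD rule), scanning a protein for residue-class motifs, total
nuclear / total cell fluorescence intensity (TNFI / TCFI, background
subtracted), pixel-level colocalization (Pearson, in [-1, 1]), and the
partition of cells into high/moderate/low intensity phenotypes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

# Printed intensity thresholds for partitioning circulating tumour cells:
# (hi, lo) — phenotype 1 above hi, 3 below lo, 2 in the closed band between.
LSD1_S111P_PHENOTYPE_THRESHOLDS = (1100.0, 500.0)
LSD1_PHENOTYPE_THRESHOLDS = (1500.0, 600.0)


class SignalInputError(ValueError):
    """Raised on malformed signal-quantification inputs."""


@dataclass
class CellImage:
    """Pixel grids per channel plus nuclear/cell masks and a background level."""

    channels: dict[str, np.ndarray]
    nuclear_mask: np.ndarray
    cell_mask: np.ndarray
    background_value: float = 0.0
    image_id: str = ""

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        shapes |= {self.nuclear_mask.shape, self.cell_mask.shape}
        if len(shapes) != 1:
            raise SignalInputError("channels and masks must share one shape")
        if np.any(self.nuclear_mask & ~self.cell_mask):
            raise SignalInputError("nuclear mask must lie inside the cell mask")
        if self.background_value < 0:
            raise SignalInputError("background_value must be non-negative")


@dataclass
class HitCallResult:
    positive: pd.Series
    threshold: float
    mean: float
    sd: float
    degenerate: bool = False
    warnings: list[str] = field(default_factory=list)


def call_phospho_hits(
    signals: pd.DataFrame | pd.Series | np.ndarray,
    k_sd: float = 2.0,
    population_sd: bool = True,
) -> HitCallResult:
    """Call array positives at mean + ``k_sd`` standard deviations.

    The threshold is computed over *all* mean signals on the array and a
    peptide is positive when its signal is greater than or equal to the
    threshold. With ``population_sd`` the SD divides by n (default);
    otherwise by n-1. A zero SD (all signals equal) yields no positives
    and sets the degenerate flag rather than calling everything positive.
    """
    if isinstance(signals, pd.DataFrame):
        values = signals["mean_signal"]
    else:
        values = pd.Series(np.asarray(signals, dtype=float))
    if len(values) < 2:
        raise SignalInputError("hit calling requires at least two peptides")
    if (values < 0).any():
        raise SignalInputError("mean signals must be non-negative")
    mean = float(values.mean())
    sd = float(values.std(ddof=0 if population_sd else 1))
    threshold = mean + k_sd * sd
    if sd == 0.0:
        return HitCallResult(
            positive=pd.Series(False, index=values.index),
            threshold=threshold,
            mean=mean,
            sd=sd,
            degenerate=True,
            warnings=["zero signal dispersion: no positives called"],
        )
    return HitCallResult(
        positive=values >= threshold, threshold=threshold, mean=mean, sd=sd
    )


def _compile_pattern(pattern: str) -> re.Pattern:
    """Compile the residue-class pattern DSL to a regex.

    Grammar: plain residues match themselves, ``x`` (or ``X``) matches any
    residue, ``[ST]`` matches a residue class. Example: ``[ST]x[KR]``.
    """
    out = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.find("]", i)
            if j < 0:
                raise SignalInputError(f"unterminated class in pattern {pattern!r}")
            members = pattern[i + 1 : j]
            bad = set(members) - AA_ALPHABET
            if not members or bad:
                raise SignalInputError(
                    f"invalid residue class {members!r} in pattern {pattern!r}"
                )
            out.append("[" + members + "]")
            i = j + 1
        elif ch in ("x", "X"):
            out.append(".")
            i += 1
        elif ch in AA_ALPHABET:
            out.append(ch)
            i += 1
        else:
            raise SignalInputError(f"invalid symbol {ch!r} in pattern {pattern!r}")
    return re.compile("(?=(" + "".join(out) + "))")


def scan_motif_windows(
    protein_seq: str,
    patterns: list[str],
    window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Find all (overlapping) pattern occurrences touching a residue window.

    ``window`` is a 1-based inclusive residue range; a match overlaps the
    window when any of its residues falls inside. Returns a frame with
    pattern, 1-based offset, and the matched substring, ordered by offset
    then pattern.
    """
    seq = protein_seq.upper()
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise SignalInputError(f"invalid residues in protein sequence: {sorted(bad)}")
    if window is not None and window[0] > window[1]:
        return pd.DataFrame(columns=["pattern", "offset", "match"])
    rows = []
    for pat in patterns:
        rx = _compile_pattern(pat)
        for m in rx.finditer(seq):
            s = m.start() + 1  # 1-based
            matched = m.group(1)
            e = s + len(matched) - 1
            if window is None or (e >= window[0] and s <= window[1]):
                rows.append((pat, s, matched))
    rows.sort(key=lambda r: (r[1], r[0]))
    return pd.DataFrame(rows, columns=["pattern", "offset", "match"])


def fluorescence_intensity(
    image: CellImage, mask_kind: str = "nuclear", channel: str | None = None
) -> float:
    """Total background-subtracted fluorescence over a mask (TNFI / TCFI).

    Sum of channel intensity over the chosen mask minus
    ``background_value`` times the mask area. A negative result means the
    background estimate exceeds the masked signal; it is returned as-is.
    """
    if mask_kind not in ("nuclear", "cell"):
        raise SignalInputError(f"mask_kind must be 'nuclear' or 'cell', got {mask_kind!r}")
    mask = image.nuclear_mask if mask_kind == "nuclear" else image.cell_mask
    if not mask.any():
        raise SignalInputError(
            f"{mask_kind} mask is empty: fluorescence intensity is undefined"
        )
    if channel is None:
        channel = next(iter(image.channels))
    grid = image.channels[channel]
    return float(grid[mask].sum() - image.background_value * int(mask.sum()))


def pixel_colocalization(
    channel_a: np.ndarray, channel_b: np.ndarray, mask: np.ndarray
) -> float | None:
    """Pearson correlation of two channels over masked pixels.

    -1 = inverse of colocalization, 0 = none, +1 = perfect. Returns None
    (undefined) when fewer than 3 pixels are masked or a channel is
    constant within the mask — never a silent 0.
    """
    a = np.asarray(channel_a, dtype=float)[mask]
    b = np.asarray(channel_b, dtype=float)[mask]
    if a.size < 3:
        return None
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    r = float(np.corrcoef(a, b)[0, 1])
    return max(-1.0, min(1.0, r))


def phenotype_partition(
    values, hi: float, lo: float
) -> np.ndarray:
    """Partition intensities into phenotypes 1 (high), 2 (moderate), 3 (low).

    1 iff value > hi; 3 iff value < lo; the closed band [lo, hi] is
    phenotype 2, so boundary values are moderate.
    """
    if not lo < hi:
        raise SignalInputError(f"lo ({lo}) must be below hi ({hi})")
    v = np.asarray(values, dtype=float)
    return np.where(v > hi, 1, np.where(v < lo, 3, 2)).astype(int)
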