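"""Differential-expression direction, knockdown-sensitivity, and CSC-bias calls.

All calls are simple thresholded log2 contrasts with strict inequalities at
the boundary: a probe is induced when the stimulated-minus-baseline change
exceeds the threshold (default log2 0.5), and an induced/repressed probe is
knockdown-sensitive ("reversible") when the siRNA-minus-mock contrast in
the stimulated state crosses the same threshold in the opposing direction.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

DIRECTIONS = ("induced", "repressed", "unchanged")
CSC_BIAS = ("csc", "ncsc", "none")


class ExpressionInputError(ValueError):
    """Raised when an expression table lacks a required arm or value."""


def _require(table: pd.DataFrame, columns: list[str]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ExpressionInputError(f"expression table missing columns: {missing}")
    for col in columns:
        bad = table.loc[table[col].isna(), "probe_id"]
        if len(bad):
            raise ExpressionInputError(
                f"missing {col} values for probes: {list(bad.head(5))}"
                + ("..." if len(bad) > 5 else "")
            )


def call_emt_direction(table: pd.DataFrame, threshold_log2: float = 0.5) -> pd.Series:
    """Label probes induced / repressed / unchanged on stimulation.

    induced iff stim_mock - baseline_mock > threshold; repressed iff
    < -threshold; otherwise unchanged. Inequalities are strict, so a
    change of exactly the threshold is unchanged.
    """
    _require(table, ["probe_id", "baseline_mock", "stim_mock"])
    diff = table["stim_mock"] - table["baseline_mock"]
    out = pd.Series(
        np.where(
            diff > threshold_log2,
            "induced",
            np.where(diff < -threshold_log2, "repressed", "unchanged"),
        ),
        index=table.index,
        name="emt_direction",
    )
    return out


def call_lsd1_sensitivity(
    table: pd.DataFrame,
    directions: pd.Series,
    threshold_log2: float = 0.5,
    mode: str = "opposing_shift",
) -> pd.Series:
    """Flag probes whose stimulation change is reversed by knockdown.

    Default ``opposing_shift`` mode: an induced probe is sensitive iff
    stim_sirna - stim_mock < -threshold; a repressed probe iff
    > +threshold; unchanged probes are never sensitive.

    ``toward_baseline`` mode instead asks whether knockdown returned the
    stimulated level to within the threshold of the mock baseline:
    |stim_sirna - baseline_mock| <= threshold for induced or repressed
    probes.
    """
    if mode not in ("opposing_shift", "toward_baseline"):
        raise ValueError(f"unknown sensitivity mode {mode!r}")
    cols = ["probe_id", "stim_mock", "stim_sirna"]
    if mode == "toward_baseline":
        cols.append("baseline_mock")
    _require(table, cols)
    if mode == "opposing_shift":
        diff = table["stim_sirna"] - table["stim_mock"]
        sensitive = np.where(
            directions == "induced",
            diff < -threshold_log2,
            np.where(directions == "repressed", diff > threshold_log2, False),
        )
    else:
        back = (table["stim_sirna"] - table["baseline_mock"]).abs() <= threshold_log2
        sensitive = np.where(directions != "unchanged", back, False)
    return pd.Series(sensitive.astype(bool), index=table.index, name="lsd1_sensitive")


def call_csc_bias(table: pd.DataFrame, threshold_log2: float = 0.5) -> pd.Series:
    """Label probes by expression compartment: csc, ncsc, or none.

    csc iff csc_log2 - ncsc_log2 > threshold; ncsc iff < -threshold.
    """
    _require(table, ["probe_id", "csc_log2", "ncsc_log2"])
    diff = table["csc_log2"] - table["ncsc_log2"]
    return pd.Series(
        np.where(
            diff > threshold_log2, "csc", np.where(diff < -threshold_log2, "ncsc", "none")
        ),
        index=table.index,
        name="csc_bias",
    )


def make_calls(
    table: pd.DataFrame,
    threshold_log2: float = 0.5,
    sensitivity_mode: str = "opposing_shift",
    with_csc: bool = True,
) -> pd.DataFrame:
    """Convenience: full per-probe call table (direction, sensitivity, bias)."""
    directions = call_emt_direction(table, threshold_log2)
    sensitive = call_lsd1_sensitivity(table, directions, threshold_log2, sensitivity_mode)
    calls = pd.DataFrame(
        {
            "probe_id": table["probe_id"],
            "gene_id": table.get("gene_id", table["probe_id"]),
            "emt_direction": directions,
            "lsd1_sensitive": sensitive,
        }
    )
    if with_csc and {"csc_log2", "ncsc_log2"} <= set(table.columns):
        calls["csc_bias"] = call_csc_bias(table, threshold_log2)
    return calls


def _percent_1dp(numer: int, denom: int) -> float:
    """Exact half-up rounding of 100*numer/denom to one decimal place."""
    pct = Decimal(100 * numer) / Decimal(denom)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_reversibility(
    directions: pd.Series, sensitivity: pd.Series
) -> pd.DataFrame:
    """Reversibility table: per direction, total probes, reversible, percent.

    Percent is 100 * n_reversible / n_total, rounded half-up to one
    decimal. A direction with no probes reports NaN (undefined), not 0.
    """
    if len(directions) != len(sensitivity):
        raise ExpressionInputError("direction and sensitivity vectors differ in length")
    rows = []
    for direction in ("induced", "repressed"):
        mask = (directions == direction).to_numpy()
        n_total = int(mask.sum())
        n_rev = int(sensitivity.to_numpy()[mask].sum())
        pct = _percent_1dp(n_rev, n_total) if n_total else float("nan")
        rows.append((direction, n_total, n_rev, pct))
    return pd.DataFrame(rows, columns=["direction", "n_total", "n_reversible", "percent"])


def reversibility_from_counts(n_total: int, n_reversible: int) -> float:
    """Percent reversible from plain counts (half-up, one decimal)."""
    if n_total <= 0:
        return float("nan")
    return _percent_1dp(n_reversible, n_total)
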