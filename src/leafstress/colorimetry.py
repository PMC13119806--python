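"""Replicate-level CIELAB color aggregation and anatomical derived traits.

Color is read on the adaxial leaf surface with a colorimeter: several leaves
per replicate, several readings per leaf.  Leaves are the sampling unit, so
aggregation averages readings within each leaf first and then averages the
per-leaf means (unweighted); the reported SE is over leaves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: required columns of a color readings table
COLOR_COLUMNS = ("leaf_id", "reading_index", "L_star", "a_star", "b_star")

#: fixed long-format trait table columns
TRAIT_COLUMNS = ("treatment", "period", "replicate", "trait", "value", "units")


@dataclass(frozen=True)
class ColorAggregate:
    """Replicate-level CIELAB summary: means and SEs over leaves."""

    L_star: float
    a_star: float
    b_star: float
    se_L: float
    se_a: float
    se_b: float
    n_leaves: int


def aggregate_color(readings: pd.DataFrame) -> ColorAggregate:
    """Aggregate raw per-leaf CIELAB readings to replicate level.

    Parameters
    ----------
    readings
        Table with columns ``leaf_id, reading_index, L_star, a_star, b_star``.
        Reads per leaf may be unequal; leaves are weighted equally.

    Returns
    -------
    ColorAggregate
        Unweighted mean over per-leaf means, with SE over leaves (0 when a
        single leaf is supplied).
    """
    if readings is None or len(readings) == 0:
        raise ValueError("no color readings supplied")
    missing = [c for c in ("leaf_id", "L_star", "a_star", "b_star") if c not in readings]
    if missing:
        raise ValueError(f"color readings missing columns: {missing}")
    bad_L = readings["L_star"]
    if (bad_L < 0).any() or (bad_L > 100).any():
        raise ValueError("L* readings must lie in [0, 100]")

    per_leaf = readings.groupby("leaf_id")[["L_star", "a_star", "b_star"]].mean()
    n = len(per_leaf)
    means = per_leaf.mean(axis=0)
    if n > 1:
        ses = per_leaf.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        ses = pd.Series(0.0, index=means.index)
    return ColorAggregate(
        L_star=float(means["L_star"]),
        a_star=float(means["a_star"]),
        b_star=float(means["b_star"]),
        se_L=float(ses["L_star"]),
        se_a=float(ses["a_star"]),
        se_b=float(ses["b_star"]),
        n_leaves=n,
    )


def compute_psr(pt: float, st: float) -> float:
    """Palisade-to-spongy thickness ratio, rounded to 2 decimals.

    PSR = Pt / St, the classic anatomical drought-response index.  Rounding
    to two decimals matches the convention of published anatomy tables.
    """
    if st <= 0:
        raise ValueError("spongy tissue thickness must be positive")
    if pt <= 0:
        raise ValueError("palisade tissue thickness must be positive")
    return round(pt / st, 2)


def assemble_trait_records(
    color: pd.DataFrame | None = None,
    anatomy: pd.DataFrame | None = None,
    external: pd.DataFrame | None = None,
    units: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Merge per-replicate measurements into one long-format trait table.

    Each input is either already long (columns ``treatment, period,
    replicate, trait, value`` and optionally ``units``) or wide
    (``treatment, period, replicate`` plus one column per trait).  Duplicate
    (treatment, period, replicate, trait) keys raise.
    """
    units = units or {}
    frames = []
    for part in (color, anatomy, external):
        if part is None or len(part) == 0:
            continue
        frames.append(_to_long(part, units))
    if not frames:
        return pd.DataFrame(columns=list(TRAIT_COLUMNS))
    table = pd.concat(frames, ignore_index=True)
    key_cols = ["treatment", "period", "replicate", "trait"]
    dupes = table.duplicated(subset=key_cols)
    if dupes.any():
        offending = table.loc[dupes, key_cols].to_records(index=False).tolist()
        raise ValueError(f"duplicate trait records for keys: {offending[:5]}")
    return table[list(TRAIT_COLUMNS)].reset_index(drop=True)


def _to_long(part: pd.DataFrame, units: dict[str, str]) -> pd.DataFrame:
    base = {"treatment", "period", "replicate"}
    if not base.issubset(part.columns):
        raise ValueError(f"input lacks design columns {sorted(base - set(part.columns))}")
    if "trait" in part.columns and "value" in part.columns:
        out = part.copy()
        if "units" not in out.columns:
            out["units"] = out["trait"].map(lambda t: units.get(t, ""))
        return out[list(TRAIT_COLUMNS)]
    value_cols = [c for c in part.columns if c not in base]
    out = part.melt(
        id_vars=sorted(base), value_vars=value_cols, var_name="trait", value_name="value"
    )
    out["units"] = out["trait"].map(lambda t: units.get(t, ""))
    return out[list(TRAIT_COLUMNS)]


def read_trait_table(path) -> pd.DataFrame:
    """Read a long-format trait table CSV, validating the fixed header."""
    table = pd.read_csv(path)
    missing = [c for c in TRAIT_COLUMNS if c not in table.columns and c != "units"]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    if "units" not in table.columns:
        table["units"] = ""
    return table[list(TRAIT_COLUMNS)]


def write_trait_table(table: pd.DataFrame, path) -> None:
    table[list(TRAIT_COLUMNS)].to_csv(path, index=False)
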