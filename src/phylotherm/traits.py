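"""Growth-temperature trait tables.

A trait table is a TSV with one row per tree tip: required column ``tip`` and
``t_min`` (minimum growth temperature, degrees C), optional ``t_opt``,
``t_max``, ``source`` (isolation source) and ``group`` (clade label such as
L / L' / M).  Unknown columns are preserved.  Missing temperatures are
explicit NaN; rows with missing ``t_min`` are excluded from binary
cold/not-cold analyses downstream.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import TraitTableError
from .tree import Phylogeny

__all__ = ["read_trait_table", "classify_cold", "align_to_tree",
           "COLD_THRESHOLD_C"]

logger = logging.getLogger(__name__)

#: Default cold-adaptation cutoff: a type strain whose minimum growth
#: temperature is at or below this value (degrees C) counts as cold-adapted.
COLD_THRESHOLD_C = 5.0

_TEMP_COLS = ("t_min", "t_opt", "t_max")


def read_trait_table(path) -> pd.DataFrame:
    """Read a tip trait TSV into a DataFrame indexed by tip label.

    Raises :class:`TraitTableError` naming the 1-based data line for
    non-numeric temperatures, duplicate tips, or missing required columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "tip" not in df.columns:
        raise TraitTableError("trait table must have a 'tip' column")
    if "t_min" not in df.columns:
        raise TraitTableError("trait table must have a 't_min' column")
    dup = df["tip"][df["tip"].duplicated()]
    if len(dup):
        raise TraitTableError(f"duplicate tip rows: {sorted(set(dup))}")
    for col in _TEMP_COLS:
        if col not in df.columns:
            continue
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.str.strip() != "") \
            & (raw.str.upper() != "NA")
        if bad.any():
            line = int(np.flatnonzero(bad.values)[0]) + 2  # +header, 1-based
            raise TraitTableError(
                f"non-numeric {col} value {raw[bad].iloc[0]!r} at line {line}")
        df[col] = parsed
        if np.isinf(df[col]).any():
            raise TraitTableError(f"non-finite {col} value")
    present = df[list(c for c in _TEMP_COLS if c in df)].dropna()
    if {"t_min", "t_opt", "t_max"} <= set(present.columns):
        viol = ~((present["t_min"] <= present["t_opt"])
                 & (present["t_opt"] <= present["t_max"]))
        if viol.any():
            warnings.warn(f"{int(viol.sum())} rows violate "
                          "t_min <= t_opt <= t_max", stacklevel=2)
    return df.set_index("tip")


def classify_cold(table: pd.DataFrame,
                  threshold: float = COLD_THRESHOLD_C) -> pd.DataFrame:
    """Add a boolean ``cold`` column: ``t_min <= threshold`` (inclusive).

    Rows with missing ``t_min`` get ``cold = <NA>`` (unclassified) and are
    dropped from binary analyses by callers.  Returns a copy.
    """
    out = table.copy()
    t = out["t_min"]
    cold = pd.array(t <= threshold, dtype="boolean")
    cold[t.isna()] = pd.NA
    out["cold"] = cold
    return out


def align_to_tree(table: pd.DataFrame, tree: Phylogeny) -> pd.DataFrame:
    """Restrict a trait table to tips present in the tree.

    Tips found only on one side are dropped with a logged warning; the
    returned table is ordered as the tree's tips.
    """
    tree_tips = tree.tip_labels
    have = set(table.index)
    missing_in_table = [t for t in tree_tips if t not in have]
    missing_in_tree = sorted(have - set(tree_tips))
    if missing_in_table:
        logger.warning("%d tree tips absent from trait table (dropped): %s",
                       len(missing_in_table), missing_in_table[:5])
    if missing_in_tree:
        logger.warning("%d trait rows absent from tree (dropped): %s",
                       len(missing_in_tree), missing_in_tree[:5])
    keep = [t for t in tree_tips if t in have]
    return table.loc[keep]
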