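"""Temperature-differential hit calling.

Same-temperature replicates are averaged per dsRNA amplicon; amplicons are
then assigned to hit lists by comparing the mean B-score of the cell count at
the low (17 C) and near-optimal (27 C) incubation temperatures:

* ``l17weak``      low counts at 17 C only (b17 <= low, b27 above the floor)
* ``l17weak_a``    low at both but far more extensively at 17 C
* ``l27weak``      low at 27 C only
* ``l_both_weak``  low at both temperatures
* ``l17strong`` / ``l27strong`` / ``l_both_strong``  the high-count analogues

Cell-cycle hit lists (l17caP1 ... l27caP1toP2) flag amplicons whose robust Z
for a cell-cycle parameter is extreme at one temperature but not the other.
Amplicon lists collapse to gene lists by union over a gene's amplicons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COUNT_LISTS = (
    "l17weak",
    "l17weak_a",
    "l27weak",
    "l_both_weak",
    "l17strong",
    "l27strong",
    "l_both_strong",
)

CC_PARAMS = ("P1", "P2", "P3", "P1toP2")
CC_LISTS = tuple(f"l{t}ca{p}" for t in ("17", "27") for p in CC_PARAMS)


@dataclass
class HitThresholds:
    """Cut-offs for list membership; all boundaries are inclusive.

    ``slight_floor`` is the 27 C ceiling for l17weak ("at most slightly
    reduced" at 27 C) and ``delta`` the minimum b27 - b17 separation for
    l17weak_a ("far more extensively" reduced at 17 C); both are exposed
    because the analysis text fixes only the +/-2 outer thresholds.
    """

    low: float = -2.0
    high: float = 2.0
    slight_floor: float = -2.0
    delta: float = 2.0
    z_threshold: float = 3.0


def average_replicates(scores: pd.DataFrame, score_col: str = "bscore") -> pd.DataFrame:
    """Per-amplicon mean of the same-temperature replicate scores.

    ``scores`` needs columns amplicon_id, gene, replicate, temperature and
    ``score_col`` (plus optional ``z_*`` columns, averaged the same way).
    Control wells (amplicon_id 'negative'/'positive') are dropped.  An
    amplicon appearing twice within one replicate is an error; an amplicon
    missing one whole temperature is kept but flagged unscoreable.
    """
    df = scores[~scores["amplicon_id"].isin(["negative", "positive"])].copy()
    dup = df.duplicated(subset=["amplicon_id", "replicate"], keep=False)
    if dup.any():
        wells = df.loc[dup, ["amplicon_id", "replicate", "plate", "row", "col"]] \
            if {"plate", "row", "col"} <= set(df.columns) else df.loc[dup, ["amplicon_id", "replicate"]]
        raise ValueError(f"duplicate amplicon within a replicate:\n{wells.to_string()}")

    z_cols = [c for c in df.columns if c.startswith("z_")]
    rows = []
    for amp, g in df.groupby("amplicon_id", sort=True):
        rec: dict = {"amplicon_id": amp, "gene": g["gene"].iloc[0]}
        for temp, tag in (("17C", "17"), ("27C", "27")):
            sub = g[g["temperature"] == temp]
            vals = sub[score_col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            rec[f"b{tag}"] = float(vals.mean()) if vals.size else np.nan
            rec[f"n_{tag}"] = int(vals.size)
            for zc in z_cols:
                zv = sub[zc].to_numpy(dtype=float)
                zv = zv[np.isfinite(zv)]
                rec[f"{zc}_{tag}"] = float(zv.mean()) if zv.size else np.nan
        rec["unscoreable"] = rec["n_17"] == 0 or rec["n_27"] == 0
        rows.append(rec)
    return pd.DataFrame(rows)


def call_count_hits(scores: pd.DataFrame, thresholds: HitThresholds | None = None) -> pd.DataFrame:
    """Assign amplicons to the cell-count hit lists from their (b17, b27) means."""
    thr = thresholds or HitThresholds()
    df = scores.copy()
    b17 = df["b17"].to_numpy(dtype=float)
    b27 = df["b27"].to_numpy(dtype=float)
    defined = np.isfinite(b17) & np.isfinite(b27)

    low17 = defined & (b17 <= thr.low)
    low27 = defined & (b27 <= thr.low)
    high17 = defined & (b17 >= thr.high)
    high27 = defined & (b27 >= thr.high)

    df["l_both_weak"] = low17 & low27
    df["l17weak"] = low17 & (b27 > thr.slight_floor)
    df["l27weak"] = low27 & (b17 > thr.low)
    df["l17weak_a"] = low17 & low27 & ((b27 - b17) >= thr.delta)
    df["l_both_strong"] = high17 & high27
    df["l17strong"] = high17 & (b27 < thr.high)
    df["l27strong"] = high27 & (b17 < thr.high)
    return df


def call_cellcycle_hits(
    scores: pd.DataFrame,
    thresholds: HitThresholds | None = None,
    z_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Temperature-differential lists from cell-cycle robust Z-scores.

    For each parameter, an amplicon joins the 17 C list when |Z| exceeds the
    threshold at 17 C but not at 27 C (and vice versa).  ``z_map`` maps list
    parameter tags (P1, P2, P3, P1toP2) to the column stems of the averaged
    score table (default ``z_p1`` ... ``z_p1_to_p2``).
    """
    thr = thresholds or HitThresholds()
    stems = z_map or {"P1": "z_p1", "P2": "z_p2", "P3": "z_p3", "P1toP2": "z_p1_to_p2"}
    df = scores.copy()
    for tag, stem in stems.items():
        z17 = np.abs(df[f"{stem}_17"].to_numpy(dtype=float))
        z27 = np.abs(df[f"{stem}_27"].to_numpy(dtype=float))
        ok = np.isfinite(z17) & np.isfinite(z27)
        df[f"l17ca{tag}"] = ok & (z17 > thr.z_threshold) & (z27 <= thr.z_threshold)
        df[f"l27ca{tag}"] = ok & (z27 > thr.z_threshold) & (z17 <= thr.z_threshold)
    return df


def collapse_to_genes(
    hit_table: pd.DataFrame,
    lists: tuple[str, ...] | None = None,
    min_amplicons: int = 1,
) -> pd.DataFrame:
    """Gene-level lists: a gene is on a list iff >= ``min_amplicons`` of its
    amplicons are.  Amplicons without a gene mapping are excluded with a
    warning column rather than an error.
    """
    if lists is None:
        lists = tuple(c for c in hit_table.columns if c in COUNT_LISTS + CC_LISTS)
    mapped = hit_table[hit_table["gene"].notna() & (hit_table["gene"] != "")]
    if len(mapped) < len(hit_table):
        import warnings

        warnings.warn(
            f"{len(hit_table) - len(mapped)} amplicon(s) without gene mapping excluded",
            stacklevel=2,
        )
    if not len(mapped):
        return pd.DataFrame(columns=["gene", *lists])
    agg = mapped.groupby("gene", sort=True)[list(lists)].sum()
    out = (agg >= min_amplicons)
    return out.reset_index()


def list_sizes(hit_table: pd.DataFrame) -> dict[str, int]:
    """Membership counts for every list column present."""
    return {
        c: int(hit_table[c].sum())
        for c in hit_table.columns
        if c in COUNT_LISTS + CC_LISTS
    }
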