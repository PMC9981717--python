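"""Validation statistics: normalized count ratios and twin-spot clone areas.

Knockdown validation experiments report, per gene, the control-normalized mean
cell count at each temperature and the 27 C / 17 C ratio, with the ratio's
standard deviation obtained by first-order error propagation:

    sd(r) = r * sqrt((s27/m27)^2 + (s17/m17)^2)

Ratios above 1.1 are shaded light, above 1.5 dark (fewer cells at the low
temperature).  Twin-spot clone analysis summarizes, per wing disc, the ratio
of marker-homozygous to mutant clone areas and compares temperature groups
with t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

LIGHT_THRESHOLD = 1.1
DARK_THRESHOLD = 1.5


@dataclass
class CountRatio:
    mean_17: float
    mean_27: float
    sd_17: float
    sd_27: float
    ratio_27_to_17: float
    ratio_sd: float
    shading: str  # none | light | dark


def propagate_ratio_sd(m17: float, s17: float, m27: float, s27: float) -> float:
    """Standard deviation of r = m27/m17 by first-order error propagation."""
    r = m27 / m17
    return float(r * np.sqrt((s27 / m27) ** 2 + (s17 / m17) ** 2))


def classify_shading(
    ratio: float, light: float = LIGHT_THRESHOLD, dark: float = DARK_THRESHOLD
) -> str:
    if ratio > dark:
        return "dark"
    if ratio > light:
        return "light"
    return "none"


def normalized_count_ratio(
    counts_17: np.ndarray,
    counts_27: np.ndarray,
    neg_17: float,
    neg_27: float,
    light: float = LIGHT_THRESHOLD,
    dark: float = DARK_THRESHOLD,
) -> CountRatio:
    """Control-normalized 27 C / 17 C cell-count ratio with propagated s.d.

    Replicate counts at each temperature are normalized to that temperature's
    negative-control mean, then averaged; the s.d. uses the sample (ddof=1)
    convention, contributing 0 when only a single replicate exists (as for
    genes analyzed in one well only).  Multiplying all counts at one
    temperature together with its control leaves the result unchanged.
    """
    if neg_17 <= 0 or neg_27 <= 0:
        raise ValueError("negative-control means must be positive")
    c17 = np.asarray(counts_17, dtype=float) / neg_17
    c27 = np.asarray(counts_27, dtype=float) / neg_27
    if c17.size < 1 or c27.size < 1:
        raise ValueError("need at least one replicate per temperature")
    m17, m27 = float(c17.mean()), float(c27.mean())
    if m17 <= 0:
        raise ValueError("17 C normalized mean must be positive for a ratio")
    s17 = float(c17.std(ddof=1)) if c17.size > 1 else 0.0
    s27 = float(c27.std(ddof=1)) if c27.size > 1 else 0.0
    r = m27 / m17
    return CountRatio(
        mean_17=m17,
        mean_27=m27,
        sd_17=s17,
        sd_27=s27,
        ratio_27_to_17=r,
        ratio_sd=propagate_ratio_sd(m17, s17, m27, s27),
        shading=classify_shading(r, light, dark),
    )


def clone_ratio_stats(
    records: pd.DataFrame,
    group_col: str = "temperature",
    equal_var: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Twin-spot clone-area statistics per group, with pairwise t-tests.

    ``records`` has one row per imaginal disc with columns ``area_plus``
    (marker-homozygous clones), ``area_minus`` (mutant clones) and
    ``group_col``.  Returns (per-group summary of the per-disc area ratio,
    pairwise two-sided t-tests on the ratios and on the raw clone areas).
    """
    df = records.copy()
    if (df["area_plus"] <= 0).any() or (df["area_minus"] <= 0).any():
        raise ValueError("clone areas must be positive")
    df["ratio"] = df["area_plus"] / df["area_minus"]

    summaries = []
    for grp, g in df.groupby(group_col, sort=True):
        if len(g) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 discs")
        summaries.append(
            {
                group_col: grp,
                "mean_ratio": float(g["ratio"].mean()),
                "sd_ratio": float(g["ratio"].std(ddof=1)),
                "n": int(len(g)),
                "mean_area_plus": float(g["area_plus"].mean()),
                "mean_area_minus": float(g["area_minus"].mean()),
            }
        )
    summary = pd.DataFrame(summaries)

    tests = []
    for ga, gb in combinations(summary[group_col], 2):
        a = df[df[group_col] == ga]
        b = df[df[group_col] == gb]
        for col in ("ratio", "area_plus", "area_minus"):
            t, p = stats.ttest_ind(a[col], b[col], equal_var=equal_var)
            tests.append(
                {"group_a": ga, "group_b": gb, "quantity": col, "t": float(t), "p": float(p)}
            )
    return summary, pd.DataFrame(tests)
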