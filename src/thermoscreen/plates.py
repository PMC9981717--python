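"""Plate-level normalization for high-content screens.

The screen readout is a cell count per well of a 384-well plate.  Systematic
row and column effects (edge evaporation, dispensing gradients) are removed
with Tukey's two-way median polish; the residuals, scaled by the plate's
median absolute residual, are the B-scores used for hit selection.  Robust
Z-scores provide the analogous per-replicate standardization for cell-cycle
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Consistency factor making the MAD an unbiased sigma estimate under normality.
MAD_SCALE = 1.4826

NEGATIVE_CONTROL = "negative"
POSITIVE_CONTROL = "positive"
CONTROL_TAGS = (NEGATIVE_CONTROL, POSITIVE_CONTROL)


class DegeneratePlateError(ValueError):
    """Raised when a plate's residual MAD is zero and no epsilon fallback is set."""


@dataclass
class WellRecord:
    """One well's identity, condition and measurements."""

    plate_id: str
    row: int
    col: int
    replicate_id: str
    temperature: str
    amplicon_id: str
    gene: str | None
    cell_count: float
    dna_intensities: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cell_count < 0:
            raise ValueError("cell_count must be non-negative")

    @property
    def is_control(self) -> bool:
        return self.amplicon_id in CONTROL_TAGS


@dataclass
class PlateGrid:
    """A plate's counts as a rows x cols matrix, the unit of B-scoring.

    ``control_mask`` marks control wells, ``missing_mask`` marks wells lost to
    imaging failures; missing wells are excluded from every statistic and are
    never imputed.
    """

    plate_id: str
    counts: np.ndarray
    control_mask: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.control_mask = np.asarray(self.control_mask, dtype=bool)
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.counts)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if not (self.counts.shape == self.control_mask.shape == self.missing_mask.shape):
            raise ValueError("counts, control_mask and missing_mask shapes disagree")


@dataclass
class MedianPolishResult:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    iterations: int
    converged: bool


def median_polish(
    matrix: np.ndarray,
    mask: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float | None = None,
) -> MedianPolishResult:
    """Tukey two-way median polish of ``matrix`` (row sweeps first).

    Alternating row/column median subtraction until the change in the sum of
    absolute residuals falls below ``tol`` (default ``1e-6`` times the initial
    sum of absolute residuals).  ``mask`` marks missing cells (True = missing);
    medians are taken over present cells only.  Ties resolve by the midpoint
    convention of ``numpy.median``.

    Returns the additive decomposition ``overall + row + col + residual``,
    which reconstructs every unmasked cell exactly (to floating precision).
    """
    data = np.asarray(matrix, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("median polish needs a matrix with >= 2 rows and >= 2 columns")
    if mask is None:
        mask = ~np.isfinite(data)
    mask = np.asarray(mask, dtype=bool) | ~np.isfinite(data)

    present = ~mask
    empty_rows = np.flatnonzero(present.sum(axis=1) == 0)
    if empty_rows.size:
        raise ValueError(f"row(s) {empty_rows.tolist()} have no unmasked cells")
    empty_cols = np.flatnonzero(present.sum(axis=0) == 0)
    if empty_cols.size:
        raise ValueError(f"column(s) {empty_cols.tolist()} have no unmasked cells")

    resid = np.where(mask, np.nan, data)
    n_rows, n_cols = data.shape
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    overall = 0.0

    # Tolerance is relative to the initial residual spread about the overall
    # median: shift-invariant and scale-equivariant, so B-scores stay exactly
    # invariant under positive affine transforms of the plate.
    init_sum = float(np.nansum(np.abs(resid - np.nanmedian(resid))))
    if tol is None:
        tol = 1e-6 * init_sum if init_sum > 0 else 1e-12

    old_sum = float(np.nansum(np.abs(resid)))
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        rdelta = np.nanmedian(resid, axis=1)
        resid -= rdelta[:, None]
        row_eff += rdelta
        delta = float(np.median(col_eff))
        col_eff -= delta
        overall += delta

        cdelta = np.nanmedian(resid, axis=0)
        resid -= cdelta[None, :]
        col_eff += cdelta
        delta = float(np.median(row_eff))
        row_eff -= delta
        overall += delta

        new_sum = float(np.nansum(np.abs(resid)))
        if new_sum == 0.0 or abs(new_sum - old_sum) < tol:
            converged = True
            break
        old_sum = new_sum

    return MedianPolishResult(
        overall=overall,
        row_effects=row_eff,
        col_effects=col_eff,
        residuals=resid,
        iterations=iterations,
        converged=converged,
    )


def bscore_plate(
    plate: PlateGrid,
    exclude_controls: bool = True,
    max_iter: int = 100,
    tol: float | None = None,
    mad_epsilon: float | None = None,
) -> np.ndarray:
    """B-scores for one plate: polish residual over 1.4826 x median |residual|.

    With ``exclude_controls`` (default) control wells neither influence the
    row/column fit nor the MAD scale; their B-scores are still reported, as
    residuals against the fitted effects.  Missing wells come back as NaN.

    Raises :class:`DegeneratePlateError` when the sample-well residual MAD is
    zero, unless ``mad_epsilon`` provides a fallback scale.
    """
    fit_mask = plate.missing_mask.copy()
    if exclude_controls:
        fit_mask |= plate.control_mask

    mp = median_polish(plate.counts, mask=fit_mask, max_iter=max_iter, tol=tol)

    fitted = mp.overall + mp.row_effects[:, None] + mp.col_effects[None, :]
    residuals = np.where(plate.missing_mask, np.nan, plate.counts - fitted)

    sample_resid = residuals[~fit_mask]
    mad = float(np.median(np.abs(sample_resid)))
    if mad == 0.0:
        if mad_epsilon is None:
            raise DegeneratePlateError(
                f"degenerate plate {plate.plate_id!r}: median absolute residual is zero"
            )
        mad = mad_epsilon
    return residuals / (MAD_SCALE * mad)


def robust_z(values: np.ndarray, epsilon: float | None = None) -> np.ndarray:
    """Robust Z-scores: (x - median) / (1.4826 x MAD).

    Requires at least two finite values.  A zero MAD raises unless ``epsilon``
    supplies a fallback scale (with which an all-identical input maps to zeros).
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("robust_z needs at least 2 finite values")
    med = float(np.median(x[finite]))
    mad = float(np.median(np.abs(x[finite] - med)))
    if mad == 0.0:
        if epsilon is None:
            raise ValueError("MAD is zero; pass epsilon for a fallback scale")
        mad = epsilon
    out = np.full_like(x, np.nan)
    out[finite] = (x[finite] - med) / (MAD_SCALE * mad)
    return out


def replicate_concordance(bscores_rep1: np.ndarray, bscores_rep2: np.ndarray) -> float:
    """Squared Pearson correlation between two replicates' matched scores.

    Wells missing (non-finite) in either replicate are dropped pairwise; fewer
    than 3 surviving pairs is an error.
    """
    a = np.asarray(bscores_rep1, dtype=float).ravel()
    b = np.asarray(bscores_rep2, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("replicate vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    if keep.sum() < 3:
        raise ValueError("need at least 3 paired finite values")
    r = np.corrcoef(a[keep], b[keep])[0, 1]
    return float(r * r)


def wells_to_grid(wells: pd.DataFrame, plate_shape: tuple[int, int] = (16, 24)) -> PlateGrid:
    """Assemble one plate/replicate's well rows into a :class:`PlateGrid`."""
    n_rows, n_cols = plate_shape
    counts = np.full(plate_shape, np.nan)
    control = np.zeros(plate_shape, dtype=bool)
    missing = np.ones(plate_shape, dtype=bool)
    plate_ids = wells["plate"].unique()
    if len(plate_ids) != 1:
        raise ValueError(f"expected wells from one plate, got {plate_ids.tolist()}")
    for rec in wells.itertuples():
        r, c = int(rec.row), int(rec.col)
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise ValueError(f"well ({r}, {c}) outside plate shape {plate_shape}")
        counts[r, c] = rec.cell_count
        control[r, c] = rec.amplicon_id in CONTROL_TAGS
        missing[r, c] = not np.isfinite(rec.cell_count)
    return PlateGrid(str(plate_ids[0]), counts, control, missing)


def score_screen(
    wells: pd.DataFrame,
    plate_shape: tuple[int, int] = (16, 24),
    exclude_controls: bool = True,
    mad_epsilon: float | None = None,
) -> pd.DataFrame:
    """Add a ``bscore`` column to a well table, plate by plate per replicate."""
    out = wells.copy()
    out["bscore"] = np.nan
    for (_, _), group in wells.groupby(["plate", "replicate"], sort=False):
        grid = wells_to_grid(group, plate_shape)
        b = bscore_plate(grid, exclude_controls=exclude_controls, mad_epsilon=mad_epsilon)
        rows = group["row"].to_numpy(dtype=int)
        cols = group["col"].to_numpy(dtype=int)
        out.loc[group.index, "bscore"] = b[rows, cols]
    return out
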