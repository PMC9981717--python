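"""Cell-cycle profiling from per-nucleus DNA content.

Each well's integrated nuclear DNA intensities are binned into a histogram and
described by a three-component Gaussian population model: P1 (G1 cells, ~2C),
P2 (G2/M cells, ~4C, mean near twice the G1 mean) and P3 (hyperploid cells,
~8C).  The fitted component weights give the sub-population fractions, the
P1/P2 ratio summarizes G1-vs-G2 balance, and the quotient of that ratio across
two incubation temperatures quantifies temperature dependence of the profile
(1 means no dependence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .plates import robust_z


class TooFewNucleiError(ValueError):
    """Well has too few nuclei for a meaningful histogram; flag it, don't fit."""


@dataclass
class DNAContentHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(edges) == len(counts) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class CellCycleFit:
    """Fitted three-Gaussian model; fractions are the normalized component areas."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    p1: float
    p2: float
    p3: float
    p1_to_p2: float | None
    rss: float
    converged: bool


@dataclass
class TemperaturePairMetric:
    ratio_17: float
    ratio_27: float
    quotient: float


def build_histogram(
    intensities: np.ndarray,
    n_bins: int = 100,
    range_mode: str = "auto",
    fixed_range: tuple[float, float] | None = None,
    min_nuclei: int = 50,
) -> DNAContentHistogram:
    """Bin per-nucleus DNA intensities.

    ``auto`` range spans [0, 1.1 x the 99.9th percentile], clipping only the
    brightest debris; counts sum to the number of nuclei retained in range.
    Wells with fewer than ``min_nuclei`` nuclei raise
    :class:`TooFewNucleiError` so callers can flag them instead of fitting.
    """
    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_nuclei:
        raise TooFewNucleiError(f"only {x.size} nuclei (< {min_nuclei})")
    if range_mode == "auto":
        hi = float(np.quantile(x, 0.999)) * 1.1
        rng = (0.0, hi if hi > 0 else float(x.max()) + 1.0)
    elif range_mode == "fixed":
        if fixed_range is None:
            raise ValueError("fixed range_mode requires fixed_range")
        rng = fixed_range
    else:
        raise ValueError(f"unknown range_mode {range_mode!r}")
    counts, edges = np.histogram(x, bins=n_bins, range=rng)
    return DNAContentHistogram(edges, counts)


def _three_gauss(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    a1, a2, a3, mu1, r21, r32, s1, s2, s3 = p
    mu2 = mu1 * r21
    mu3 = mu2 * r32
    out = a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2)
    out += a2 * np.exp(-0.5 * ((x - mu2) / s2) ** 2)
    out += a3 * np.exp(-0.5 * ((x - mu3) / s3) ** 2)
    return out


def _mu1_candidates(hist: DNAContentHistogram) -> list[float]:
    """Candidate G1 means from the histogram's peaks.

    Every prominent peak is a candidate mu1, and so is half its position (a
    G2-arrested well's dominant peak is the 4C one, with only a minor 2C
    peak); the fit is started from each candidate and the lowest-RSS solution
    wins, which resolves the G1/G2 identifiability of peak assignment.
    """
    from scipy.signal import find_peaks

    x, c = hist.centers, hist.counts
    smooth = np.convolve(c, np.ones(3) / 3.0, mode="same")
    peaks, _ = find_peaks(smooth, prominence=0.05 * smooth.max())
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(smooth))])
    order = np.argsort(smooth[peaks])[::-1][:3]
    cands: list[float] = []
    for p in peaks[order]:
        for mu in (float(x[p]), float(x[p]) / 2.0):
            if mu <= 0:
                continue
            if all(abs(mu - m) > 0.1 * m for m in cands):
                cands.append(mu)
    return cands[:4]


def _init_for(hist: DNAContentHistogram, mu1: float) -> np.ndarray:
    """Seed from the DNA-doubling structure: mu2 = 2 mu1, mu3 = 4 mu1,
    sigmas at 15% of the means, amplitudes from the counts near each mean."""
    x, c = hist.centers, hist.counts
    amps = []
    for mu in (mu1, 2 * mu1, 4 * mu1):
        near = np.abs(x - mu) <= 0.3 * mu
        amps.append(float(c[near].max()) if near.any() else 1e-6)
    amps = [max(a, 1e-6) for a in amps]
    return np.array([*amps, mu1, 2.0, 2.0, 0.15 * mu1, 0.3 * mu1, 0.6 * mu1])


def fit_population_model(
    hist: DNAContentHistogram,
    init: np.ndarray | str = "auto",
    p2_floor: float = 1e-3,
) -> CellCycleFit:
    """Nonlinear least squares of a sum of three Gaussians to the bin counts.

    The component means are parameterized as mu1 and the ratios mu2/mu1 and
    mu3/mu2, softly bounded to the DNA-doubling windows [1.6, 2.4] and
    [1.6, 2.6], which keeps the components identifiable as G1 / G2 / hyperploid
    and enforces the mean ordering by construction.  Fractions come from the
    fitted component areas (amplitude x sigma), not bin mass.

    Fractions are the components' share of model mass over the histogram's
    support (a component pushed outside the data range contributes nothing),
    which keeps them interpretable as fractions of the observed nuclei.

    A fit that does not converge returns ``converged=False`` with best-effort
    parameters.  When P2 falls below ``p2_floor``, the minor G2 peak was not
    recognized and the P1/P2 ratio is left undefined (None).
    """
    if int(np.count_nonzero(hist.counts)) < 3:
        raise ValueError("histogram needs at least 3 nonzero bins")
    x, c = hist.centers, hist.counts
    span = hist.bin_edges[-1] - hist.bin_edges[0]
    lower = np.array([0, 0, 0, hist.bin_edges[0] + 1e-9, 1.6, 1.6, 1e-6 * span, 1e-6 * span, 1e-6 * span])
    upper = np.array([np.inf, np.inf, np.inf, hist.bin_edges[-1], 2.4, 2.6, span, span, span])

    if isinstance(init, str):
        inits = [_init_for(hist, mu1) for mu1 in _mu1_candidates(hist)]
    else:
        inits = [np.asarray(init, dtype=float)]

    res = None
    for p0 in inits:
        p0 = np.clip(p0, lower + 1e-12, upper - 1e-12)
        trial = least_squares(
            lambda p: _three_gauss(x, p) - c,
            p0,
            bounds=(lower, upper),
            max_nfev=2000,
        )
        # Candidates are ordered dominant-peak-first; a later start (e.g. the
        # half-position of the dominant peak) must clearly improve the fit to
        # displace it, so ties do not relabel G1 mass as G2.
        if res is None or trial.cost < 0.99 * res.cost:
            res = trial
    a1, a2, a3, mu1, r21, r32, s1, s2, s3 = res.x
    means = np.array([mu1, mu1 * r21, mu1 * r21 * r32])
    sds = np.array([s1, s2, s3])
    mass = np.array(
        [
            float(np.sum(a * np.exp(-0.5 * ((x - m) / s) ** 2)))
            for a, m, s in zip((a1, a2, a3), means, sds)
        ]
    )
    total = mass.sum()
    weights = mass / total if total > 0 else np.array([np.nan] * 3)
    p1, p2, p3 = (float(w) for w in weights)
    ratio = p1 / p2 if (np.isfinite(p2) and p2 > p2_floor) else None
    return CellCycleFit(
        means=means,
        sds=sds,
        weights=weights,
        p1=p1,
        p2=p2,
        p3=p3,
        p1_to_p2=ratio,
        rss=float(2.0 * res.cost),
        converged=bool(res.success),
    )


def fit_intensities(intensities: np.ndarray, n_bins: int = 100, **kwargs) -> CellCycleFit:
    """Convenience: histogram then fit, with the default auto range."""
    return fit_population_model(build_histogram(intensities, n_bins=n_bins), **kwargs)


def temperature_quotient(fit17: CellCycleFit, fit27: CellCycleFit) -> TemperaturePairMetric:
    """Quotient of the G1/G2 ratio at the low over the high temperature.

    Identical profiles give 1; values above 1 mean relatively more G1 cells at
    the low temperature.  Undefined when either fit failed to converge or its
    P1/P2 ratio is undefined.
    """
    for name, fit in (("17", fit17), ("27", fit27)):
        if not fit.converged:
            raise ValueError(f"fit at {name} deg C did not converge")
        if fit.p1_to_p2 is None:
            raise ValueError(f"P1/P2 undefined at {name} deg C (P2 below floor)")
    return TemperaturePairMetric(
        ratio_17=fit17.p1_to_p2,
        ratio_27=fit27.p1_to_p2,
        quotient=fit17.p1_to_p2 / fit27.p1_to_p2,
    )


def cellcycle_scores(
    fits: pd.DataFrame,
    params: tuple[str, ...] = ("p1", "p2", "p3", "p1_to_p2"),
    group_col: str = "replicate",
    min_wells: int = 10,
    epsilon: float | None = None,
) -> pd.DataFrame:
    """Robust Z-scores of the fitted cell-cycle parameters, per grouping unit.

    ``fits`` is a per-well table with one column per parameter plus
    ``group_col`` (by default the replicate: fractions, unlike counts, are not
    expected to show strong plate gradients, so standardization is across all
    plates of a replicate).  Returns the input keyed by well with added
    ``z_<param>`` columns.
    """
    out = fits.copy()
    for p in params:
        out[f"z_{p}"] = np.nan
    for _, group in fits.groupby(group_col, sort=False):
        if len(group) < min_wells:
            raise ValueError(f"grouping unit has {len(group)} wells (< {min_wells})")
        for p in params:
            vals = group[p].to_numpy(dtype=float)
            out.loc[group.index, f"z_{p}"] = robust_z(vals, epsilon=epsilon)
    return out
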