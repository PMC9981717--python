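"""Synthetic inputs for every pipeline stage.

Three generators emulate the data a temperature-differential RNAi screen
produces, so the whole analysis chain is testable offline:

* :func:`simulate_screen` — 384-well plates of cell counts with additive
  row/column plate biases, negative (no dsRNA) and positive (lethal-knockdown)
  controls, and planted temperature-dependent gene effects, over two
  replicates each at 17 C and 27 C.
* :func:`simulate_dna_contents` — per-well nucleus DNA intensities from a
  three-Gaussian mixture (G1 ~ 2C, G2/M ~ 4C, hyperploid ~ 8C).
* :func:`simulate_timelapse` — two-channel (lamina, chromatin) 3-D time-lapse
  stacks of syncytial-blastoderm-like nuclei entering mitosis, with chromatin
  condensing either at the nuclear periphery (low-temperature phenotype) or
  internally, ending in a metaphase plate on the final frame.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Mixture weights (P1, P2, P3) by planted cell-cycle phenotype.
CC_WEIGHTS = {
    "null": (0.60, 0.35, 0.05),
    "g1_arrest": (0.85, 0.10, 0.05),
    "g2_arrest": (0.10, 0.85, 0.05),
    "hyperploid": (0.45, 0.30, 0.25),
}

REPLICATE_LABELS = ("17_repl1", "17_repl2", "27_repl1", "27_repl2")


def _default_control_layout() -> dict[tuple[int, int], str]:
    """10 negative + 4 positive control wells in column 0 of every plate,
    approximating the real screen's control density (~14 of 384 wells)."""
    layout = {(r, 0): "negative" for r in range(10)}
    layout.update({(r, 0): "positive" for r in range(12, 16)})
    return layout


@dataclass
class MixtureSimConfig:
    """Three-Gaussian DNA-content mixture; means follow the 2C/4C/8C doubling."""

    n_nuclei: int = 1000
    means: tuple[float, float, float] = (1.0, 2.0, 4.0)
    sds: tuple[float, float, float] = (0.10, 0.20, 0.40)
    weights: tuple[float, float, float] = (0.60, 0.35, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if np.any(np.asarray(self.sds) <= 0):
            raise ValueError("sds must be positive")
        m = np.asarray(self.means)
        if not (m[0] < m[1] < m[2]):
            raise ValueError("means must be strictly increasing")


@dataclass
class ScreenSimConfig:
    """Design of the simulated screen.

    The defaults mirror the screened format: 384-well plates, two replicates
    per temperature at 17 C and 27 C, additive row/column biases (what a
    median polish removes), multiplicative planted gene effects, and
    count noise with a fixed coefficient of variation.
    """

    n_plates: int = 4
    plate_shape: tuple[int, int] = (16, 24)
    n_replicates_per_temp: int = 2
    temperatures: tuple[str, str] = ("17C", "27C")
    baseline_count: float = 2000.0
    row_bias_sd: float = 60.0
    col_bias_sd: float = 60.0
    noise_cv: float = 0.08
    frac_17_specific: float = 0.0
    frac_27_specific: float = 0.0
    frac_both: float = 0.0
    frac_enhancer: float = 0.0
    effect_size: float = 0.4
    positive_control_effect: float = 0.1
    cellcycle_effects: tuple[tuple[str, str, float], ...] = ()
    control_layout: dict[tuple[int, int], str] = field(default_factory=_default_control_layout)
    multiplicative_bias: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_17_specific
            + self.frac_27_specific
            + self.frac_both
            + self.frac_enhancer
            + sum(f for _, _, f in self.cellcycle_effects)
        )
        if fracs > 1.0 + 1e-9:
            raise ValueError("planted effect-class proportions sum to > 1")
        for kind, scope, _ in self.cellcycle_effects:
            if kind not in ("g1_arrest", "g2_arrest", "hyperploid"):
                raise ValueError(f"unknown cell-cycle effect kind {kind!r}")
            if scope not in ("17", "27", "both"):
                raise ValueError(f"unknown cell-cycle effect scope {scope!r}")


@dataclass
class ScreenSimResult:
    wells: pd.DataFrame
    truth: pd.DataFrame
    dna: dict[tuple[str, str, int, int], np.ndarray]


def simulate_dna_contents(cfg: MixtureSimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw per-nucleus integrated DNA intensities from the 3-Gaussian mixture."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    comp = rng.choice(3, size=cfg.n_nuclei, p=np.asarray(cfg.weights, dtype=float))
    means = np.asarray(cfg.means)[comp]
    sds = np.asarray(cfg.sds)[comp]
    return rng.normal(means, sds)


def _assign_classes(n: int, cfg: ScreenSimConfig, rng: np.random.Generator):
    """Deterministically partition amplicons into planted effect classes.

    Exactly floor(frac * n) amplicons per class, chosen from a seeded
    permutation; count classes and cell-cycle classes are assigned from
    disjoint stretches of the same permutation.
    """
    order = rng.permutation(n)
    count_class = np.array(["null"] * n, dtype=object)
    cc_class = np.array(["null"] * n, dtype=object)
    cc_scope = np.array([""] * n, dtype=object)
    pos = 0
    for name, frac in (
        ("17_specific", cfg.frac_17_specific),
        ("27_specific", cfg.frac_27_specific),
        ("both", cfg.frac_both),
        ("enhancer", cfg.frac_enhancer),
    ):
        k = int(np.floor(frac * n))
        count_class[order[pos : pos + k]] = name
        pos += k
    for kind, scope, frac in cfg.cellcycle_effects:
        k = int(np.floor(frac * n))
        cc_class[order[pos : pos + k]] = kind
        cc_scope[order[pos : pos + k]] = scope
        pos += k
    return count_class, cc_class, cc_scope


def _count_effect(count_class: str, temp: str, cfg: ScreenSimConfig) -> float:
    e = cfg.effect_size
    if count_class == "17_specific":
        return e if temp == "17C" else 1.0
    if count_class == "27_specific":
        return e if temp == "27C" else 1.0
    if count_class == "both":
        return e
    if count_class == "enhancer":
        return 1.0 / e
    return 1.0


def _mixture_for(cc_class: str, cc_scope: str, temp: str) -> tuple[float, float, float]:
    active = cc_class != "null" and (cc_scope == "both" or temp.startswith(cc_scope))
    return CC_WEIGHTS[cc_class] if active else CC_WEIGHTS["null"]


def simulate_screen(
    cfg: ScreenSimConfig,
    with_dna: bool = False,
    nuclei_per_well: int = 300,
    mixture: MixtureSimConfig | None = None,
) -> ScreenSimResult:
    """Simulate the whole screen: well table plus ground-truth effect table.

    Each well's count is baseline x gene effect (temperature-dependent per
    planted class) plus additive row/column plate biases plus Gaussian noise
    with coefficient of variation ``noise_cv``.  Negative controls behave like
    nulls; positive controls are strongly reduced at both temperatures.  With
    ``with_dna`` every well also receives per-nucleus DNA intensities drawn
    from the three-Gaussian mixture, reweighted for planted cell-cycle
    classes.
    """
    rng = np.random.default_rng(cfg.seed)
    n_rows, n_cols = cfg.plate_shape
    layout = cfg.control_layout
    sample_wells = [
        (r, c) for r in range(n_rows) for c in range(n_cols) if (r, c) not in layout
    ]
    n_amp_per_plate = len(sample_wells)
    n_amp = cfg.n_plates * n_amp_per_plate

    count_class, cc_class, cc_scope = _assign_classes(n_amp, cfg, rng)
    amp_ids = np.array(
        [f"amp_{i // n_amp_per_plate:02d}_{i % n_amp_per_plate:03d}" for i in range(n_amp)]
    )
    genes = np.array([aid.replace("amp_", "gene_") for aid in amp_ids])
    truth = pd.DataFrame(
        {
            "amplicon_id": amp_ids,
            "gene": genes,
            "count_class": count_class,
            "cellcycle_class": cc_class,
            "cellcycle_scope": cc_scope,
        }
    )

    base_mix = mixture or MixtureSimConfig(n_nuclei=nuclei_per_well)
    replicates = [
        f"{t.rstrip('C')}_repl{i + 1}"
        for t in cfg.temperatures
        for i in range(cfg.n_replicates_per_temp)
    ]
    temps = {rep: f"{rep.split('_')[0]}C" for rep in replicates}

    rows_out: list[dict] = []
    dna: dict[tuple[str, str, int, int], np.ndarray] = {}
    for rep in replicates:
        temp = temps[rep]
        for p in range(cfg.n_plates):
            plate_id = f"plate_{p:02d}"
            row_bias = rng.normal(0.0, cfg.row_bias_sd, size=n_rows)
            col_bias = rng.normal(0.0, cfg.col_bias_sd, size=n_cols)
            for i, (r, c) in enumerate(sample_wells):
                idx = p * n_amp_per_plate + i
                eff = _count_effect(count_class[idx], temp, cfg)
                mean = cfg.baseline_count * eff
                count = _noisy_count(mean, row_bias[r], col_bias[c], cfg, rng)
                rows_out.append(
                    {
                        "plate": plate_id,
                        "row": r,
                        "col": c,
                        "replicate": rep,
                        "temperature": temp,
                        "amplicon_id": amp_ids[idx],
                        "gene": genes[idx],
                        "cell_count": count,
                    }
                )
                if with_dna:
                    w = _mixture_for(cc_class[idx], cc_scope[idx], temp)
                    mix = MixtureSimConfig(
                        n_nuclei=nuclei_per_well,
                        means=base_mix.means,
                        sds=base_mix.sds,
                        weights=w,
                        seed=0,
                    )
                    dna[(rep, plate_id, r, c)] = simulate_dna_contents(mix, rng=rng)
            for (r, c), tag in layout.items():
                eff = cfg.positive_control_effect if tag == "positive" else 1.0
                mean = cfg.baseline_count * eff
                count = _noisy_count(mean, row_bias[r], col_bias[c], cfg, rng)
                rows_out.append(
                    {
                        "plate": plate_id,
                        "row": r,
                        "col": c,
                        "replicate": rep,
                        "temperature": temp,
                        "amplicon_id": tag,
                        "gene": None,
                        "cell_count": count,
                    }
                )
                if with_dna:
                    mix = MixtureSimConfig(
                        n_nuclei=nuclei_per_well,
                        means=base_mix.means,
                        sds=base_mix.sds,
                        weights=CC_WEIGHTS["null"],
                        seed=0,
                    )
                    dna[(rep, plate_id, r, c)] = simulate_dna_contents(mix, rng=rng)

    wells = pd.DataFrame(rows_out)
    return ScreenSimResult(wells=wells, truth=truth, dna=dna)


def _noisy_count(
    mean: float, row_bias: float, col_bias: float, cfg: ScreenSimConfig, rng: np.random.Generator
) -> float:
    if cfg.multiplicative_bias:
        value = mean * (1.0 + row_bias / cfg.baseline_count) * (1.0 + col_bias / cfg.baseline_count)
    else:
        value = mean + row_bias + col_bias
    value += rng.normal(0.0, cfg.noise_cv * mean)
    return float(max(value, 0.0))


# ---------------------------------------------------------------------------
# Time-lapse stacks


@dataclass
class TimelapseSimConfig:
    """Two-channel nucleus time-lapse.

    ``n_timepoints`` counts 8 pre-metaphase frames plus one final
    metaphase-plate frame (known by construction to be the last frame).
    ``mode`` selects the condensation phenotype: ``peripheral`` places the
    condensation foci adjacent to the lamina shell (the low-temperature,
    delayed-release phenotype), ``internal`` contracts chromatin towards the
    centroid.  ``frame_interval_s`` is pure metadata (110/65/20/25/25 s for
    imaging at 11/14/18/25/29 C).
    """

    image_shape: tuple[int, int, int] = (36, 224, 224)
    nucleus_radius: float = 16.0
    n_nuclei: int = 6
    n_timepoints: int = 9
    mode: str = "peripheral"
    focus_count: int = 7
    lamina_ring_width: float = 2.0
    snr: float = 10.0
    gain: float = 1.0
    frame_interval_s: float = 25.0
    doubled_rate: bool = False
    margin: float = 6.0
    max_placement_tries: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("peripheral", "internal"):
            raise ValueError("mode must be 'peripheral' or 'internal'")
        nz, ny, nx = self.image_shape
        need = 2 * self.nucleus_radius + 2 * self.margin
        if min(ny, nx) < need or nz < 2 * self.nucleus_radius + 2:
            raise ValueError("nucleus does not fit inside the image with margin")


@dataclass
class TimelapseSimResult:
    stack: np.ndarray  # (T, Z, Y, X, 2) float32; channel 0 lamina, 1 chromatin
    truth: pd.DataFrame  # nucleus_id, z, y, x, radius, mode
    metaphase_timepoint: int
    config: TimelapseSimConfig


def _place_nuclei(cfg: TimelapseSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Random non-overlapping XY placement on the mid-z monolayer."""
    nz, ny, nx = cfg.image_shape
    lo = cfg.nucleus_radius + cfg.margin
    min_sep = 2 * cfg.nucleus_radius + 10.0
    centers: list[tuple[float, float, float]] = []
    tries = 0
    zc = float(nz // 2)  # integer slice so the equatorial plane is exact
    while len(centers) < cfg.n_nuclei:
        tries += 1
        if tries > cfg.max_placement_tries:
            raise RuntimeError(
                f"could not place {cfg.n_nuclei} non-overlapping nuclei "
                f"in {ny}x{nx} within {cfg.max_placement_tries} tries"
            )
        y = rng.uniform(lo, ny - 1 - lo)
        x = rng.uniform(lo, nx - 1 - lo)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_sep**2 for _, cy, cx in centers):
            centers.append((zc, y, x))
    return np.asarray(centers)


def _paint_nucleus(
    lam: np.ndarray,
    chrom: np.ndarray,
    center: np.ndarray,
    cfg: TimelapseSimConfig,
    t: int,
    foci_angles: np.ndarray,
    foci_radii: np.ndarray,
) -> None:
    r = cfg.nucleus_radius
    w = cfg.lamina_ring_width
    zc, yc, xc = center
    pad = int(np.ceil(r + w + 3))
    z0, z1 = max(int(zc) - pad, 0), min(int(zc) + pad + 1, lam.shape[0])
    y0, y1 = max(int(yc) - pad, 0), min(int(yc) + pad + 1, lam.shape[1])
    x0, x1 = max(int(xc) - pad, 0), min(int(xc) + pad + 1, lam.shape[2])
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    dist = np.sqrt((zz - zc) ** 2 + (yy - yc) ** 2 + (xx - xc) ** 2)

    # Lamina: a bright spherical shell, persistent through all frames.
    lam[z0:z1, y0:y1, x0:x1] += np.exp(-0.5 * ((dist - r) / (w / 2.0)) ** 2).astype(np.float32)

    # Chromatin fills the nucleus up to the inner edge of the lamina shell, so
    # the detected interior (which ends just inside the shell) is fully covered.
    interior = dist < (r - w / 2.0)
    n_pre = cfg.n_timepoints - 1
    if t >= n_pre:  # final frame: central metaphase plate
        plate = interior & (np.abs(xx - xc) < 2.0) & (dist < 0.7 * r)
        sig = 0.15 * interior + 3.0 * plate
        chrom[z0:z1, y0:y1, x0:x1] += sig.astype(np.float32)
        return

    progress = t / max(n_pre - 1, 1)
    base = (1.0 - 0.9 * progress) * interior
    foci = np.zeros_like(dist)
    sigma = 1.5
    r_interior = r - w / 2.0
    for ang, frad in zip(foci_angles, foci_radii):
        if cfg.mode == "peripheral":
            rho = r - 2.0  # focus core sits in the outermost 2-px segment
        else:
            rho = frad * (1.0 - 0.7 * progress)  # contracting towards the centroid
        fy = yc + rho * np.sin(ang)
        fx = xc + rho * np.cos(ang)
        fz = zc
        if cfg.mode == "peripheral":
            # Arc-like condensation foci hugging the periphery: tight radially,
            # elongated tangentially and in z (the attachment is a surface patch).
            d_rad = (yy - fy) * np.sin(ang) + (xx - fx) * np.cos(ang)
            d_tan = (yy - fy) * np.cos(ang) - (xx - fx) * np.sin(ang)
            d2 = ((zz - fz) / 2.0) ** 2 + (d_rad / 1.0) ** 2 + (d_tan / 3.0) ** 2
            foci += np.exp(-0.5 * d2)
        else:
            d2 = ((zz - fz) / 2.0) ** 2 + (yy - fy) ** 2 + (xx - fx) ** 2
            foci += np.exp(-0.5 * d2 / sigma**2)
    chrom[z0:z1, y0:y1, x0:x1] += (base + 3.0 * progress * foci * interior).astype(np.float32)


def simulate_timelapse(cfg: TimelapseSimConfig) -> TimelapseSimResult:
    """Generate the two-channel stack series and its ground-truth table.

    Channel 0 (lamina) is a bright shell at each nucleus boundary in every
    frame.  Channel 1 (chromatin) starts uniform inside the nucleus and over
    the pre-metaphase frames concentrates into ``focus_count`` foci — adjacent
    to the shell in ``peripheral`` mode, contracting to the centroid in
    ``internal`` mode — and shows a central plate on the final frame.  Noise
    is Poisson-like (variance proportional to ``gain`` x signal) plus Gaussian
    read noise, both scaled by 1/snr; ``snr = inf`` disables noise entirely.
    """
    rng = np.random.default_rng(cfg.seed)
    centers = _place_nuclei(cfg, rng)
    nz, ny, nx = cfg.image_shape
    T = cfg.n_timepoints
    stack = np.zeros((T, nz, ny, nx, 2), dtype=np.float32)

    foci = []
    for _ in range(cfg.n_nuclei):
        angles = rng.uniform(0, 2 * np.pi, size=cfg.focus_count)
        radii = rng.uniform(0.0, cfg.nucleus_radius / 4.0, size=cfg.focus_count)
        foci.append((angles, radii))

    for t in range(T):
        lam = stack[t, ..., 0]
        chrom = stack[t, ..., 1]
        for i, center in enumerate(centers):
            _paint_nucleus(lam, chrom, center, cfg, t, *foci[i])
        if np.isfinite(cfg.snr):
            for ch in (lam, chrom):
                sd = np.sqrt(cfg.gain * np.clip(ch, 0, None) + 1.0) / cfg.snr
                ch += rng.normal(0.0, 1.0, size=ch.shape).astype(np.float32) * sd.astype(np.float32)

    truth = pd.DataFrame(
        {
            "nucleus_id": np.arange(cfg.n_nuclei),
            "z": centers[:, 0],
            "y": centers[:, 1],
            "x": centers[:, 2],
            "radius": cfg.nucleus_radius,
            "mode": cfg.mode,
        }
    )
    return TimelapseSimResult(
        stack=stack, truth=truth, metaphase_timepoint=T - 1, config=cfg
    )


def simulate_clone_areas(
    mean_ratio: float,
    sd_ratio: float,
    n_discs: int,
    mean_area_plus: float = 20000.0,
    cv_area: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-disc twin-spot clone areas whose +/+ over -/- ratio is ~N(mean, sd).

    Emulates the wing-disc clone measurements: the marker-homozygous clone
    area is lognormal around ``mean_area_plus`` (px^2) and the mutant clone
    area is derived from the drawn ratio.
    """
    rng = np.random.default_rng(seed)
    ratios = rng.normal(mean_ratio, sd_ratio, size=n_discs)
    ratios = np.clip(ratios, 0.05, None)
    area_plus = rng.lognormal(np.log(mean_area_plus), cv_area, size=n_discs)
    return pd.DataFrame(
        {
            "disc_id": [f"disc_{i:03d}" for i in range(n_discs)],
            "area_plus": area_plus,
            "area_minus": area_plus / ratios,
        }
    )
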