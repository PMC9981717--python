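# Methods

This note documents the models and procedures implemented in `thermoscreen`,
the assumptions behind them, the defaults that matter, and what the synthetic
data generators do and do not emulate.

## Plate normalization (B-scores)

Each 384-well plate (16 × 24) of cell counts is decomposed by Tukey's two-way
median polish into `count = overall + row_effect + col_effect + residual`.
The polish alternates row and column median sweeps, starting with rows, with
median ties resolved by the midpoint convention; it stops when the change in
the sum of absolute residuals falls below `tol` (default 10⁻⁶ × the initial
sum of absolute residuals about the overall median — this reference is
shift-invariant and scale-equivariant, which makes B-scores exactly invariant
under positive affine transforms of a plate) or after `max_iter = 100`
iterations. The B-score of a well is its residual divided by
1.4826 × median |residual| of the plate's sample wells.

Control wells are excluded from both the polish fit and the MAD scale by
default (`exclude_controls=True`): controls occupy fixed wells, and letting
them into the fit would bias the row/column effects of their rows and
columns. Their B-scores are still reported, computed as residuals against
the fitted effects. Missing wells (imaging failures) are carried as a mask
and never imputed; a plate whose residual MAD is zero raises
`DegeneratePlateError` (a degenerate plate indicates upstream failure) unless
an epsilon fallback is configured.

A caveat worth knowing: median polish compresses the central residuals, so
the scaled MAD underestimates the residual standard deviation by ~15 % at
this plate size. B-scores are therefore slightly heavy-tailed relative to
N(0, 1) — on pure-noise plates ~8 % of wells have |B| > 2 rather than the
Gaussian 4.6 % (the same behaviour is reproduced by R's `stats::medpolish`).
Threshold-based hit lists inherit this; the ±2 cut-offs are conventions, not
calibrated false-positive rates.

Robust Z-scores, `(x − median) / (1.4826 × MAD)`, standardize the cell-cycle
parameters. They are computed per replicate across all plates (configurable):
unlike counts, cell-cycle fractions are not expected to show strong plate
gradients, and per-replicate grouping gives the MAD a stable sample size.

## Cell-cycle population model

Per-nucleus integrated DNA intensities of a well are binned into a histogram
(default 100 bins; auto range [0, 1.1 × 99.9th percentile]; wells with fewer
than 50 nuclei are flagged and not fitted). A sum of three Gaussians is fitted
to the bin counts by nonlinear least squares (`scipy.optimize.least_squares`),
matching a procedure that fits the histogram rather than running EM on raw
intensities.

Identifiability comes from the DNA-doubling structure: the component means
are parameterized as μ₁ and the ratios μ₂/μ₁ ∈ [1.6, 2.4] and
μ₃/μ₂ ∈ [1.6, 2.6] (the hyperploid mean is free within its window, since
hyperploid populations may sit at 8C or form a broad tail). Ordering of the
means holds by construction. Starts are generated from every prominent
histogram peak and from half of each peak position (a G2-arrested well's
dominant peak is the 4C one); the lowest-RSS solution wins, with a later
start needing a ≥ 1 % RSS improvement to displace an earlier one so that
near-ties do not relabel G1 mass as G2. Sub-population fractions P1/P2/P3 are
each component's share of the model mass over the histogram support — a
component pushed outside the data range contributes nothing — so
P1 + P2 + P3 = 1 exactly. When P2 falls below 10⁻³ the G2 peak was not
recognized and the P1/P2 ratio is reported undefined rather than exploding.

The temperature metric for a perturbation is the quotient
(P1/P2 at 17 °C) / (P1/P2 at 27 °C); identical profiles give 1, values far
from 1 indicate a temperature-dependent cell-cycle effect.

## Hit calling

Same-temperature replicate B-scores are averaged per dsRNA amplicon
(`b17`, `b27`); an amplicon missing one temperature entirely is flagged
unscoreable, and a duplicate within a replicate is an error. List rules, all
boundaries inclusive, with `low = −2`, `high = +2`:

| list | rule |
|---|---|
| `l_both_weak` | b17 ≤ low ∧ b27 ≤ low |
| `l17weak` | b17 ≤ low ∧ b27 > slight_floor (default −2) |
| `l27weak` | b27 ≤ low ∧ b17 > low |
| `l17weak_a` | b17 ≤ low ∧ b27 ≤ low ∧ (b27 − b17) ≥ delta (default 2) |
| `l17strong` / `l27strong` / `l_both_strong` | mirrored with ≥ high |

`slight_floor` and `delta` are configuration, not constants: the source
rules for "at most slightly reduced" and "far more extensively" are
qualitative, so the defaults encode the plain ±2 reading and can be
overridden. Cell-cycle lists (`l17caP1` … `l27caP1toP2`) flag amplicons with
|robust Z| > 3 for P1, P2, P3 or P1/P2 at one temperature but not the other.
Gene lists are the union over a gene's amplicons (`min_amplicons=1`,
configurable to require more).

## Condensation imaging

The pipeline quantifies where chromatin condenses at mitotic entry relative
to the nuclear envelope, on two-channel (lamina, chromatin) 3-D time-lapse
stacks of syncytial-blastoderm nuclei:

1. **Detection** per frame on the chromatin channel: Gaussian smoothing
   (σ = 4 px), Otsu threshold, connected components, size filter; candidates
   within `border_margin` (10 px) of a lateral image edge or closer than
   `min_separation` (30 px) to another candidate are excluded.
2. **Tracking** by greedy nearest-centroid linking, links made globally in
   order of increasing distance (order-independent); links beyond
   `max_displacement` (10 px) start new tracks, and tracks not spanning the
   full analysis window are dropped.
3. **Equatorial section** from the lamina channel: per z-slice the
   thresholded lamina ring is hole-filled and the enclosed area measured; the
   z maximizing the enclosed area is the equator (ties resolve to the most
   central z). The periphery is the largest closed contour; the interior
   excludes the ring. Nuclei without a closed contour, or with the shell at
   noise level, are excluded at that timepoint.
4. **Ring segments**: Euclidean distance transform of the interior; segment k
   (k = 1…5) covers depths (2(k−1), 2k] px inward from the contour and
   segment 6 absorbs everything deeper than 10 px, so the central mass is
   always counted (an `equal_depth` mode with six equal shells is available).
   Segments tile the interior exactly.
5. **HIP fractions**: the threshold is the 70th percentile of intranuclear
   chromatin intensities, per nucleus per timepoint, so ~30 % of interior
   pixels are high-intensity pixels; the HIP fraction per segment is the
   segment's share of all HIPs. Heavy ties that push the realized HIP count
   more than 20 % off target are flagged.
6. **Statistic**: per nucleus, the maximum segment-1 HIP fraction over the 8
   timepoints before metaphase-plate formation (16 under the doubled
   acquisition-rate flag used for 18 °C imaging). The metaphase timepoint is
   an input (ground truth in synthetic data; manual annotation in real data).
7. **Group comparison**: per-embryo means are the unit of analysis; groups
   are compared with a two-sided Student's t-test (Welch switchable).

Peripheral condensation — delayed release of chromosomes from the nuclear
envelope, the low-temperature phenotype — appears as a segment-1 statistic
far above the segment's area share (~0.24 for the synthetic geometry);
prompt internal condensation leaves it at the area share, because the
uniform-chromatin interphase frames inside the window set the floor.

Analysis is strictly 2-D on the equatorial section, as in the source
procedure; no 3-D shell analysis is attempted.

## Validation statistics

Count-ratio validation normalizes replicate counts to the same-temperature
negative-control mean, averages, and propagates the standard deviation of
r = m27/m17 to first order: `sd(r) = r·sqrt((s27/m27)² + (s17/m17)²)`.
Replicate s.d. uses the sample convention (ddof = 1), contributing zero when
only one replicate exists. Ratios above 1.1 are shaded light, above 1.5
dark. Twin-spot clone records start from per-disc area tables (the clone
delineation itself is manual, hence not re-implemented); per-group mean ±
s.d. of the per-disc (+/+)/(−/−) area ratio and pairwise t-tests on ratios
and raw areas are reported.

## Synthetic data

The generators produce inputs with the statistical structure the analyses
assume, at the study's design sizes.

**Screen**: 16 × 24 plates with 10 negative and 4 positive control wells in
a fixed column (≈14/384, matching the real screen's control density); two
replicates per temperature (17 °C, 27 °C); baseline 2000 cells/well; additive
row/column biases (s.d. 60 cells) — additive because that is what median
polish removes, with a multiplicative-bias option to test robustness — and
Gaussian count noise with CV 0.08. Planted classes are multiplicative count
effects (default 0.4 at the affected temperature, 1/0.4 for enhancers);
positive controls are reduced to 0.1 × baseline at both temperatures. Exactly
⌊fraction × n⌋ amplicons per class are drawn from a seeded permutation, so
ground truth proportions are recoverable exactly. Per-well DNA intensities
(generated on demand, `with_dna=True`) come from the three-Gaussian mixture
with weights (0.60, 0.35, 0.05), means (1, 2, 4) and s.d. 10 % of the mean,
reweighted for planted G1-arrest, G2-arrest or hyperploid wells.

**Time-lapse**: isotropic spherical nuclei (radius 16 px, z-spacing 1 unit)
in a mid-z monolayer, placed with ≥ 10 px gaps between shells; 8
pre-metaphase frames plus a final metaphase-plate frame, which is always the
last frame so the ground-truth metaphase timepoint is known by construction.
The lamina channel is a persistent Gaussian shell (width 2 px). The
chromatin channel starts uniform and, over the pre-metaphase frames, shifts
into condensation foci: in `peripheral` mode, arc-like patches hugging the
shell (tight radially, elongated tangentially and in z, cores ~1 px below
the detected interior boundary); in `internal` mode, isotropic foci
contracting towards the centroid. Noise is Poisson-like (variance
`gain × signal`) plus Gaussian read noise, both scaled by 1/snr (default
snr = 10); `snr = inf` disables noise entirely. Frame intervals
(110/65/20/25/25 s for 11/14/18/25/29 °C) are metadata only, except that the
doubled 18 °C rate doubles the analysis window to 16 frames.

What the generators do **not** emulate: optical blur and anisotropic PSFs,
photobleaching, nucleus movement and deformation, mitotic-wave asynchrony,
segmentation-hostile clutter, and amplicon-level off-target structure.
Passing tests therefore demonstrate that the statistics and algorithms are
implemented correctly and discriminate the planted phenotypes under
realistic noise — not that the segmentation would survive arbitrary real
microscopy. Conversely the analysis thresholds (Otsu, size and distance
filters) are generic, not tuned to the synthetic geometry beyond the
smoothing scale matching the nucleus radius.

## Problem sizes and numerical choices

Simulation-driven checks use 4-plate screens (1480 amplicons), mixture fits
at n = 2000–5000 nuclei over 50 seeds, and 6 + 6 embryos with 11 nuclei each
at 36 × 288 × 288 voxels — sizes chosen to estimate each quantity stably
while keeping a full run around a minute. HIP thresholds use strict
inequality; quantiles are empirical; equatorial-z ties resolve to the most
central slice; all randomness flows from explicit integer seeds
(`numpy.random.default_rng`), and fixed seeds reproduce tables and stacks
bit-for-bit.

## Known limitations

* The supplementary-spreadsheet reader's column dialect is a documented
  guess pending the real file; it fails loudly on unmapped columns.
* B-score tails are heavier than Gaussian (see above); list sizes at ±2 are
  therefore larger than a 4.6 % tail would suggest.
* The automatic metaphase detector is not implemented; the metaphase
  timepoint is an input.
* Greedy nearest-neighbour tracking is adequate for slowly-moving syncytial
  nuclei but is not a general-purpose tracker.
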