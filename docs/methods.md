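# Methods

## The measurement chain

A microwell array traps at most one red blood cell per well; a nitrogen
channel behind a thin PDMS wall washes oxygen out of each well, and an
O₂-quenched fluorescent probe (RTDP) in the suspending buffer reports the
local oxygen level. The analysis chain is

1. **Quantification** — per-well mean intensity over a circular ROI in
   every frame (`oxywell.imaging`);
2. **Conversion** — intensity to PO₂ through the inverted first-order
   Stern–Volmer relation (`oxywell.quench`);
3. **Decay fit** — nonlinear least squares of `PO₂(t) = A·e^(−Kt)` per
   well, and `D50 = ln(2)/K` (`oxywell.decay`);
4. **Population analytics** — cohort shape statistics, kernel densities
   and the group-comparison battery (`oxywell.popstats`);
5. **Orchestration** — seeded, hash-stamped end-to-end runs
   (`oxywell.pipeline`, `oxywell.cli`).

A synthetic-data generator (`oxywell.sim`) produces physically grounded
inputs for all of the above and is first-class, tested code: it is how the
pipeline's statistical behaviour is validated in the absence of deposited
raw images.

## Conversion model

`I₀/I = 1 + Kq[O₂]` with `Kq` defaulting to 2.2×10⁻³ µM⁻¹ (a typical
experimentally determined value for RTDP in buffer). Dissolved
concentration and partial pressure interconvert through the solubility
`α` (default 1.3 µM/mmHg, aqueous buffer near room temperature), giving
`PO₂ = (I₀/I − 1)/(Kq·α)`. `I₀` is taken from the zero-O₂ calibration
point, from the plateau of a fully deoxygenated trace, or supplied by the
user; the calibration fit is a through-origin least-squares line on
`(I₀/I − 1)` versus `[O₂]`, matching the first-order form of the
relation.

Intensities above `I₀` imply negative oxygen. Frames within a relative
tolerance (default 1%) of `I₀` are clamped to PO₂ = 0 silently — a fully
deoxygenated well's read noise routinely strays just above `I₀`, and
counting those frames would selectively disqualify fast-decaying wells
and bias cohort statistics upward. Frames *beyond* the tolerance are
counted, and a well with more than 10% of them is QC-failed (its `I₀` or
calibration is suspect).

## Decay fitting

Bounded nonlinear least squares (`scipy.optimize.least_squares`) with
`K ∈ [10⁻³, 50] s⁻¹`, seeded by a log-linear regression over the first
2 s. The default mode holds `A` fixed at the configured initial PO₂
(155.3 mmHg, the air-equilibrated level), making single-well fits a
robust one-parameter problem; a free-amplitude mode exists and is used to
verify amplitude recovery. A fit whose `K` lands on the lower bound, or a
zero-variance trace, is flagged as failed (never raised) and excluded
from cohort statistics with a reason code. `R² = 1 − SSres/SStot`;
the log-linear fit is initialization only and never reported.

## The well model

The simulator is a lumped two-compartment mass balance, not a spatial
PDE — the exact device geometry is not part of this package, and a
first-order wall term `k_wall` absorbs wall diffusivity and well shape:

    d/dt [ α·v_well·P + 4·c_heme·v_cell·S(P) ] = −k_wall·α·v_well·P

with Hill saturation `S(P) = Pⁿ/(Pⁿ + P50ⁿ)` and heme concentration from
the cell's MCHC (tetramer mass 64,500 g/mol, four O₂ sites). Hb–O₂
equilibrium is quasi-static: binding kinetics are milliseconds against
the ~1 s decay. The integrated form is `dP/dt = −k_wall·P/(1 + β·S′(P))`
with buffering ratio `β = 4·c_heme·v_cell/(α·v_well)`; the equation is
mildly stiff near `P50` and is integrated with LSODA at rtol 10⁻⁸,
alongside a cumulative wall-flux state so mass conservation is checked to
<10⁻⁶ relative. An empty well reduces exactly to
`P(t) = p_init·e^(−k_wall·t)` and is evaluated in closed form.

Defaults (configurable): `v_well` 1,800 fL (≈15 µm diameter × 10 µm
depth), `p_init` 155.3 mmHg, `v_cell` 90 fL, MCHC 33 g/dL, `P50` 30 mmHg,
Hill n 2.7, acquisition 100 frames/s for 4 s on 640×540-pixel frames —
the regime of the experimental platform this emulates. Time stamps follow
the frame convention `t = frame/frame_rate` (400 frames end at 3.99 s).

## Population generation and calibration

A cohort is specified by the *fitted* D50 distribution it should produce —
the quantity the pipeline measures — as a normal `(mean, SD)` truncated
at 0.1 s. Empty wells take `k_wall = ln 2/D50` directly; occupied wells
get `k_wall` from 1-D root finding (Brent) so that the buffered trace,
refitted by the very pipeline fit stage, lands on the drawn D50. This
closes the loop through the full analysis rather than calibrating raw
rates.

Draws use randomized-stratified (Latin-hypercube) inverse-CDF sampling by
default: each well's D50 retains the exact truncated-normal marginal,
while the cohort's empirical distribution reproduces the calibration
target's quantiles with minimal Monte-Carlo distortion — appropriate for
a generator whose purpose is calibration to stated population statistics.
Plain i.i.d. sampling is available (`sampling="iid"`). Note that the
truncated normal's mean exceeds the nominal mean slightly (for the widest
cohort used in the recovery experiments, 1.17 ± 0.52 s floored at 0.1 s,
by ≈ +0.025 s); recovered cohort means inherit this and stay well inside
the two-standard-error band.

## Rendering and extraction

Frames paint a uniform background, then each well as a disk at
`I = I₀/(1 + Kq·α·P(t))`, then additive Gaussian read noise (default SD
1% of `I₀`), quantized to 16-bit. The noise model is deliberately plain:
no Poisson shot noise, photobleaching, drift or flat-field structure —
so passing recovery tests demonstrate the pipeline's statistical
correctness under read noise, not robustness to every real-camera
artifact. Rasterization includes a pixel iff its center lies strictly
within the ROI radius; renderer and extractor share the same mask
routine, so synthetic round trips are exact up to the ≤0.5 AU uint16
quantization of the ROI mean. ROIs come from the layout table (device
design), never from segmentation, and occupancy is metadata — inferring
it from bright-field images is out of scope. Trace mode bypasses
rasterization and applies read noise at the ROI-mean scale
(`σ/√n_pixels`); it is statistically equivalent for cohort recovery and
orders of magnitude faster.

## Population statistics

FWHM is reported as 2.355·σ with σ the n−1 sample SD — a definition, not
a measurement off the KDE curve, hence bandwidth-independent. Skewness is
the adjusted Fisher–Pearson coefficient
`n/((n−1)(n−2)) · Σ((x_j−µ)/s)³`, returned as NaN (flagged, not raised)
for n < 3 or zero SD. The KDE is a Gaussian-kernel estimate on an even
grid spanning `[min−3h, max+3h]` with Silverman's rule-of-thumb bandwidth
`h = 0.9·min(s, IQR/1.34)·n^(−1/5)` by default; normalization holds to
10⁻³ by construction of the grid span. Tests delegate to scipy
(`mannwhitneyu`, `ttest_ind/rel`, `wilcoxon`, `f_oneway`, `kruskal`,
`tukey_hsd`); the Mann–Whitney exact p is cross-checked in the test suite
against brute-force rank enumeration. Raw p-values are always emitted;
significance flags use a configurable level (default 0.05) and no
multiple-testing correction beyond Tukey HSD is applied.

## Reproducibility and problem sizes

Every stochastic element (cohort draws, occupancy, render noise) derives
from one seed via `numpy` `SeedSequence` spawning; reports carry the
seed, a config hash and the package version, and identical configs
reproduce byte-identical CSVs. The bundled recovery experiments use the
cohort sizes of the emulated study (82/127/65 wells) at full 640×540
frame scale, which completes in tens of seconds on one core; unit tests
use smaller frames and shorter traces that exercise identical code paths.

## Known limitations

- The compartment model cannot reproduce spatial gradients inside a well
  or wall; `k_wall` is an effective parameter, not a diffusivity.
- Membrane permeability is not an explicit resistance; cell-volume and
  MCHC effects enter only through O₂ content and the Hill curve.
- The renderer's noise is additive Gaussian only; quantitative behaviour
  under shot-noise-limited imaging is untested.
- Paired designs across repeated measurements of the same cells, and
  donor-level nesting of single-cell values, are not modelled; cohorts
  are flat pools.
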