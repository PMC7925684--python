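# oxywell

Single-cell oxygen-release analysis for microwell fluorescence-quenching
oximetry.

Red blood cells (RBCs) are usually characterized by P50 — the oxygen
partial pressure at which hemoglobin is half saturated — a static,
equilibrium measure of O₂ affinity. How *fast* an individual cell actually
releases its oxygen is a different question. In a microfluidic platform
that traps single RBCs in femtoliter wells, deoxygenates the wells through
a thin PDMS wall into a nitrogen channel, and reads the local O₂ level
from an oxygen-quenched fluorescent probe, each well's PO₂ decay yields a
dynamic, per-cell kinetic statistic:

- Stern–Volmer quenching: `I₀/I = 1 + Kq·[O₂]`, so probe intensity
  converts to dissolved oxygen (and to PO₂ via the solubility α);
- exponential decay: `PO₂(t) = A·e^(−Kt)`, fitted per well by nonlinear
  regression;
- **D50 = ln(2)/K** — the time for the well's oxygen to fall by half.
  A cell in the well re-supplies O₂ as the well drains, so occupied wells
  decay more slowly and carry a larger D50; a higher D50 means faster O₂
  release by the cell.

`oxywell` implements the whole measurement chain as a reusable, testable
pipeline — including a physics-based synthetic-data generator (Hb-buffered
compartment ODE plus an sCMOS-style frame renderer), ROI-based trace
extraction from TIFF stacks, the conversion and fitting stages, and the
population-level analytics used to compare cohorts (kernel densities,
FWHM = 2.355·σ, adjusted Fisher–Pearson skewness, Mann–Whitney /
t / Wilcoxon / ANOVA / Kruskal–Wallis with Tukey HSD). It is aimed at
groups building or re-analyzing single-cell oximetry experiments and at
anyone who needs a calibrated simulator for method development.

## Worked example

Simulate two cohorts matched to a with/without-cell experiment (82
occupied wells at D50 1.17 ± 0.52 s, 127 empty wells at 0.80 ± 0.29 s),
render them to 640×540 frames at 100 frames/s, and run the full analysis:

```python
from oxywell.pipeline import CohortSpec, ComparisonSpec, RunConfig, run_pipeline

cfg = RunConfig(
    seed=1,
    mode="render",
    cohorts=[
        CohortSpec("with_rbc", 82, 1.17, 0.52, occupancy=1.0),
        CohortSpec("without_rbc", 127, 0.80, 0.29, occupancy=0.0),
    ],
    comparisons=[ComparisonSpec(["with_rbc", "without_rbc"], "mann_whitney")],
)
report = run_pipeline(cfg)
for label, s in report.summaries.items():
    print(f"{label}: n={s.n} mean={s.mean:.2f} s SD={s.sd:.2f} FWHM={s.fwhm:.2f}")
print("Mann-Whitney p =", f"{report.tests[0].p_value:.3g}")
```

prints

```
with_rbc: n=82 mean=1.20 s SD=0.49 FWHM=1.17
without_rbc: n=127 mean=0.81 s SD=0.28 FWHM=0.67
Mann-Whitney p = 1.94e-09
```

i.e. both cohort means are recovered within two standard errors of their
generating targets after the traces have gone through rendering, ROI
extraction, Stern–Volmer conversion and refitting, and the occupied wells
are cleanly separated from the empty ones. The same run is available from
the shell (`oxywell run --config cfg.yaml --out outdir`), and each stage
(`simulate`, `render`, `extract`, `convert`, `fit`, `stats`) can be run
on its own against the documented CSV/TIFF interfaces.

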