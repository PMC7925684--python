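"""Synthetic microwell deoxygenation: physics simulation, population
sampling, and fluorescence image rendering.

The device traps single red blood cells in femtoliter wells whose oxygen is
washed out through a thin PDMS wall into a nitrogen channel.  The model here
is a lumped (compartment) mass balance rather than a spatial PDE — the wall
flux is first order in well PO2 with rate ``k_wall``, which absorbs wall
diffusivity and well geometry:

    d/dt [ alpha·v_well·P + 4·c_heme·v_cell·S(P) ] = −k_wall·alpha·v_well·P

with Hill-equation hemoglobin saturation S(P) = P^n / (P^n + P50^n) and
heme-tetramer concentration c_heme from the cell's MCHC (64,500 g/mol, four
O2 sites).  The Hb term is quasi-static: Hb-O2 kinetics are milliseconds
against the ~1 s decay.  Rearranged, the ODE actually integrated is

    dP/dt = −k_wall·P / (1 + beta·S'(P)),   beta = 4·c_heme·v_cell/(alpha·v_well)

An empty well (no cell) reduces exactly to P(t) = p_init·e^(−k_wall·t) and
is evaluated in closed form.  An occupied well decays slower everywhere, so
its fitted D50 always exceeds ln(2)/k_wall.

Population sampling calibrates each well to a target *fitted* D50 — the
quantity the analysis pipeline measures — drawn from a truncated normal:
empty wells get k_wall = ln(2)/D50 directly, occupied wells get k_wall from
1-D root finding through the buffered model plus the fitting stage.

Rendering paints each well as a disk whose intensity follows the inverse
Stern–Volmer relation I = I0/(1 + Kq·alpha·P), plus Gaussian read noise,
onto 16-bit frames, emulating binned sCMOS acquisition (640×540 px at
100 frames/s by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import stats as sps
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .decay import DEFAULT_INITIAL_PO2, d50_from_k, fit_exponential
from .imaging import LAYOUT_COLUMNS, disk_mask
from .quench import DEFAULT_ALPHA_UM_PER_MMHG, PO2Trace, QuenchModel

__all__ = [
    "WellConfig",
    "CellParams",
    "PopulationSpec",
    "RenderSpec",
    "simulate_well",
    "sample_population",
    "simulate_population",
    "make_grid_layout",
    "render_frames",
    "write_stack",
]

#: Hemoglobin tetramer molar mass (g/mol); each tetramer binds 4 O2.
HB_TETRAMER_G_PER_MOL = 64_500.0
O2_SITES_PER_TETRAMER = 4


@dataclass(frozen=True)
class WellConfig:
    """Microwell geometry, wash-out rate and acquisition timing.

    v_well defaults to 1,800 fL (≈15 µm diameter × 10 µm depth well);
    p_init to 155.3 mmHg, the air-equilibrated initial PO2.
    """

    v_well: float = 1800.0           # fL
    k_wall: float = 0.87             # s^-1, first-order wall wash-out
    p_init: float = DEFAULT_INITIAL_PO2  # mmHg
    alpha: float = DEFAULT_ALPHA_UM_PER_MMHG  # µM / mmHg
    frame_rate: float = 100.0        # Hz
    duration: float = 4.0            # s

    def __post_init__(self) -> None:
        for name in ("v_well", "k_wall", "p_init", "alpha", "frame_rate", "duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.frame_rate * self.duration < 10:
            raise ValueError("frame_rate * duration must give at least 10 samples")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.frame_rate * self.duration))
        return np.arange(n) / self.frame_rate


@dataclass(frozen=True)
class CellParams:
    """A trapped RBC's oxygen content and Hb–O2 affinity parameters.

    Defaults are physiological anchors: 90 fL cell volume, MCHC 33 g/dL,
    P50 30 mmHg, Hill coefficient 2.7.
    """

    present: bool = True
    v_cell: float = 90.0     # fL
    mchc: float = 33.0       # g/dL
    p50_cell: float = 30.0   # mmHg
    hill_n: float = 2.7

    def __post_init__(self) -> None:
        if self.present:
            if not (self.v_cell > 0 and self.mchc > 0 and self.p50_cell > 0):
                raise ValueError("v_cell, mchc, p50_cell must be positive")
            if self.hill_n < 1:
                raise ValueError("hill_n must be >= 1")

    @property
    def c_heme_uM(self) -> float:
        """Hb tetramer concentration in the cell, µM."""
        return self.mchc * 10.0 / HB_TETRAMER_G_PER_MOL * 1e6

    @classmethod
    def empty(cls) -> "CellParams":
        return cls(present=False)


EMPTY_CELL = CellParams.empty()


@dataclass(frozen=True)
class PopulationSpec:
    """How to draw a cohort of wells: target fitted-D50 distribution."""

    n_wells: int
    d50_mean: float
    d50_sd: float
    occupancy: float = 0.0
    seed: int = 0
    label: str = ""
    d50_floor: float = 0.1   # truncation of the normal draw, s
    sampling: str = "stratified"  # "stratified" | "iid"

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if not self.d50_mean > 0 or self.d50_sd < 0:
            raise ValueError("d50_mean must be > 0 and d50_sd >= 0")
        if not 0 <= self.occupancy <= 1:
            raise ValueError("occupancy must be in [0, 1]")
        if self.sampling not in ("stratified", "iid"):
            raise ValueError("sampling must be 'stratified' or 'iid'")


@dataclass(frozen=True)
class RenderSpec:
    """Frame geometry, intensity levels and read noise for rendering."""

    frame_w: int = 640
    frame_h: int = 540
    well_radius_px: float = 6.0
    background_au: float = 80.0
    i0_au: float = 1000.0
    noise_sd_au: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.i0_au > self.background_au >= 0:
            raise ValueError("need i0_au > background_au >= 0")
        if self.noise_sd_au < 0:
            raise ValueError("noise_sd_au must be >= 0")


def _saturation(p: np.ndarray, cell: CellParams) -> np.ndarray:
    pn = np.power(p, cell.hill_n)
    return pn / (pn + cell.p50_cell**cell.hill_n)


def _dsat_dp(p: float, cell: CellParams) -> float:
    # S'(P) = n * P50^n * P^(n-1) / (P^n + P50^n)^2 ; S'(0) = 0 for n > 1
    if p <= 0:
        return 0.0
    n = cell.hill_n
    p50n = cell.p50_cell**n
    pn = p**n
    return n * p50n * p ** (n - 1) / (pn + p50n) ** 2


def buffering_ratio(cfg: WellConfig, cell: CellParams) -> float:
    """beta = 4·c_heme·v_cell / (alpha·v_well), in mmHg."""
    if not cell.present or cell.v_cell == 0:
        return 0.0
    return (
        O2_SITES_PER_TETRAMER * cell.c_heme_uM * cell.v_cell
        / (cfg.alpha * cfg.v_well)
    )


def simulate_well(
    cfg: WellConfig,
    cell: CellParams = EMPTY_CELL,
    well_id: str = "w0",
    rtol: float = 1e-8,
    return_o2_budget: bool = False,
):
    """Simulate one well's PO2 decay, sampled at cfg.frame_rate over cfg.duration.

    Empty wells use the closed form p_init·e^(−k_wall·t); occupied wells
    integrate the Hb-buffered ODE with LSODA (mildly stiff near P50).

    With ``return_o2_budget=True`` also returns a dict with the initial and
    final total O2 content of well + cell and the cumulative amount removed
    through the wall (all in µM·fL), for mass-balance checks.
    """
    t = cfg.times
    beta = buffering_ratio(cfg, cell)
    if beta == 0.0:
        po2 = cfg.p_init * np.exp(-cfg.k_wall * t)
        trace = PO2Trace(well_id, t, po2)
        if return_o2_budget:
            content = lambda p: cfg.alpha * cfg.v_well * p  # noqa: E731
            budget = {
                "initial": content(cfg.p_init),
                "final": content(po2[-1]),
                "removed": content(cfg.p_init) - content(po2[-1]),
            }
            return trace, budget
        return trace

    def rhs(_t, y):
        p = max(y[0], 0.0)
        dp = -cfg.k_wall * p / (1.0 + beta * _dsat_dp(p, cell))
        # second state: cumulative O2 removed through the wall, µM·fL
        return [dp, cfg.k_wall * cfg.alpha * cfg.v_well * p]

    sol = solve_ivp(
        rhs,
        (0.0, float(t[-1])) if t[-1] > 0 else (0.0, cfg.duration),
        [cfg.p_init, 0.0],
        t_eval=t,
        method="LSODA",
        rtol=rtol,
        atol=[rtol * cfg.p_init * 1e-2, rtol * cfg.alpha * cfg.v_well * cfg.p_init * 1e-2],
    )
    if not sol.success:
        raise RuntimeError(f"well {well_id}: ODE integration failed: {sol.message}")
    po2 = sol.y[0]
    if np.any(po2 < -1e-9):
        raise RuntimeError(f"well {well_id}: negative PO2 state")
    trace = PO2Trace(well_id, t, np.clip(po2, 0.0, None))
    if return_o2_budget:
        def content(p):
            cell_o2 = (
                O2_SITES_PER_TETRAMER * cell.c_heme_uM * cell.v_cell
                * float(_saturation(np.asarray(p, float), cell))
            )
            return cfg.alpha * cfg.v_well * p + cell_o2

        budget = {
            "initial": content(cfg.p_init),
            "final": content(po2[-1]),
            "removed": float(sol.y[1][-1]),
        }
        return trace, budget
    return trace


def _fitted_d50(cfg: WellConfig, cell: CellParams) -> float:
    fit = fit_exponential(simulate_well(cfg, cell), fix_amplitude=cfg.p_init)
    if not fit.success:
        raise RuntimeError(f"calibration fit failed: {fit.failure_reason}")
    return fit.d50


def calibrate_k_wall(
    target_d50: float,
    cfg: WellConfig,
    cell: CellParams,
    xtol: float = 1e-6,
) -> float:
    """Find k_wall so an occupied well's *fitted* D50 equals *target_d50*.

    Buffering slows the decay, so the required k_wall exceeds ln(2)/D50;
    the bracket grows geometrically from there.  Raises if the target is
    infeasible within the fit's K bounds.
    """
    if not cell.present:
        return d50_from_k(target_d50)  # symmetric relation: k = ln2/d50
    k_lo = math.log(2.0) / target_d50

    def g(k):
        return _fitted_d50(replace(cfg, k_wall=k), cell) - target_d50

    g_lo = g(k_lo)
    if g_lo < 0:  # cannot happen physically; guard for numerics
        return k_lo
    k_hi = k_lo
    for _ in range(40):
        k_hi *= 1.6
        if k_hi > 50.0:
            raise RuntimeError(f"target D50 {target_d50} s infeasible (k_wall > 50/s)")
        if g(k_hi) < 0:
            break
    else:
        raise RuntimeError(f"no bracket found for target D50 {target_d50} s")
    return float(brentq(g, k_lo, k_hi, xtol=xtol, rtol=1e-8))


def _draw_d50s(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-well target D50s from the truncated normal (floor at d50_floor).

    Stratified mode (default) draws one value per probability stratum via
    the inverse CDF and permutes: each well's D50 keeps the exact truncated
    normal marginal while the cohort's empirical distribution — mean, SD,
    quantiles — reproduces the calibration target with minimal Monte-Carlo
    distortion, which is the generator's purpose.  "iid" gives plain
    independent draws.
    """
    n = spec.n_wells
    if spec.d50_sd == 0:
        return np.full(n, spec.d50_mean)
    a = (spec.d50_floor - spec.d50_mean) / spec.d50_sd
    tn = sps.truncnorm(a, np.inf, loc=spec.d50_mean, scale=spec.d50_sd)
    if spec.sampling == "stratified":
        u = (rng.permutation(n) + rng.uniform(size=n)) / n
        return tn.ppf(u)
    return tn.rvs(size=n, random_state=rng)


def sample_population(spec: PopulationSpec, cfg: WellConfig) -> pd.DataFrame:
    """Draw a cohort's per-well generator parameters, reproducibly.

    Each well's target fitted D50 follows N(d50_mean, d50_sd) truncated at
    d50_floor (see :func:`_draw_d50s` for the sampling scheme); occupancy
    is Bernoulli(spec.occupancy).  The returned table has columns well_id,
    cohort, occupied, d50_true_s, k_wall_per_s, v_cell_fL, mchc_g_dL,
    p50_mmHg, hill_n.
    """
    rng = np.random.default_rng(spec.seed)
    occupied_flags = rng.random(spec.n_wells) < spec.occupancy
    d50s = _draw_d50s(spec, rng)
    rows = []
    cell_defaults = CellParams()
    for i in range(spec.n_wells):
        occupied = bool(occupied_flags[i])
        cell = cell_defaults if occupied else EMPTY_CELL
        d50 = float(d50s[i])
        for attempt in range(100):
            try:
                k_wall = calibrate_k_wall(d50, cfg, cell)
                break
            except RuntimeError:
                # infeasible draw: resample this well independently
                d50 = float(rng.normal(spec.d50_mean, spec.d50_sd))
                while d50 < spec.d50_floor:
                    d50 = float(rng.normal(spec.d50_mean, spec.d50_sd))
        else:
            raise RuntimeError(
                f"could not draw a feasible D50 for well {i} after 100 attempts"
            )
        rows.append(
            {
                "well_id": f"{spec.label or 'w'}{i:04d}",
                "cohort": spec.label,
                "occupied": occupied,
                "d50_true_s": d50,
                "k_wall_per_s": k_wall,
                "v_cell_fL": cell.v_cell if occupied else 0.0,
                "mchc_g_dL": cell.mchc if occupied else 0.0,
                "p50_mmHg": cell.p50_cell if occupied else np.nan,
                "hill_n": cell.hill_n if occupied else np.nan,
            }
        )
    return pd.DataFrame(rows)


def simulate_population(
    table: pd.DataFrame, cfg: WellConfig
) -> list[PO2Trace]:
    """Simulate the PO2 trace for every well in a parameter table."""
    traces = []
    for r in table.itertuples():
        cell = (
            CellParams(
                present=True,
                v_cell=r.v_cell_fL,
                mchc=r.mchc_g_dL,
                p50_cell=r.p50_mmHg,
                hill_n=r.hill_n,
            )
            if r.occupied
            else EMPTY_CELL
        )
        traces.append(
            simulate_well(replace(cfg, k_wall=r.k_wall_per_s), cell, well_id=str(r.well_id))
        )
    return traces


def make_grid_layout(
    table: pd.DataFrame,
    rspec: RenderSpec,
    pitch: float | None = None,
    margin: float | None = None,
) -> pd.DataFrame:
    """Place the table's wells on a regular grid inside the frame.

    Returns the layout table (well_id, cx_px, cy_px, radius_px, occupied,
    cohort).  Raises if the frame cannot hold the wells without overlap.
    """
    r = rspec.well_radius_px
    pitch = pitch if pitch is not None else 4 * r + 8
    margin = margin if margin is not None else pitch / 2 + r
    n = len(table)
    n_cols = int((rspec.frame_w - 2 * margin) // pitch) + 1
    n_rows = int((rspec.frame_h - 2 * margin) // pitch) + 1
    if n_cols * n_rows < n:
        raise ValueError(
            f"frame {rspec.frame_w}x{rspec.frame_h} holds {n_cols * n_rows} wells "
            f"at pitch {pitch}; need {n}"
        )
    rows = []
    for i, rec in enumerate(table.itertuples()):
        cx = margin + (i % n_cols) * pitch
        cy = margin + (i // n_cols) * pitch
        rows.append(
            {
                "well_id": str(rec.well_id),
                "cx_px": cx,
                "cy_px": cy,
                "radius_px": r,
                "occupied": bool(rec.occupied),
                "cohort": str(rec.cohort),
            }
        )
    return pd.DataFrame(rows, columns=LAYOUT_COLUMNS)


def render_frames(
    traces: list[PO2Trace],
    quench: QuenchModel,
    rspec: RenderSpec,
    layout: pd.DataFrame,
) -> np.ndarray:
    """Render traces into a 16-bit (frames, h, w) stack.

    Each frame paints the background level, then each well's disk at
    I = I0 / (1 + Kq·alpha·P(t)), then adds Gaussian read noise and
    quantizes to uint16.  Wells must not overlap.
    """
    if len(traces) != len(layout):
        raise ValueError("one layout row per trace required")
    h, w = rspec.frame_h, rspec.frame_w
    n_frames = len(traces[0].time)
    by_id = {tr.well_id: tr for tr in traces}

    masks = []
    covered = np.zeros((h, w), dtype=bool)
    for rec in layout.itertuples():
        mask = disk_mask((h, w), rec.cx_px, rec.cy_px, rec.radius_px)
        if np.any(covered & mask):
            raise ValueError(f"well {rec.well_id}: disk overlaps another well")
        covered |= mask
        tr = by_id[str(rec.well_id)]
        if len(tr.time) != n_frames:
            raise ValueError("all traces must have the same length")
        # per-frame disk intensity from the inverse Stern–Volmer relation
        inten = rspec.i0_au / (1.0 + quench.kq * quench.alpha * tr.po2)
        masks.append((np.flatnonzero(mask.ravel()), inten))

    rng = np.random.default_rng(rspec.seed)
    stack = np.empty((n_frames, h, w), dtype=np.uint16)
    frame = np.empty(h * w, dtype=float)
    for f in range(n_frames):
        frame[:] = rspec.background_au
        for idx, inten in masks:
            frame[idx] = inten[f]
        if rspec.noise_sd_au > 0:
            frame += rng.normal(0.0, rspec.noise_sd_au, size=frame.shape)
        stack[f] = np.clip(np.rint(frame), 0, 65535).reshape(h, w).astype(np.uint16)
    return stack


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a multi-page 16-bit grayscale TIFF."""
    tifffile.imwrite(path, stack, photometric="minisblack")
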