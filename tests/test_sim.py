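"""Microwell physics simulation, population sampling, and rendering."""

import numpy as np
import pandas as pd
import pytest

from oxywell.decay import fit_exponential
from oxywell.imaging import disk_mask, extract_traces, load_layout
from oxywell.quench import intensity_to_po2
from oxywell.sim import (
    CellParams,
    PopulationSpec,
    RenderSpec,
    WellConfig,
    buffering_ratio,
    calibrate_k_wall,
    make_grid_layout,
    render_frames,
    sample_population,
    simulate_population,
    simulate_well,
)

from conftest import small_cohort_table


def rk4_oracle(cfg, cell, n_sub=10):
    """Independent fixed-step RK4 integration of the buffered O2 balance,
    at n_sub× finer step than the acquisition interval."""
    beta = buffering_ratio(cfg, cell)
    n, p50 = cell.hill_n, cell.p50_cell

    def dsat(p):
        if p <= 0:
            return 0.0
        return n * p50**n * p ** (n - 1) / (p**n + p50**n) ** 2

    def f(p):
        return -cfg.k_wall * p / (1.0 + beta * dsat(p))

    dt = 1.0 / (cfg.frame_rate * n_sub)
    times = cfg.times
    out = np.empty_like(times)
    p = cfg.p_init
    out[0] = p
    for i in range(1, len(times)):
        for _ in range(n_sub):
            k1 = f(p)
            k2 = f(p + 0.5 * dt * k1)
            k3 = f(p + 0.5 * dt * k2)
            k4 = f(p + dt * k3)
            p += dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i] = p
    return out


class TestSimulateWell:
    def test_empty_well_equals_closed_form(self):
        cfg = WellConfig(k_wall=0.63)
        tr = simulate_well(cfg)
        np.testing.assert_allclose(tr.po2, 155.3 * np.exp(-0.63 * tr.time), rtol=0, atol=0)
        fit = fit_exponential(tr, fix_amplitude=155.3)
        assert fit.K == pytest.approx(0.63, rel=1e-9)

    def test_vanishing_cell_volume_converges_to_empty_well(self):
        cfg = WellConfig(k_wall=0.87)
        empty = simulate_well(cfg)
        tiny = simulate_well(cfg, CellParams(present=True, v_cell=1e-9))
        assert np.max(np.abs(tiny.po2 - empty.po2)) < 1e-6

    def test_occupied_well_agrees_with_independent_integrator(self):
        cfg = WellConfig(k_wall=0.87)
        cell = CellParams()  # 90 fL, MCHC 33, P50 30, Hill 2.7
        tr = simulate_well(cfg, cell)
        oracle = rk4_oracle(cfg, cell, n_sub=10)
        assert np.max(np.abs(tr.po2 - oracle)) < 1e-3  # mmHg

    def test_occupied_well_slows_decay(self):
        cfg = WellConfig(k_wall=0.87)
        fit = fit_exponential(simulate_well(cfg, CellParams()), fix_amplitude=cfg.p_init)
        assert fit.d50 > np.log(2) / 0.87

    def test_o2_mass_conservation(self):
        cfg = WellConfig(k_wall=0.87)
        _, budget = simulate_well(cfg, CellParams(), return_o2_budget=True)
        lost = budget["initial"] - budget["final"]
        assert abs(lost - budget["removed"]) / budget["removed"] < 1e-6

    def test_fitted_d50_monotone_in_cell_o2_content_and_affinity(self):
        cfg = WellConfig(k_wall=0.87)

        def d50(**kw):
            fit = fit_exponential(
                simulate_well(cfg, CellParams(**kw)), fix_amplitude=cfg.p_init
            )
            return fit.d50

        # more hemoglobin (v_cell·MCHC) releases more O2 into the well
        assert d50(mchc=20.0) < d50(mchc=33.0) < d50(mchc=45.0)
        assert d50(v_cell=60.0) < d50(v_cell=90.0) < d50(v_cell=120.0)
        # higher P50 releases O2 earlier in the decay, slowing it more
        assert d50(p50_cell=15.0) < d50(p50_cell=30.0) < d50(p50_cell=45.0)


class TestPopulationSampling:
    def test_calibrated_k_wall_closes_the_loop(self):
        cfg = WellConfig()
        cell = CellParams()
        k = calibrate_k_wall(1.17, cfg, cell)
        fit = fit_exponential(simulate_well(WellConfig(k_wall=k), cell),
                              fix_amplitude=cfg.p_init)
        assert fit.d50 == pytest.approx(1.17, abs=1e-5)
        assert k > np.log(2) / 1.17  # buffering always demands faster wash-out

    def test_cohort_mean_recovers_target(self):
        spec = PopulationSpec(n_wells=1000, d50_mean=0.80, d50_sd=0.29, seed=7)
        table = sample_population(spec, WellConfig())
        se = 0.29 / np.sqrt(1000)
        assert abs(table.d50_true_s.mean() - 0.80) < 2 * se
        # empty wells: k_wall is exactly ln2/D50
        np.testing.assert_allclose(
            table.k_wall_per_s, np.log(2) / table.d50_true_s, rtol=1e-12
        )

    def test_zero_sd_gives_identical_wells(self):
        spec = PopulationSpec(n_wells=5, d50_mean=0.8, d50_sd=0.0, seed=1)
        table = sample_population(spec, WellConfig())
        assert table.d50_true_s.nunique() == 1

    def test_same_seed_reproduces_table_exactly(self):
        spec = PopulationSpec(n_wells=8, d50_mean=1.0, d50_sd=0.3,
                              occupancy=0.5, seed=3, label="a")
        cfg = WellConfig()
        pd.testing.assert_frame_equal(
            sample_population(spec, cfg), sample_population(spec, cfg)
        )

    def test_iid_mode_also_recovers_target(self):
        spec = PopulationSpec(n_wells=1000, d50_mean=0.80, d50_sd=0.29,
                              seed=7, sampling="iid")
        table = sample_population(spec, WellConfig())
        assert abs(table.d50_true_s.mean() - 0.80) < 2 * 0.29 / np.sqrt(1000) + 0.02


class TestRendering:
    def test_fully_deoxygenated_wells_render_at_i0(self, quench):
        cfg = WellConfig(duration=0.2)
        table = small_cohort_table([1.0])
        traces = simulate_population(table, cfg)
        for tr in traces:
            tr.po2[:] = 0.0
        rspec = RenderSpec(frame_w=64, frame_h=64, well_radius_px=5,
                           noise_sd_au=0.0)
        layout = make_grid_layout(table, rspec)
        stack = render_frames(traces, quench, rspec, layout)
        mask = disk_mask((64, 64), layout.cx_px[0], layout.cy_px[0], 5)
        assert np.all(stack[:, mask] == 1000)
        assert np.all(stack[:, ~mask] == 80)

    def test_well_mean_intensity_matches_quench_formula(self, quench):
        # PO2 = 155.3 at alpha 1.3 gives I = I0/1.4442; uint16 quantization
        # bounds the ROI-mean error at 0.5 AU
        cfg = WellConfig(k_wall=0.6, duration=0.2)
        table = small_cohort_table([0.6])
        traces = simulate_population(table, cfg)
        rspec = RenderSpec(frame_w=64, frame_h=64, well_radius_px=6, noise_sd_au=0.0)
        layout = make_grid_layout(table, rspec)
        stack = render_frames(traces, quench, rspec, layout)
        mask = disk_mask((64, 64), layout.cx_px[0], layout.cy_px[0], 6)
        assert stack[0, mask].mean() == pytest.approx(1000 / 1.4442, abs=0.5)

    def test_overlapping_wells_rejected(self, quench, small_stack):
        layout = small_stack["layout"].copy()
        layout.loc[1, ["cx_px", "cy_px"]] = layout.loc[0, ["cx_px", "cy_px"]].values
        with pytest.raises(ValueError, match="overlap"):
            render_frames(small_stack["traces"], quench, small_stack["rspec"], layout)

    def test_render_extract_fit_round_trip(self, quench):
        """10 wells rendered at 1% read noise refit to their generating D50
        within 3% each."""
        cfg = WellConfig()
        k_walls = np.log(2) / np.linspace(0.5, 1.5, 10)
        table = small_cohort_table(k_walls)
        traces = simulate_population(table, cfg)
        rspec = RenderSpec(frame_w=256, frame_h=192, well_radius_px=6,
                           noise_sd_au=10.0, seed=11)
        layout = make_grid_layout(table, rspec)
        stack = render_frames(traces, quench, rspec, layout)
        rois = load_layout(layout, frame_shape=(192, 256))
        itraces = extract_traces(stack, rois, cfg.frame_rate)
        for itr, d50_true in zip(itraces, table.d50_true_s):
            fit = fit_exponential(intensity_to_po2(itr, quench),
                                  fix_amplitude=cfg.p_init)
            assert fit.d50 == pytest.approx(d50_true, rel=0.03)


class TestValidation:
    @pytest.mark.parametrize(
        "kw", [dict(v_well=0), dict(k_wall=-1), dict(frame_rate=0),
               dict(frame_rate=1.0, duration=2.0)],
    )
    def test_bad_well_config_rejected(self, kw):
        with pytest.raises(ValueError):
            WellConfig(**kw)

    def test_bad_cell_params_rejected(self):
        with pytest.raises(ValueError):
            CellParams(present=True, hill_n=0.5)

    def test_bad_render_spec_rejected(self):
        with pytest.raises(ValueError):
            RenderSpec(background_au=2000.0, i0_au=1000.0)

    def test_grid_capacity_enforced(self):
        table = small_cohort_table(np.full(100, 0.8))
        with pytest.raises(ValueError, match="holds"):
            make_grid_layout(table, RenderSpec(frame_w=64, frame_h=64))
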