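import numpy as np
import pandas as pd
import pytest

from oxywell.quench import QuenchModel
from oxywell.sim import (
    RenderSpec,
    WellConfig,
    make_grid_layout,
    render_frames,
    simulate_population,
)

KQ = 2.2e-3  # Stern–Volmer constant, µM^-1
P_INIT = 155.3  # air-equilibrated initial PO2, mmHg


@pytest.fixture(scope="session")
def quench() -> QuenchModel:
    return QuenchModel(kq=KQ, i0=1000.0, alpha=1.3)


def small_cohort_table(k_walls, occupied=False, label="t"):
    """Parameter table for empty wells at given wash-out rates."""
    return pd.DataFrame(
        {
            "well_id": [f"{label}{i}" for i in range(len(k_walls))],
            "cohort": label,
            "occupied": occupied,
            "d50_true_s": np.log(2) / np.asarray(k_walls, float),
            "k_wall_per_s": k_walls,
            "v_cell_fL": 0.0,
            "mchc_g_dL": 0.0,
            "p50_mmHg": np.nan,
            "hill_n": np.nan,
        }
    )


@pytest.fixture(scope="session")
def small_stack(quench):
    """A noiseless 3-well rendered stack with its layout and ground truth.

    Small frame (128×96) and short duration keep rendering tests fast while
    exercising the same code paths as full-size acquisition.
    """
    cfg = WellConfig(frame_rate=100.0, duration=2.0)
    k_walls = [0.5, 0.87, 1.3]
    table = small_cohort_table(k_walls)
    traces = simulate_population(table, cfg)
    rspec = RenderSpec(
        frame_w=128, frame_h=96, well_radius_px=5.0,
        background_au=80.0, i0_au=1000.0, noise_sd_au=0.0, seed=0,
    )
    layout = make_grid_layout(table, rspec)
    stack = render_frames(traces, quench, rspec, layout)
    return {
        "cfg": cfg, "table": table, "traces": traces,
        "rspec": rspec, "layout": layout, "stack": stack,
    }
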