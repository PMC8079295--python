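"""Shared fixtures: one simulated default cohort reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import shuttlebox as sb


@pytest.fixture(scope="session")
def default_cfg() -> sb.SimulationConfig:
    return sb.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def cohort(default_cfg):
    return sb.sample_cohort(default_cfg)


@pytest.fixture(scope="session")
def cohort_logs(default_cfg, cohort):
    return [sb.simulate_trajectory(f, default_cfg) for f in cohort]


@pytest.fixture(scope="session")
def cohort_summaries(default_cfg, cohort_logs):
    out = []
    for log in cohort_logs:
        out.extend(sb.bin_intervals(log, default_cfg.protocol, default_cfg.geometry))
    return out


def make_flat_log(n_s: int, fish_id: str = "f01", sbl: float = 9.0,
                  temp_start: float = 25.65, temp_drift: float = 0.0,
                  x: float = -32.0, y: float = 0.0) -> sb.PositionLog:
    """Minimal valid stationary position log for EOD-oriented tests."""
    temp = temp_start + temp_drift * np.arange(n_s) / max(n_s - 1, 1)
    frame = pd.DataFrame({
        "t_s": np.arange(n_s), "x_cm": x, "y_cm": y,
        "dist_cm": 0.0, "vel_cm_s": 0.0,
        "do_left": 97.0, "do_right": 97.0, "temp_c": np.round(temp, 4),
    })
    return sb.PositionLog(fish_id, sbl, "left", frame)
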