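import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spliffkit as sk

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def noiseless_config():
    """Reporter kinetics with measurement effects switched off."""
    return sk.ReporterKineticsConfig(
        noise_sd=0.0,
        background_level=0.0,
        bleach_per_exposure_red=0.0,
        bleach_per_exposure_green=0.0,
    )


@pytest.fixture
def benchmark_schedule():
    return sk.standard_benchmark_schedule()


@pytest.fixture
def short_schedule():
    """A small, fast schedule: 40 min at 2-min sampling, one window."""
    return sk.InteractionSchedule(
        windows=[(4.0, 20.0, "PCDI")],
        total_duration=40.0,
        sampling_interval=2.0,
        fusion_time=4.0,
    )


def make_conversion_frame(times, fd_by_cell):
    """Build a minimal conversion table from {cell_id: fd_values}."""
    import pandas as pd

    rows = []
    for cell, fds in fd_by_cell.items():
        for t, fd in zip(times, fds):
            rows.append(
                {
                    "cell_id": cell,
                    "time_min": float(t),
                    "rfi_red": 1.0,
                    "rfi_green": 1.0 - fd / 100.0,
                    "fd_percent": float(fd),
                    "phase": "unassigned",
                    "flag_negative": fd < 0,
                    "flag_caveat": fd >= 80,
                    "flag_invalid": not np.isfinite(fd),
                }
            )
    return pd.DataFrame(rows)
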