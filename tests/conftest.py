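import numpy as np
import pytest

import cardioahi as ca


@pytest.fixture(scope="session")
def small_recording():
    """One 1-h synthetic recording with moderate OSA and some ectopy."""
    cfg = ca.SimulationConfig(duration_h=1.0, target_ahi=20.0, seed=42,
                              ectopic_rate=0.002)
    return ca.generate_recording(cfg)


@pytest.fixture(scope="session")
def small_population():
    """Twelve 1-h recordings across the four severity classes."""
    mix = {"normal": 0.25, "mild": 0.25, "moderate": 0.25, "severe": 0.25}
    cfg = ca.SimulationConfig(duration_h=1.0, seed=0)
    return ca.generate_population(12, mix, cfg, seed=7)


def grid_events(rng, n_epochs, n_events, kinds=("obstructive_apnea",
                                                "hypopnea", "central_apnea",
                                                "mixed_apnea")):
    """Random events on a 0.125-s grid (exactly representable in floats,
    and an integer number of milliseconds) for oracle comparisons."""
    total_ticks = n_epochs * 240  # 240 ticks of 0.125 s per epoch
    events = []
    for _ in range(n_events):
        dur_ticks = 80 + int(rng.integers(0, 241))  # 10-40 s
        onset_ticks = int(rng.integers(0, max(1, total_ticks - dur_ticks)))
        events.append(ca.RespiratoryEvent(
            kinds[int(rng.integers(0, len(kinds)))],
            onset_ticks * 0.125, dur_ticks * 0.125))
    return events
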