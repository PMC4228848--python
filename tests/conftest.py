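import numpy as np
import pytest

from patchdose.simulate import GatingModel, gating_preset, simulate_gating, render_trace


@pytest.fixture(scope="session")
def atp1_trace():
    """60-s two-channel trace at 20 kHz, SNR 8, 1 kHz filter (ATP1-like gating)."""
    model = gating_preset("gh3-atp1", n_channels=2)
    paths = simulate_gating(model, 60_000.0, seed=101)
    return model, render_trace(model, paths, seed=202)


@pytest.fixture(scope="session")
def noiseless_two_state():
    """5-s noise-free unfiltered single-channel trace (tau_o 2 ms, tau_c 20 ms)."""
    model = GatingModel.two_state(2.0, 20.0, n_channels=1)
    paths = simulate_gating(model, 5_000.0, seed=7)
    trace = render_trace(model, paths, noise_sd=0.0, filter_cutoff_khz=None, seed=0)
    return model, trace


def truth_events(trace):
    """Run-length encode the sampled ground-truth level path."""
    lv = trace.ground_truth["level_per_sample"]
    change = np.flatnonzero(np.diff(lv)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(lv)]))
    return lv[starts].astype(int), (ends - starts) * trace.dt_ms
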