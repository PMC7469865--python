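import numpy as np
import pandas as pd
import pytest

from erpdecode.containers import EpochSet, times_for_window


def make_epochs(data, sfreq=250.0, start_ms=-200.0, channels=None,
                condition=None, trial_info=None, **kw):
    """Assemble an EpochSet from a raw array with minimal boilerplate."""
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, n_samp = data.shape
    if channels is None:
        channels = [f"C{i}" for i in range(n_ch)]
    if condition is None:
        condition = np.array(["a"] * n_trials, dtype=object)
    times = start_ms + np.arange(n_samp) * 1000.0 / sfreq
    return EpochSet(data=data, times=times, sfreq=sfreq, channels=channels,
                    condition=np.asarray(condition, dtype=object),
                    trial_info=trial_info, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cue_like_epochs(rng):
    """Small cue-locked epochs: 2 conditions x 12 trials, 6 channels, 250 Hz."""
    times = times_for_window(-1000.0, 1400.0, 250.0)
    data = rng.normal(0, 5, size=(24, 6, len(times)))
    condition = np.array(["cue_left"] * 12 + ["cue_right"] * 12, dtype=object)
    return make_epochs(data, start_ms=-1000.0, condition=condition,
                       channels=["F7", "F8", "P3", "P4", "O1", "O2"])


@pytest.fixture
def target_like_epochs(rng):
    """Target-locked epochs with cue/target side metadata."""
    times = times_for_window(-500.0, 1000.0, 250.0)
    n = 40
    data = rng.normal(0, 5, size=(n, 8, len(times)))
    cue = rng.choice(["left", "right"], size=n).astype(object)
    tgt = rng.choice(["left", "right"], size=n).astype(object)
    cued = cue == tgt
    info = pd.DataFrame({"cue_side": cue, "target_side": tgt,
                         "rt": rng.normal(500, 50, n), "correct": True})
    condition = np.where(cued, "cued_target", "uncued_target").astype(object)
    return make_epochs(data, start_ms=-500.0, condition=condition,
                       channels=["P3", "P4", "P7", "P8", "O1", "O2", "Cz", "Fz"],
                       trial_info=info)
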