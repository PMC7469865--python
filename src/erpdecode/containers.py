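"""In-memory containers for epoched EEG.

The central object is :class:`EpochSet`: a trials x channels x samples
array in microvolts with a millisecond time axis relative to the locking
event (cue or target onset), per-trial condition labels, and an optional
per-trial metadata table (cue side, target side, reaction time, ...).

Time-axis convention
--------------------
Epoch windows are half-open ``[start, end)`` on the sample grid: an epoch
from -1000 to 1400 ms at 250 Hz holds 600 samples at
``-1000, -996, ..., 1396`` ms.  With this convention the standard analysis
windows come out at exactly 100 cue-locked and 55 target-locked points
after trimming and 50 Hz downsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ChannelError, ConfigurationError, DataError

#: Labels treated as electro-oculogram (excluded from "EEG channels").
EOG_LABELS = ("HEOG", "VEOG")


def times_for_window(start_ms: float, end_ms: float, sfreq: float) -> np.ndarray:
    """Sample times (ms) of the half-open window ``[start_ms, end_ms)``."""
    if end_ms <= start_ms:
        raise ConfigurationError(f"window start {start_ms} must precede end {end_ms}")
    if sfreq <= 0:
        raise ConfigurationError("sampling rate must be positive")
    step = 1000.0 / sfreq
    n = int(round((end_ms - start_ms) / step))
    return start_ms + np.arange(n) * step


def window_indices(times: np.ndarray, start_ms: float, end_ms: float,
                   inclusive: bool = False) -> np.ndarray:
    """Indices of samples in ``[start, end)`` (or ``[start, end]``)."""
    if inclusive:
        sel = (times >= start_ms - 1e-9) & (times <= end_ms + 1e-9)
    else:
        sel = (times >= start_ms - 1e-9) & (times < end_ms - 1e-9)
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise ConfigurationError(
            f"window {start_ms}..{end_ms} ms contains no samples")
    return idx


@dataclass
class EpochSet:
    """Epoched multichannel EEG for one subject and one locking event.

    Parameters
    ----------
    data
        ``(n_trials, n_channels, n_samples)`` array, microvolts.
    times
        Sample times in ms relative to the locking event; strictly
        increasing with uniform spacing ``1000 / sfreq``.
    sfreq
        Sampling rate in Hz.
    channels
        Unique channel labels (10-20 montage names plus optional
        ``HEOG``/``VEOG``).
    condition
        Per-trial condition label (e.g. ``cue_left``/``cue_right`` or
        ``cued_target``/``uncued_target``).
    trial_info
        Optional per-trial metadata (``cue_side``, ``target_side``,
        ``rt``, ``correct``, ...), one row per trial.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    channels: list[str]
    condition: np.ndarray
    subject_id: str = ""
    locking_event: str = ""
    trial_info: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        self.channels = list(self.channels)
        if self.data.ndim != 3:
            raise DataError("data must be trials x channels x samples")
        n_trials, n_channels, n_samples = self.data.shape
        if len(self.channels) != n_channels:
            raise DataError("channel label count does not match data")
        if len(set(self.channels)) != n_channels:
            raise DataError("channel labels must be unique")
        if self.times.shape != (n_samples,):
            raise DataError("time vector length does not match data")
        if n_samples > 1:
            dt = np.diff(self.times)
            if not np.all(dt > 0):
                raise DataError("time vector must be strictly increasing")
            if not np.allclose(dt, 1000.0 / self.sfreq, atol=1e-6):
                raise DataError("time spacing must equal 1000/sfreq ms")
        if self.condition.shape != (n_trials,):
            raise DataError("condition label count does not match trials")
        if self.trial_info is not None and len(self.trial_info) != n_trials:
            raise DataError("trial_info row count does not match trials")

    # -- basic accessors -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise ChannelError(f"channel {label!r} not present") from None

    def eeg_channels(self) -> list[str]:
        """Channel labels excluding EOG derivations."""
        return [c for c in self.channels if c not in EOG_LABELS]

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            times=self.times.copy(),
            condition=self.condition.copy(),
            trial_info=None if self.trial_info is None else self.trial_info.copy(),
        )

    # -- selection -------------------------------------------------------
    def select_channels(self, labels: list[str]) -> "EpochSet":
        idx = [self.channel_index(lb) for lb in labels]
        return replace(self, data=self.data[:, idx, :], channels=list(labels))

    def select_trials(self, index: np.ndarray) -> "EpochSet":
        index = np.asarray(index)
        info = None if self.trial_info is None else (
            self.trial_info.iloc[index].reset_index(drop=True))
        return replace(self, data=self.data[index], condition=self.condition[index],
                       trial_info=info)

    def select_samples(self, index: np.ndarray, sfreq: float | None = None) -> "EpochSet":
        index = np.asarray(index)
        return replace(self, data=self.data[:, :, index], times=self.times[index],
                       sfreq=self.sfreq if sfreq is None else sfreq)

    def trials_of(self, condition: str) -> np.ndarray:
        return np.flatnonzero(self.condition == condition)
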