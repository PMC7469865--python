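"""Trial-level artifact screening.

Four rejection criteria operating on epoched data:

1. moving-window peak-to-peak on any EEG channel (200 ms window, 50 ms
   step, 150 uV),
2. absolute voltage anywhere in the epoch on any EEG channel (100 uV),
3. step function on the bipolar HEOG (400 ms window, 10 ms step, 40 uV):
   difference in mean amplitude between the two window halves, sensitive
   to small saccades,
4. moving-window peak-to-peak on the bipolar VEOG restricted to the
   stimulus period -200..200 ms (200 ms window, 10 ms step, 50 uV),
   catching blinks around stimulus presentation.

Windows are evaluated only where they fit entirely inside the epoch (or
scan interval); no partial end window is tested.  The final rejection mask
is the union over criteria, so the criteria are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochSet, window_indices
from .errors import ChannelError, ConfigurationError, DataError


@dataclass(frozen=True)
class RejectionCriteria:
    """Thresholds (uV) and window geometry (ms) of the four criteria."""

    p2p_window: float = 200.0
    p2p_step: float = 50.0
    p2p_threshold: float = 150.0
    abs_threshold: float = 100.0
    heog_step_window: float = 400.0
    heog_step_step: float = 10.0
    heog_step_threshold: float = 40.0
    veog_window: float = 200.0
    veog_step: float = 10.0
    veog_threshold: float = 50.0
    veog_scan_interval: tuple[float, float] = (-200.0, 200.0)

    def __post_init__(self) -> None:
        for name in ("p2p_threshold", "abs_threshold", "heog_step_threshold",
                     "veog_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


def _window_starts(n_samples: int, wlen: int, step: int) -> np.ndarray:
    if wlen > n_samples:
        raise ConfigurationError("window longer than epoch")
    if step < 1 or wlen < 2:
        raise ConfigurationError("window/step must cover at least one sample pair")
    return np.arange(0, n_samples - wlen + 1, step)


def _ms_to_samp(ms: float, sfreq: float) -> int:
    return max(int(round(ms * sfreq / 1000.0)), 1)


def moving_p2p_reject(epochs: EpochSet, window_ms: float = 200.0,
                      step_ms: float = 50.0, threshold: float = 150.0,
                      channels: list[str] | None = None,
                      sample_range: np.ndarray | None = None) -> np.ndarray:
    """Flag trials whose max-minus-min exceeds ``threshold`` in any window.

    Returns a boolean vector, one entry per trial.  ``channels`` defaults
    to all EEG channels; ``sample_range`` optionally restricts the scanned
    samples (used by the blink criterion).
    """
    labels = channels if channels is not None else epochs.eeg_channels()
    idx = [epochs.channel_index(lb) for lb in labels]
    data = epochs.data[:, idx, :]
    if sample_range is not None:
        data = data[:, :, sample_range]
    wlen = _ms_to_samp(window_ms, epochs.sfreq)
    step = _ms_to_samp(step_ms, epochs.sfreq)
    starts = _window_starts(data.shape[-1], wlen, step)
    flagged = np.zeros(epochs.n_trials, dtype=bool)
    for s in starts:
        seg = data[:, :, s:s + wlen]
        p2p = seg.max(axis=-1) - seg.min(axis=-1)
        flagged |= (p2p > threshold).any(axis=1)
    return flagged


def abs_threshold_reject(epochs: EpochSet, threshold: float = 100.0,
                         channels: list[str] | None = None) -> np.ndarray:
    """Flag trials with any |sample| above ``threshold`` on any EEG channel."""
    labels = channels if channels is not None else epochs.eeg_channels()
    idx = [epochs.channel_index(lb) for lb in labels]
    return (np.abs(epochs.data[:, idx, :]) > threshold).any(axis=(1, 2))


def heog_step_reject(epochs: EpochSet, window_ms: float = 400.0,
                     step_ms: float = 10.0, threshold: float = 40.0,
                     channel: str = "HEOG") -> np.ndarray:
    """Step-function criterion on the HEOG trace.

    For every full window, the absolute difference between the mean of the
    second half and the mean of the first half is compared to the
    threshold; any exceedance flags the trial.
    """
    if channel not in epochs.channels:
        raise ChannelError(f"HEOG channel {channel!r} missing")
    trace = epochs.data[:, epochs.channel_index(channel), :]
    wlen = _ms_to_samp(window_ms, epochs.sfreq)
    wlen -= wlen % 2  # two equal halves
    step = _ms_to_samp(step_ms, epochs.sfreq)
    starts = _window_starts(trace.shape[-1], wlen, step)
    half = wlen // 2
    flagged = np.zeros(epochs.n_trials, dtype=bool)
    for s in starts:
        first = trace[:, s:s + half].mean(axis=-1)
        second = trace[:, s + half:s + wlen].mean(axis=-1)
        flagged |= np.abs(second - first) > threshold
    return flagged


def veog_blink_reject(epochs: EpochSet, window_ms: float = 200.0,
                      step_ms: float = 10.0, threshold: float = 50.0,
                      scan_interval: tuple[float, float] = (-200.0, 200.0),
                      channel: str = "VEOG") -> np.ndarray:
    """Moving-window peak-to-peak on VEOG, restricted to the stimulus period."""
    if channel not in epochs.channels:
        raise ChannelError(f"VEOG channel {channel!r} missing")
    rng = window_indices(epochs.times, scan_interval[0], scan_interval[1],
                         inclusive=True)
    return moving_p2p_reject(epochs, window_ms=window_ms, step_ms=step_ms,
                             threshold=threshold, channels=[channel],
                             sample_range=rng)


@dataclass
class RejectionReport:
    """Per-trial flags per criterion plus per-condition rejection rates."""

    flags: pd.DataFrame  # one boolean column per criterion + "rejected"
    rates: dict[str, float]  # condition -> % rejected
    retained: np.ndarray = field(repr=False)  # indices of kept trials

    def to_csv(self, path) -> None:
        self.flags.to_csv(path, index_label="trial")

    def summary(self) -> dict:
        return {"rates_percent": self.rates,
                "n_rejected": int(self.flags["rejected"].sum()),
                "n_retained": int(len(self.retained))}


def screen_epochs(epochs: EpochSet,
                  criteria: RejectionCriteria = RejectionCriteria()) -> RejectionReport:
    """Apply all four criteria; the rejection mask is their union.

    Criteria 3-4 silently pass when the corresponding EOG channel is not
    in the montage (e.g. on EEG-only fixtures).
    """
    c = criteria
    cols: dict[str, np.ndarray] = {}
    cols["p2p"] = moving_p2p_reject(epochs, c.p2p_window, c.p2p_step, c.p2p_threshold)
    cols["abs"] = abs_threshold_reject(epochs, c.abs_threshold)
    if "HEOG" in epochs.channels:
        cols["heog_step"] = heog_step_reject(
            epochs, c.heog_step_window, c.heog_step_step, c.heog_step_threshold)
    else:
        cols["heog_step"] = np.zeros(epochs.n_trials, dtype=bool)
    if "VEOG" in epochs.channels:
        cols["veog_blink"] = veog_blink_reject(
            epochs, c.veog_window, c.veog_step, c.veog_threshold,
            c.veog_scan_interval)
    else:
        cols["veog_blink"] = np.zeros(epochs.n_trials, dtype=bool)
    flags = pd.DataFrame(cols)
    flags["rejected"] = flags.any(axis=1)
    rejected = flags["rejected"].to_numpy()
    rates = {}
    for cond in np.unique(epochs.condition):
        sel = epochs.condition == cond
        rates[str(cond)] = float(100.0 * rejected[sel].mean())
    return RejectionReport(flags=flags, rates=rates,
                           retained=np.flatnonzero(~rejected))


def heog_residual_report(cue_epochs: list[EpochSet] | EpochSet,
                         interval: tuple[float, float] = (0.0, 1200.0),
                         uv_per_degree: float = 16.0,
                         conditions: tuple[str, str] = ("cue_left", "cue_right"),
                         channel: str = "HEOG") -> dict:
    """Grand-average HEOG difference (cue left minus cue right) in ``interval``.

    A residual-gaze check on screened data: near-zero values indicate that
    systematic eye movements do not differ between cue conditions.  The
    degree conversion uses a configurable uV-per-degree factor (default 16,
    a conventional HEOG propagation figure; treat it as an assumption).
    """
    if isinstance(cue_epochs, EpochSet):
        cue_epochs = [cue_epochs]
    diffs = []
    for ep in cue_epochs:
        if channel not in ep.channels:
            raise ChannelError(f"HEOG channel {channel!r} missing")
        idx = window_indices(ep.times, interval[0], interval[1])
        trace = ep.data[:, ep.channel_index(channel), :][:, idx]
        means = []
        for cond in conditions:
            sel = ep.condition == cond
            if not sel.any():
                raise DataError(f"condition {cond!r} has no trials")
            means.append(trace[sel].mean())
        diffs.append(means[0] - means[1])
    mean_uv = float(np.mean(diffs))
    return {"difference_uv": mean_uv,
            "difference_deg": mean_uv / uv_per_degree,
            "per_subject_uv": [float(d) for d in diffs]}
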