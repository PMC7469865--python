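"""Univariate ERP measures.

Condition averages, difference waves, and the target-locked N1 attention
modulation: mean voltage 170-210 ms post-target over the posterior region
of interest contralateral to the target, compared between cued and uncued
targets.  The modulation (cued minus uncued, negative sign preserved) is
the per-subject scalar the linkage analyses correlate with decoding
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet, window_indices
from .errors import ChannelError, DataError

#: Posterior ROI variants; the 3-channel pair suits ~30-channel montages,
#: the 7-channel pair denser (~60-channel) montages.
N1_ROIS = {
    "3ch": {"left": ["P3", "P7", "O1"], "right": ["P4", "P8", "O2"]},
    "7ch": {"left": ["P1", "P3", "P5", "P7", "PO3", "PO7", "O1"],
            "right": ["P2", "P4", "P6", "P8", "PO4", "PO8", "O2"]},
}


def default_roi(channels: list[str]) -> dict[str, list[str]]:
    """Pick the densest ROI variant fully contained in the montage."""
    for key in ("7ch", "3ch"):
        roi = N1_ROIS[key]
        if set(roi["left"]) | set(roi["right"]) <= set(channels):
            return roi
    raise ChannelError("montage contains no complete posterior ROI pair")


@dataclass
class ErpSet:
    """Condition-averaged waveforms (channels x samples, uV)."""

    waveforms: np.ndarray
    times: np.ndarray
    channels: list[str]
    condition: str
    n_trials: int

    def to_frame(self, subject_id: str = "") -> pd.DataFrame:
        """Long-format table: subject, condition, channel, time, voltage."""
        n_ch, n_t = self.waveforms.shape
        return pd.DataFrame({
            "subject": subject_id,
            "condition": self.condition,
            "channel": np.repeat(self.channels, n_t),
            "time_ms": np.tile(self.times, n_ch),
            "value_uv": self.waveforms.ravel()})


def average_condition(epochs: EpochSet, condition: str) -> ErpSet:
    """Arithmetic mean across the trials of one condition."""
    sel = epochs.trials_of(condition)
    if sel.size == 0:
        raise DataError(f"condition {condition!r} has no trials")
    return ErpSet(waveforms=epochs.data[sel].mean(axis=0), times=epochs.times,
                  channels=list(epochs.channels), condition=condition,
                  n_trials=int(sel.size))


def difference_wave(erp_a: ErpSet, erp_b: ErpSet) -> np.ndarray:
    """Elementwise a minus b (channels x samples)."""
    if erp_a.waveforms.shape != erp_b.waveforms.shape:
        raise DataError("difference requires matching shapes")
    return erp_a.waveforms - erp_b.waveforms


@dataclass
class N1Measure:
    """Mean-amplitude N1 per attention condition and their difference."""

    amplitude_cued: float
    amplitude_uncued: float
    modulation: float  # cued - uncued, uV, sign preserved
    roi: dict[str, list[str]]
    window: tuple[float, float]

    def to_frame(self, subject_id: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {"subject": subject_id,
             "condition": ["cued", "uncued", "modulation"],
             "value_uv": [self.amplitude_cued, self.amplitude_uncued,
                          self.modulation]})


def measure_n1(target_epochs: EpochSet, roi: dict[str, list[str]] | None = None,
               window: tuple[float, float] = (170.0, 210.0)) -> N1Measure:
    """N1 mean amplitude over the contralateral ROI, per attention condition.

    Uses the raw (uncollapsed) per-trial labels in ``trial_info``
    (``cue_side``, ``target_side``).  For each target side, trials are
    averaged per attention condition (cued: cue side equals target side),
    the mean is taken over the ROI contralateral to the target (left-ROI
    for right targets and vice versa) within the window (endpoints
    inclusive on the sample grid), and the two sides are then averaged with
    equal weight.  Modulation is cued minus uncued.
    """
    info = target_epochs.trial_info
    if info is None or not {"cue_side", "target_side"} <= set(info.columns):
        raise DataError("measure_n1 requires trial_info with cue_side and target_side")
    roi = roi if roi is not None else default_roi(target_epochs.channels)
    for side in ("left", "right"):
        for lb in roi[side]:
            if lb not in target_epochs.channels:
                raise ChannelError(f"ROI channel {lb!r} missing")
    t_idx = window_indices(target_epochs.times, window[0], window[1], inclusive=True)
    target_side = info["target_side"].to_numpy()
    cued = target_side == info["cue_side"].to_numpy()
    contra = {"left": "right", "right": "left"}
    amps: dict[bool, list[float]] = {True: [], False: []}
    for side in ("left", "right"):
        ch_idx = [target_epochs.channel_index(lb) for lb in roi[contra[side]]]
        for is_cued in (True, False):
            sel = (target_side == side) & (cued == is_cued)
            if not sel.any():
                raise DataError(f"no {'cued' if is_cued else 'uncued'} {side}-target trials")
            seg = target_epochs.data[np.flatnonzero(sel)][:, ch_idx][:, :, t_idx]
            amps[is_cued].append(float(seg.mean()))
    a_cued = float(np.mean(amps[True]))
    a_uncued = float(np.mean(amps[False]))
    return N1Measure(amplitude_cued=a_cued, amplitude_uncued=a_uncued,
                     modulation=a_cued - a_uncued, roi=roi, window=window)
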