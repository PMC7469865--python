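"""Deterministic signal conditioning.

Filter chain for continuous data (0.1-40 Hz Butterworth band-pass applied
forward-backward, equiripple 50 Hz notch), the epoch-level 8 Hz two-way
least-squares FIR low-pass used before decoding, epoch trimming with 50 Hz
downsampling, baseline correction, condition collapsing, linear
re-referencing, and alpha (8-13 Hz) power features for the control
decoding.

All filters are zero-phase (applied forward then backward), so symmetric
transients keep their peak latency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .containers import EpochSet, window_indices
from .errors import ConfigurationError, DataError, FilterError


@dataclass(frozen=True)
class FilterSpec:
    """Specification of one filter in the chain.

    ``kind`` is one of ``butterworth_bandpass``, ``pm_notch`` (equiripple
    band-stop), ``ls_fir_lowpass``.  For the FIR low-pass the order follows
    the rule ``order = 3 * floor(sfreq / cutoff)`` (93 taps of order at
    250 Hz / 8 Hz).  All filters are applied forward-backward (zero phase).
    """

    kind: str
    low: float | None = None
    high: float | None = None
    order: int | None = None
    zero_phase: bool = True


def fir_lowpass_order(sfreq: float, cutoff: float) -> int:
    """Order rule of the two-way least-squares FIR low-pass: 3*floor(sfreq/cutoff)."""
    if cutoff <= 0 or cutoff >= sfreq / 2:
        raise ConfigurationError("cutoff must lie in (0, sfreq/2)")
    return 3 * int(np.floor(sfreq / cutoff))


def _check_band(sfreq: float, *edges: float) -> None:
    ny = sfreq / 2.0
    for e in edges:
        if not 0 < e < ny:
            raise ConfigurationError(f"band edge {e} Hz outside (0, {ny}) Hz")


def bandpass_continuous(data: np.ndarray, sfreq: float,
                        low: float = 0.1, high: float = 40.0,
                        order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass on continuous data (last axis = time).

    ``order=2`` gives a 12 dB/oct roll-off per pass direction; the
    forward-backward application doubles the effective order and removes
    the phase shift.
    """
    _check_band(sfreq, low, high)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=sfreq, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def design_notch(sfreq: float, freq: float = 50.0, width: float = 2.0,
                 trans: float = 2.0, numtaps: int | None = None) -> np.ndarray:
    """Equiripple (Parks-McClellan) FIR band-stop coefficients around ``freq``.

    The stopband spans ``freq +/- width/2`` (49-51 Hz by default) with a
    ``trans`` Hz transition on either side.
    """
    _check_band(sfreq, freq)
    ny = sfreq / 2.0
    lo, hi = freq - width / 2.0, freq + width / 2.0
    if lo - trans <= 0 or hi + trans >= ny:
        raise ConfigurationError("notch band plus transition exceeds (0, Nyquist)")
    if numtaps is None:
        numtaps = 2 * int(sfreq) + 1
    if numtaps % 2 == 0:
        numtaps += 1
    bands = [0.0, lo - trans, lo, hi, hi + trans, ny]
    return signal.remez(numtaps, bands, [1.0, 0.0, 1.0], fs=sfreq)


def notch_continuous(data: np.ndarray, sfreq: float, freq: float = 50.0,
                     width: float = 2.0, trans: float = 2.0,
                     numtaps: int | None = None) -> np.ndarray:
    """Zero-phase equiripple notch at ``freq`` Hz on continuous data."""
    taps = design_notch(sfreq, freq, width, trans, numtaps)
    data = np.asarray(data, dtype=float)
    padlen = 3 * len(taps)
    if data.shape[-1] <= padlen:
        raise FilterError(
            f"signal length {data.shape[-1]} too short for {len(taps)}-tap notch")
    return signal.filtfilt(taps, [1.0], data, axis=-1)


def _firls_lowpass(sfreq: float, cutoff: float, order: int,
                   trans_frac: float = 0.15) -> np.ndarray:
    numtaps = order + 1
    if numtaps % 2 == 0:  # scipy firls needs an odd tap count (type-I FIR)
        numtaps += 1
    ny = sfreq / 2.0
    edge = min(cutoff * (1.0 + trans_frac), 0.99 * ny)
    # mild passband emphasis keeps the passband flat despite the wide
    # stopband dominating the least-squares objective; unity gain at DC
    taps = signal.firls(numtaps, [0.0, cutoff, edge, ny], [1, 1, 0, 0],
                        weight=[5.0, 1.0], fs=sfreq)
    return taps / taps.sum()


def lowpass_epochs(epochs: EpochSet, cutoff: float = 8.0,
                   trans_frac: float = 0.15) -> EpochSet:
    """Two-way least-squares FIR low-pass applied to epoched data.

    The order follows ``3 * floor(sfreq / cutoff)`` and the filter is run
    forward-backward.  Applied before trial averaging and decoding so the
    decoded patterns reflect slow event-related activity rather than alpha.
    """
    order = fir_lowpass_order(epochs.sfreq, cutoff)
    if epochs.n_samples <= 3 * order:
        raise FilterError(
            f"epochs of {epochs.n_samples} samples too short for FIR order {order}")
    taps = _firls_lowpass(epochs.sfreq, cutoff, order, trans_frac)
    out = signal.filtfilt(taps, [1.0], epochs.data, axis=-1, padlen=3 * order)
    return replace(epochs, data=out)


def trim_and_downsample(epochs: EpochSet, trim_ms: float = 200.0,
                        target_sfreq: float = 50.0) -> EpochSet:
    """Drop ``trim_ms`` from both epoch ends, then decimate to ``target_sfreq``.

    Downsampling keeps every k-th sample (k = sfreq/target_sfreq, an
    integer), starting from the first retained sample; the preceding 8 Hz
    low-pass acts as the anti-alias step for voltage features.  The
    standard windows come out at 100 cue-locked points (-800..1180 ms) and
    55 target-locked points (-300..780 ms).
    """
    if trim_ms < 0:
        raise ConfigurationError("trim_ms must be nonnegative")
    ratio = epochs.sfreq / target_sfreq
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ConfigurationError(
            f"sfreq {epochs.sfreq} not an integer multiple of target {target_sfreq}")
    decim = int(round(ratio))
    n_trim = int(round(trim_ms * epochs.sfreq / 1000.0))
    if 2 * n_trim >= epochs.n_samples:
        raise ConfigurationError("trim exceeds epoch length")
    keep = np.arange(n_trim, epochs.n_samples - n_trim)[::decim]
    return epochs.select_samples(keep, sfreq=target_sfreq)


def baseline_correct(epochs: EpochSet, window: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract per trial/channel the mean over ``[window)`` from every sample."""
    idx = window_indices(epochs.times, window[0], window[1])
    base = epochs.data[:, :, idx].mean(axis=-1, keepdims=True)
    return replace(epochs, data=epochs.data - base)


def rereference(epochs: EpochSet, ref_labels: tuple[str, str] = ("TP9", "TP10")) -> EpochSet:
    """Linear re-reference of EEG channels to the mean of ``ref_labels``.

    EOG derivations are bipolar already and are left untouched.
    """
    ref_idx = [epochs.channel_index(lb) for lb in ref_labels]
    ref = epochs.data[:, ref_idx, :].mean(axis=1, keepdims=True)
    out = epochs.data.copy()
    eeg_idx = [i for i, c in enumerate(epochs.channels) if c in epochs.eeg_channels()]
    out[:, eeg_idx, :] -= ref
    return replace(epochs, data=out)


def collapse_target_conditions(epochs: EpochSet) -> EpochSet:
    """Relabel target trials as cued/uncued, collapsing left and right.

    A target preceded by a same-side cue becomes ``cued_target``; an
    opposite-side one becomes ``uncued_target``.  Trial counts are
    conserved.
    """
    info = epochs.trial_info
    if info is None or not {"cue_side", "target_side"} <= set(info.columns):
        raise DataError("collapse requires trial_info with cue_side and target_side")
    cued = info["cue_side"].to_numpy() == info["target_side"].to_numpy()
    condition = np.where(cued, "cued_target", "uncued_target").astype(object)
    return replace(epochs, condition=condition)


def alpha_power_features(epochs: EpochSet, band: tuple[float, float] = (8.0, 13.0),
                         trim_ms: float = 200.0, target_sfreq: float = 50.0,
                         antialias_hz: float = 20.0) -> EpochSet:
    """Band-limited power envelope features (control decoding).

    Per trial/channel: band-pass to ``band``, squared analytic amplitude
    (Hilbert), an explicit ``antialias_hz`` low-pass (the envelope carries
    content above 8 Hz by design), then the same trim/downsample as the
    voltage features.  Output is clipped at zero (power is nonnegative;
    the smoothing low-pass can undershoot slightly).
    """
    _check_band(epochs.sfreq, *band)
    sos = signal.butter(4, list(band), btype="bandpass", fs=epochs.sfreq, output="sos")
    narrow = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    power = np.abs(signal.hilbert(narrow, axis=-1)) ** 2
    sos_lp = signal.butter(4, antialias_hz, btype="lowpass", fs=epochs.sfreq, output="sos")
    power = np.clip(signal.sosfiltfilt(sos_lp, power, axis=-1), 0.0, None)
    out = replace(epochs, data=power)
    return trim_and_downsample(out, trim_ms=trim_ms, target_sfreq=target_sfreq)
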