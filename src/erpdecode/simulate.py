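"""Synthetic cued-attention EEG cohorts with ground truth.

The generator emulates the statistical structure a cued visual spatial
attention experiment gives the analysis:

* cue-locked epochs carrying a lateralized slow component that ramps up
  from a subject-specific onset and mirrors its polarity across
  hemispheric channel pairs for cue-left vs cue-right;
* target-locked epochs with a contralateral posterior N1 (negative peak
  near 190 ms) whose amplitude is more negative for cued than uncued
  targets by a planted, subject-specific modulation;
* 1/f ("pink") background noise spatially mixed by a random orthonormal
  matrix per subject, plus narrowband alpha (8-13 Hz) activity;
* per-trial reaction times coupled to the subject's planted target effect;
* optional frontal eye-movement leakage for the F7/F8 confound check.

Subject effect amplitudes are drawn log-normal (positive, right-skewed) to
create the between-subject heterogeneity the linkage correlations need.
All randomness flows from one seeded generator per cohort, with
per-subject substreams derived deterministically, so identical seed and
config give bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet, times_for_window, window_indices
from .erp import default_roi
from .errors import ChannelError, ConfigurationError

__all__ = [
    "SimulationConfig", "SimulationGroundTruth", "standard_montage",
    "generate_subject", "generate_cohort", "inject_eog",
    "instructional_config", "probabilistic_config",
]

# 10-20 montage label pools.  The 30-channel set mirrors a 32-electrode
# cap minus the mastoid references; the 60-channel set a 65-electrode cap
# minus ground/reference/mastoids and the extra ocular site.
_MONTAGE_30 = [
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz", "FC1", "FC2", "FC5", "FC6",
    "FCz", "C3", "C4", "Cz", "T7", "T8", "CP1", "CP2", "CP5", "CP6",
    "P3", "P4", "P7", "P8", "Pz", "O1", "O2", "Oz", "POz",
]
_MONTAGE_60 = [
    "Fp1", "Fp2", "Fpz", "AF3", "AF4", "AF7", "AF8",
    "F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8", "Fz",
    "FC1", "FC2", "FC3", "FC4", "FC5", "FC6", "FT7", "FT8", "FCz",
    "C1", "C2", "C3", "C4", "C5", "C6", "Cz", "T7", "T8",
    "CP1", "CP2", "CP3", "CP4", "CP5", "CP6", "CPz", "TP7", "TP8",
    "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8", "Pz",
    "PO3", "PO4", "PO7", "PO8", "POz", "O1", "O2", "Oz",
]

_ROW_Y = {"FP": 0.95, "AF": 0.75, "F": 0.55, "FT": 0.3, "FC": 0.3,
          "T": 0.0, "C": 0.0, "TP": -0.3, "CP": -0.3, "P": -0.6,
          "PO": -0.8, "O": -0.95}
_COL_X = {1: 0.2, 2: 0.2, 3: 0.45, 4: 0.45, 5: 0.7, 6: 0.7,
          7: 0.9, 8: 0.9, 9: 1.0, 10: 1.0}


def standard_montage(n_channels: int = 30) -> list[str]:
    """First ``n_channels`` labels of the closest standard montage."""
    pool = _MONTAGE_30 if n_channels <= 30 else _MONTAGE_60
    if n_channels > len(pool):
        raise ConfigurationError(f"at most {len(pool)} channels supported")
    return pool[:n_channels]


def label_position(label: str) -> tuple[float, float]:
    """Approximate 2D scalp position of a 10-20 label.

    x runs left (-1) to right (+1), y posterior (-1) to anterior (+1).
    Accurate enough for smooth Gaussian topography templates; not a
    measured electrode geometry.
    """
    row = "".join(ch for ch in label if ch.isalpha() and ch != "z").upper()
    if label.lower().endswith("z"):
        return 0.0, _ROW_Y[row]
    digits = "".join(ch for ch in label if ch.isdigit())
    num = int(digits)
    x = _COL_X[num]
    if num % 2 == 1:
        x = -x
    return x, _ROW_Y[row]


def _gauss_bump(positions: np.ndarray, center: tuple[float, float],
                sigma: float = 0.45) -> np.ndarray:
    d2 = ((positions - np.asarray(center)) ** 2).sum(axis=1)
    return np.exp(-d2 / (2 * sigma ** 2))


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generator settings (the study conditions).

    Defaults emulate an instructional-cueing-style cohort: 250 Hz
    sampling, cue epochs -1000..1400 ms, target epochs -500..1000 ms,
    240 trials per condition, a lateralized cue component ramping up from
    80 ms with a 1.2 uV population-mean amplitude, and pink + alpha
    background noise.  ``n1_coupling`` links a subject's cue-effect
    amplitude to the planted N1 attention modulation; ``rt_coupling`` (ms
    per uV) links the target effect to reaction time.
    """

    n_subjects: int = 30
    n_channels: int = 30
    sfreq: float = 250.0
    cue_epoch_window: tuple[float, float] = (-1000.0, 1400.0)
    target_epoch_window: tuple[float, float] = (-500.0, 1000.0)
    n_trials_per_condition: int = 240
    effect_onset_ms: float = 80.0
    effect_amplitude_uv: float = 1.2
    n1_coupling: float = 0.6
    rt_coupling: float = 40.0
    noise_alpha_power: float = 4.0
    noise_pink_exponent: float = 1.0
    eog_leak: float = 0.0
    seed: int = 0
    paradigm: str = "instructional"  # or "probabilistic"
    # secondary shape parameters
    noise_pink_rms_uv: float = 8.0
    effect_rise_ms: float = 150.0
    onset_sd_ms: float = 10.0
    amplitude_lognorm_sigma: float = 0.4
    n1_base_uv: float = -3.5
    n1_noise_uv: float = 0.3
    n1_peak_ms: float = 190.0
    n1_width_ms: float = 20.0
    rt_baseline_ms: float = 500.0
    rt_trial_sd_ms: float = 80.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_channels < 1 or self.n_trials_per_condition < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.sfreq <= 0:
            raise ConfigurationError("sfreq must be positive")
        for w in (self.cue_epoch_window, self.target_epoch_window):
            if w[0] >= w[1]:
                raise ConfigurationError(f"window {w} must have start < end")
        if self.paradigm not in ("instructional", "probabilistic"):
            raise ConfigurationError(f"unknown paradigm {self.paradigm!r}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def instructional_config(**overrides) -> SimulationConfig:
    """Instructional-like cohort: early (80 ms) and strong lateralized effect."""
    kw = dict(n_subjects=30, effect_onset_ms=80.0, effect_amplitude_uv=1.2,
              paradigm="instructional")
    kw.update(overrides)
    return SimulationConfig(**kw)


def probabilistic_config(**overrides) -> SimulationConfig:
    """Probabilistic-like cohort: later (160 ms) and weaker lateralized effect."""
    kw = dict(n_subjects=26, effect_onset_ms=160.0, effect_amplitude_uv=0.9,
              paradigm="probabilistic")
    kw.update(overrides)
    return SimulationConfig(**kw)


@dataclass
class SimulationGroundTruth:
    """Planted per-subject parameters; one row per generated subject."""

    table: pd.DataFrame
    config: SimulationConfig

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# component templates
# ---------------------------------------------------------------------------

def _positions(channels: list[str]) -> np.ndarray:
    return np.array([label_position(c) for c in channels])


def cue_template(channels: list[str]) -> np.ndarray:
    """Hemisphere-antisymmetric topography of the cue-locked slow component.

    Posterior and frontal Gaussian bumps, sign-flipped across the midline
    (a frontally-posteriorly lateralized distribution); normalized to unit
    maximum so amplitudes are in uV at the template peak.
    """
    pos = _positions(channels)
    t = (_gauss_bump(pos, (-0.6, -0.7)) - _gauss_bump(pos, (0.6, -0.7))
         + 0.6 * (_gauss_bump(pos, (-0.5, 0.5)) - _gauss_bump(pos, (0.5, 0.5))))
    return t / np.abs(t).max()


def n1_template(channels: list[str], hemisphere: str) -> np.ndarray:
    """Posterior unilateral topography of the target-locked N1 (unit max)."""
    pos = _positions(channels)
    x = -0.65 if hemisphere == "left" else 0.65
    t = _gauss_bump(pos, (x, -0.75), sigma=0.4)
    return t / np.abs(t).max()


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
                exponent: float, sfreq: float) -> np.ndarray:
    """1/f^exponent noise along the last axis, unit variance."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal(shape + (len(freqs),))
            + 1j * rng.standard_normal(shape + (len(freqs),))) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _alpha_noise(rng: np.random.Generator, shape: tuple[int, ...],
                 times_s: np.ndarray, power_uv2: float) -> np.ndarray:
    """Random-phase 8-13 Hz oscillation with variance ``power_uv2`` per channel."""
    if power_uv2 <= 0:
        return np.zeros(shape + (len(times_s),))
    f = rng.uniform(8.0, 13.0, size=shape + (1,))
    phi = rng.uniform(0, 2 * np.pi, size=shape + (1,))
    amp = np.sqrt(2.0 * power_uv2)
    return amp * np.cos(2 * np.pi * f * times_s + phi)


def _background(rng: np.random.Generator, n_trials: int, n_ch: int,
                times_ms: np.ndarray, cfg: SimulationConfig,
                mixing: np.ndarray) -> np.ndarray:
    pink = cfg.noise_pink_rms_uv * _pink_noise(
        rng, (n_trials, n_ch), len(times_ms), cfg.noise_pink_exponent, cfg.sfreq)
    alpha = _alpha_noise(rng, (n_trials, n_ch), times_ms[None, None, :] / 1000.0,
                         cfg.noise_alpha_power)
    # spatial mixing gives the channels a realistic covariance structure
    return np.einsum("ij,tjs->tis", mixing, pink + alpha)


def _random_orthonormal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


# ---------------------------------------------------------------------------
# subject-level generation
# ---------------------------------------------------------------------------

def _draw_subject_params(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    if cfg.effect_amplitude_uv > 0:
        sigma = cfg.amplitude_lognorm_sigma
        mu = np.log(cfg.effect_amplitude_uv) - sigma ** 2 / 2.0
        amp = float(rng.lognormal(mu, sigma))
    else:
        amp = 0.0
    onset = float(cfg.effect_onset_ms + rng.normal(0.0, cfg.onset_sd_ms))
    n1_mod = float(-(cfg.n1_coupling * amp) + rng.normal(0.0, cfg.n1_noise_uv))
    if cfg.effect_amplitude_uv == 0:
        n1_mod = 0.0
    target_effect = -n1_mod  # positive magnitude of the planted modulation
    return {"effect_amplitude_uv": amp, "effect_onset_ms": onset,
            "n1_modulation_uv": n1_mod, "target_effect_uv": target_effect}


def _subject_rng(cfg: SimulationConfig, subject_index: int) -> np.random.Generator:
    root = np.random.SeedSequence(cfg.seed)
    return np.random.default_rng(root.spawn(cfg.n_subjects)[subject_index])


def generate_subject(cfg: SimulationConfig, subject_index: int
                     ) -> tuple[EpochSet, EpochSet, dict]:
    """One subject's cue-locked and target-locked epochs plus ground truth.

    The returned epochs include bipolar ``HEOG``/``VEOG`` channels (pure
    noise unless ``eog_leak`` > 0, in which case a condition-locked gaze
    drift contaminates HEOG and leaks into F7/F8).
    """
    if not 0 <= subject_index < cfg.n_subjects:
        raise ConfigurationError("subject_index out of range")
    rng = _subject_rng(cfg, subject_index)
    params = _draw_subject_params(cfg, rng)
    channels = standard_montage(cfg.n_channels)
    n_ch = len(channels)
    mixing = _random_orthonormal(rng, n_ch)
    subject_id = f"S{subject_index:02d}"

    # ---- cue-locked epochs -------------------------------------------
    t_cue = times_for_window(*cfg.cue_epoch_window, cfg.sfreq)
    n_per = cfg.n_trials_per_condition
    cue_side = np.array(["left"] * n_per + ["right"] * n_per, dtype=object)
    cue_condition = np.array(["cue_left"] * n_per + ["cue_right"] * n_per,
                             dtype=object)
    data = _background(rng, 2 * n_per, n_ch, t_cue, cfg, mixing)
    if params["effect_amplitude_uv"] > 0:
        ramp = np.clip((t_cue - params["effect_onset_ms"]) / cfg.effect_rise_ms,
                       0.0, 1.0)
        topo = cue_template(channels)
        signal = 0.5 * params["effect_amplitude_uv"] * topo[:, None] * ramp[None, :]
        data[:n_per] += signal
        data[n_per:] -= signal
    cue_epochs = _with_eog(data, t_cue, cue_condition, cfg, rng, channels,
                           subject_id, "cue", pd.DataFrame({"cue_side": cue_side}))

    # ---- target-locked epochs ----------------------------------------
    t_tgt = times_for_window(*cfg.target_epoch_window, cfg.sfreq)
    n_trials = 2 * n_per
    cued = np.repeat([True, False], n_per)
    target_side = np.where(rng.random(n_trials) < 0.5, "left", "right").astype(object)
    tgt_cue_side = np.where(
        cued, target_side,
        np.where(target_side == "left", "right", "left")).astype(object)
    data = _background(rng, n_trials, n_ch, t_tgt, cfg, mixing)
    wave = -np.exp(-0.5 * ((t_tgt - cfg.n1_peak_ms) / cfg.n1_width_ms) ** 2)
    contra = {"left": "right", "right": "left"}
    # calibrate the spatiotemporal kernel so the ROI/window mean-amplitude
    # measurement recovers the planted values in uV exactly (in expectation)
    roi = default_roi(channels)
    w_idx = window_indices(t_tgt, 170.0, 210.0, inclusive=True)
    for side in ("left", "right"):
        topo = n1_template(channels, contra[side])
        kernel = topo[:, None] * wave[None, :]
        ch_idx = [channels.index(lb) for lb in roi[contra[side]]]
        calib = kernel[np.ix_(ch_idx, w_idx)].mean()  # negative
        sel = target_side == side
        base = np.abs(cfg.n1_base_uv)
        amp = (base + np.where(cued[sel], params["target_effect_uv"], 0.0)) / (-calib)
        data[np.flatnonzero(sel)] += amp[:, None, None] * kernel[None, :, :]

    # ---- behavior -----------------------------------------------------
    rt = np.full(n_trials, np.nan)
    correct = np.ones(n_trials, dtype=bool)
    if cfg.paradigm == "instructional":
        # responses only to cued targets; faster with stronger selection
        mean_rt = cfg.rt_baseline_ms - cfg.rt_coupling * params["target_effect_uv"]
        rt[cued] = mean_rt + rng.normal(0.0, cfg.rt_trial_sd_ms, size=cued.sum())
        validity = None
    else:
        # valid and invalid targets both answered; the validity cost grows
        # with the strength of attentional selection
        rt_valid = cfg.rt_baseline_ms
        rt_invalid = cfg.rt_baseline_ms + cfg.rt_coupling * params["target_effect_uv"]
        rt[cued] = rt_valid + rng.normal(0.0, cfg.rt_trial_sd_ms, size=cued.sum())
        rt[~cued] = rt_invalid + rng.normal(0.0, cfg.rt_trial_sd_ms, size=(~cued).sum())
        validity = np.where(cued, "valid", "invalid").astype(object)
    rt = np.clip(rt, 150.0, None)

    info = pd.DataFrame({"cue_side": tgt_cue_side, "target_side": target_side,
                         "rt": rt, "correct": correct})
    if validity is not None:
        info["validity"] = validity
    condition = np.where(cued, "cued_target", "uncued_target").astype(object)
    target_epochs = _with_eog(data, t_tgt, condition, cfg, rng, channels,
                              subject_id, "target", info)

    resp = info["rt"].notna()
    truth = {
        "subject_id": subject_id, **params,
        "rt_mean_ms": float(info.loc[resp, "rt"].mean()),
        "rt_median_ms": float(info.loc[resp, "rt"].median()),
        "n1_coupling": cfg.n1_coupling, "rt_coupling": cfg.rt_coupling,
    }
    if validity is not None:
        v = info.loc[resp & (info["validity"] == "valid"), "rt"]
        iv = info.loc[resp & (info["validity"] == "invalid"), "rt"]
        truth["rt_difference_ms"] = float(iv.mean() - v.mean())
    return cue_epochs, target_epochs, truth


def _with_eog(data: np.ndarray, times: np.ndarray, condition: np.ndarray,
              cfg: SimulationConfig, rng: np.random.Generator,
              channels: list[str], subject_id: str, locking: str,
              info: pd.DataFrame) -> EpochSet:
    """Append HEOG/VEOG noise channels and assemble the EpochSet."""
    n_trials = data.shape[0]
    eog = 5.0 * _pink_noise(rng, (n_trials, 2), len(times), 1.0, cfg.sfreq)
    full = np.concatenate([data, eog], axis=1)
    ep = EpochSet(data=full, times=times, sfreq=cfg.sfreq,
                  channels=channels + ["HEOG", "VEOG"], condition=condition,
                  subject_id=subject_id, locking_event=locking, trial_info=info)
    if cfg.eog_leak > 0 and locking == "cue":
        ep = inject_eog(ep, cfg.eog_leak, condition_locked=True, rng=rng)
    return ep


def generate_cohort(cfg: SimulationConfig
                    ) -> tuple[list[tuple[EpochSet, EpochSet]], SimulationGroundTruth]:
    """All subjects of a cohort plus the ground-truth table."""
    datasets = []
    rows = []
    for si in range(cfg.n_subjects):
        cue, tgt, truth = generate_subject(cfg, si)
        datasets.append((cue, tgt))
        rows.append(truth)
    return datasets, SimulationGroundTruth(table=pd.DataFrame(rows), config=cfg)


def inject_eog(epochs: EpochSet, amplitude: float, condition_locked: bool = True,
               frontal: tuple[str, str] = ("F7", "F8"),
               onset_ms: float = 300.0, rise_ms: float = 300.0,
               heog_gain: float = 3.0,
               rng: np.random.Generator | int = 0) -> EpochSet:
    """Add a slow frontal gaze-shift artifact to existing epochs.

    A ramped deflection of ``amplitude`` uV (opposite polarity on the two
    frontal channels, amplified on HEOG when present) starting at
    ``onset_ms``.  With ``condition_locked`` the deflection's sign follows
    the condition label (mimicking residual systematic gaze toward the
    cued side); otherwise the sign is random per trial and carries no
    condition information.  ``amplitude=0`` returns an identical copy.
    """
    for lb in frontal:
        if lb not in epochs.channels:
            raise ChannelError(f"frontal channel {lb!r} missing")
    out = epochs.copy()
    if amplitude == 0:
        return out
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ramp = np.clip((epochs.times - onset_ms) / rise_ms, 0.0, 1.0)
    conds = sorted(np.unique(epochs.condition))
    if condition_locked:
        sign = np.where(epochs.condition == conds[0], 1.0, -1.0)
    else:
        sign = rng.choice([-1.0, 1.0], size=epochs.n_trials)
    deflect = amplitude * sign[:, None] * ramp[None, :]
    i7, i8 = (epochs.channel_index(lb) for lb in frontal)
    out.data[:, i7, :] += deflect
    out.data[:, i8, :] -= deflect
    if "HEOG" in epochs.channels:
        out.data[:, epochs.channel_index("HEOG"), :] += heog_gain * deflect
    return out
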