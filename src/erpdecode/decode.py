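"""Trial-averaged multivariate decoding of attention conditions.

The procedure, per subject and time point:

1. split the trials of each condition at random into ``n_groups`` (3)
   equal-sized groups, omitting remainder trials;
2. average each group into one scalp pattern (channels) at the time point
   and z-score it across channels (per class, per pattern), consuming any
   common voltage offset, e.g. slow drift shared by all channels;
3. three-fold cross-validation: train a linear SVM on the patterns of two
   groups (2 classes x 2 groups = 4 training patterns), predict the two
   held-out patterns;
4. repeat with ``n_iterations`` (20) fresh random groupings, so each time
   point's accuracy rests on 2 x 3 x 20 = 120 decoding attempts;
5. smooth the accuracy time course with a centered five-point moving
   average (+/-40 ms at 50 Hz; truncated at the series edges).

Channel contributions are reported as activation maps: the classifier
weight vector multiplied by the covariance of the training patterns
(Haufe transform), averaged over folds and iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .containers import EpochSet
from .errors import ConfigurationError, DataError

__all__ = [
    "DecoderConfig", "DecodingTimecourse", "partition_trials", "z_normalize",
    "build_patterns", "crossval_accuracy_at_time", "decode_timecourse",
    "smooth_timecourse", "channel_subset_decode",
]


@dataclass(frozen=True)
class DecoderConfig:
    """Knobs of the trial-averaged decoding procedure.

    ``C`` is the SVM regularization constant (conventional default 1).
    ``channel_subset`` restricts the features to the listed labels (used
    for the F7/F8 eye-movement proxy check).  ``feature_kind`` is
    bookkeeping only; alpha-power features are produced upstream.
    """

    n_groups: int = 3
    n_iterations: int = 20
    C: float = 1.0
    smoothing_points: int = 5
    channel_subset: tuple[str, ...] | None = None
    feature_kind: str = "voltage"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ConfigurationError("n_groups must be >= 2")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.smoothing_points % 2 != 1:
            raise ConfigurationError("smoothing_points must be odd")


@dataclass
class DecodingTimecourse:
    """Per-subject decoding accuracy over time plus activation maps."""

    times: np.ndarray
    accuracy: np.ndarray          # raw mean accuracy per time point
    smoothed: np.ndarray          # five-point moving-average accuracy
    n_attempts: int               # decoding attempts per time point
    activations: np.ndarray       # time x channels Haufe activation maps
    channels: list[str]
    subject_id: str = ""
    config: DecoderConfig = field(default_factory=DecoderConfig)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times, "accuracy": self.accuracy,
                             "smoothed": self.smoothed,
                             "subject": self.subject_id})

    def window_maps(self, windows: list[tuple[float, float]]) -> dict[tuple[float, float], np.ndarray]:
        """Activation maps averaged within each ``[start, end)`` ms window."""
        out = {}
        for w in windows:
            sel = (self.times >= w[0]) & (self.times < w[1])
            if not sel.any():
                raise ConfigurationError(f"window {w} contains no time points")
            out[w] = self.activations[sel].mean(axis=0)
        return out


def partition_trials(condition: np.ndarray, n_groups: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Random equal-sized group assignment per condition.

    Returns one integer per trial in ``0..n_groups-1``; remainder trials
    that would make the groups unequal get ``-1`` (omitted from this
    iteration).
    """
    condition = np.asarray(condition)
    assignment = np.full(condition.shape[0], -1, dtype=int)
    for cond in np.unique(condition):
        idx = np.flatnonzero(condition == cond)
        if idx.size < n_groups:
            raise DataError(
                f"condition {cond!r} has {idx.size} trials, fewer than {n_groups} groups")
        perm = rng.permutation(idx)
        size = idx.size // n_groups
        for g in range(n_groups):
            assignment[perm[g * size:(g + 1) * size]] = g
    return assignment


def z_normalize(vec: np.ndarray) -> np.ndarray:
    """Z-score across channels (sample SD, ddof=1); zero-SD maps to zeros."""
    vec = np.asarray(vec, dtype=float)
    sd = vec.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("constant channel vector: z-normalization yields zeros",
                      RuntimeWarning, stacklevel=2)
        return np.zeros_like(vec)
    return (vec - vec.mean()) / sd


def build_patterns(epochs: EpochSet, assignment: np.ndarray,
                   time_index: int) -> np.ndarray:
    """Group-averaged, channel-z-scored patterns at one time point.

    Returns ``(n_conditions, n_groups, n_channels)`` with conditions in
    sorted label order.
    """
    conds = sorted(np.unique(epochs.condition))
    n_groups = int(assignment.max()) + 1
    out = np.empty((len(conds), n_groups, epochs.n_channels))
    for ci, cond in enumerate(conds):
        for g in range(n_groups):
            sel = (epochs.condition == cond) & (assignment == g)
            if not sel.any():
                raise DataError(f"empty group {g} for condition {cond!r}")
            out[ci, g] = z_normalize(epochs.data[sel, :, time_index].mean(axis=0))
    return out


def _fold_eval(patterns: np.ndarray, C: float) -> tuple[int, np.ndarray]:
    """Run all leave-one-group-out folds on ``(2, n_groups, n_channels)`` patterns.

    Returns the number of correct predictions (out of 2 * n_groups) and the
    summed activation vector (training-pattern covariance times SVM weights)
    across folds.  A test pattern exactly on the decision boundary is
    assigned to the first class label, deterministically.
    """
    n_cond, n_groups, n_ch = patterns.shape
    if n_cond != 2:
        raise DataError("binary decoding requires exactly two conditions")
    correct = 0
    act = np.zeros(n_ch)
    groups = np.arange(n_groups)
    for held in groups:
        train_groups = groups[groups != held]
        x_train = patterns[:, train_groups].reshape(-1, n_ch)
        y_train = np.repeat([0, 1], n_groups - 1)
        clf = SVC(kernel="linear", C=C)
        clf.fit(x_train, y_train)
        scores = clf.decision_function(patterns[:, held])
        pred = (scores > 0).astype(int)  # 0 on the boundary -> first class
        correct += int((pred == np.array([0, 1])).sum())
        w = clf.coef_[0]
        cov = np.cov(x_train, rowvar=False)
        act += cov @ w
    return correct, act


def crossval_accuracy_at_time(patterns: np.ndarray,
                              config: DecoderConfig = DecoderConfig()) -> float:
    """Accuracy of one grouping at one time point, aggregated over folds."""
    n_cond, n_groups, _ = patterns.shape
    correct, _ = _fold_eval(patterns, config.C)
    return correct / (n_cond * n_groups)


def _group_means(epochs: EpochSet, assignment: np.ndarray,
                 conds: list[str], n_groups: int) -> np.ndarray:
    """(n_cond, n_groups, n_channels, n_times) group-averaged waveforms."""
    out = np.empty((len(conds), n_groups, epochs.n_channels, epochs.n_samples))
    for ci, cond in enumerate(conds):
        for g in range(n_groups):
            sel = (epochs.condition == cond) & (assignment == g)
            out[ci, g] = epochs.data[sel].mean(axis=0)
    return out


def _z_across_channels(mat: np.ndarray) -> np.ndarray:
    """Z-score axis -2 (channels) of (..., channels, times) with ddof=1."""
    mean = mat.mean(axis=-2, keepdims=True)
    sd = mat.std(axis=-2, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (mat - mean) / sd
    bad = ~np.isfinite(out)
    if bad.any():
        warnings.warn("constant channel vector(s): z-normalization yields zeros",
                      RuntimeWarning, stacklevel=2)
        out[bad] = 0.0
    return out


def decode_timecourse(epochs: EpochSet,
                      config: DecoderConfig = DecoderConfig()) -> DecodingTimecourse:
    """Full trial-averaged decoding time course for one subject.

    ``epochs`` should already be low-passed at 8 Hz, trimmed and
    downsampled to 50 Hz.  Reproducible bit-for-bit for a fixed
    ``config.seed``: iteration k draws its grouping from substream k of the
    per-subject seed sequence.
    """
    labels = (list(config.channel_subset) if config.channel_subset is not None
              else epochs.eeg_channels())
    ep = epochs.select_channels(labels)
    conds = sorted(np.unique(ep.condition))
    if len(conds) != 2:
        raise DataError(f"binary decoding requires 2 conditions, got {conds}")
    n_t = ep.n_samples
    n_groups, n_iter = config.n_groups, config.n_iterations
    correct = np.zeros(n_t, dtype=int)
    act = np.zeros((n_t, ep.n_channels))
    streams = np.random.SeedSequence(config.seed).spawn(n_iter)
    for k in range(n_iter):
        rng = np.random.default_rng(streams[k])
        assignment = partition_trials(ep.condition, n_groups, rng)
        means = _group_means(ep, assignment, conds, n_groups)
        patterns = _z_across_channels(means)  # (2, g, ch, t)
        for ti in range(n_t):
            c, a = _fold_eval(patterns[:, :, :, ti], config.C)
            correct[ti] += c
            act[ti] += a
    n_attempts = 2 * n_groups * n_iter
    accuracy = correct / n_attempts
    act /= n_groups * n_iter
    return DecodingTimecourse(
        times=ep.times.copy(), accuracy=accuracy,
        smoothed=smooth_timecourse(accuracy, config.smoothing_points),
        n_attempts=n_attempts, activations=act, channels=labels,
        subject_id=ep.subject_id, config=config)


def smooth_timecourse(accuracy: np.ndarray, smoothing_points: int = 5) -> np.ndarray:
    """Centered moving average; edge windows shrink instead of padding."""
    if smoothing_points % 2 != 1:
        raise ConfigurationError("smoothing window must be odd")
    accuracy = np.asarray(accuracy, dtype=float)
    if smoothing_points > accuracy.size:
        raise ConfigurationError("smoothing window longer than series")
    kernel = np.ones(smoothing_points)
    sums = np.convolve(accuracy, kernel, mode="same")
    counts = np.convolve(np.ones_like(accuracy), kernel, mode="same")
    return sums / counts


def channel_subset_decode(epochs: EpochSet, labels: tuple[str, ...] = ("F7", "F8"),
                          config: DecoderConfig = DecoderConfig()) -> DecodingTimecourse:
    """Decoding restricted to a channel subset (F7/F8 eye-movement proxy)."""
    for lb in labels:
        epochs.channel_index(lb)  # raises ChannelError when missing
    cfg = DecoderConfig(**{**config.__dict__, "channel_subset": tuple(labels)})
    return decode_timecourse(epochs, cfg)
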