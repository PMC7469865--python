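"""Group-level statistics on decoding time courses.

Per time point a one-tailed Wilcoxon signed-rank test asks whether the
median subject accuracy exceeds chance (0.5); Benjamini-Hochberg FDR at
q < 0.05 corrects across time points, and runs of fewer than three
contiguous significant points are discarded.  The decoding onset is the
first significant time at or after the locking event, and its sampling
distribution is estimated by bootstrap resampling of subjects (100
resamples by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError


@dataclass
class SignificanceMask:
    """Per-timepoint p, BH-adjusted q, and the contiguity-filtered mask."""

    p: np.ndarray
    q_adjusted: np.ndarray
    mask: np.ndarray
    q_threshold: float = 0.05
    min_run: int = 3

    def to_frame(self, times: np.ndarray | None = None) -> pd.DataFrame:
        d = {"p": self.p, "q_adjusted": self.q_adjusted, "significant": self.mask}
        if times is not None:
            d = {"time_ms": times, **d}
        return pd.DataFrame(d)


@dataclass
class OnsetDistribution:
    """Bootstrap onset estimates (ms); NaN marks resamples with no onset."""

    onsets: np.ndarray
    n_boot: int
    n_excluded: int

    @property
    def valid(self) -> np.ndarray:
        return self.onsets[~np.isnan(self.onsets)]

    @property
    def mean(self) -> float:
        return float(self.valid.mean())

    @property
    def sd(self) -> float:
        return float(self.valid.std(ddof=1)) if self.valid.size > 1 else 0.0


def signed_rank_p(values: np.ndarray, mu: float = 0.5) -> float:
    """One-tailed signed-rank p for median(values) > mu.

    Zero differences are dropped (standard convention).  The exact null
    distribution is used for n <= 25 without rank ties; the normal
    approximation with continuity correction otherwise.  All differences
    zero gives p = 1 with a warning.
    """
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all differences zero: signed-rank p set to 1",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    ranks_tied = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not ranks_tied) else "approx"
    res = stats.wilcoxon(d, alternative="greater", method=method,
                         correction=(method == "approx"))
    return float(res.pvalue)


def signed_rank_timecourse(accuracy: np.ndarray, chance: float = 0.5) -> np.ndarray:
    """Per-timepoint one-tailed signed-rank p values (subjects x time input)."""
    accuracy = np.asarray(accuracy, dtype=float)
    if accuracy.ndim != 2:
        raise DataError("accuracy must be subjects x time")
    if accuracy.shape[0] < 6:
        raise DataError("signed-rank test needs at least 6 subjects")
    return np.array([signed_rank_p(accuracy[:, t], chance)
                     for t in range(accuracy.shape[1])])


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    out = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            in_run, start = True, i
        elif not v and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(mask)))
    return out


def fdr_contiguity_mask(p: np.ndarray, q: float = 0.05, min_run: int = 3,
                        method: str = "bh") -> SignificanceMask:
    """Benjamini-Hochberg step-up across time, then drop short runs.

    ``method`` may be ``"bh"`` or ``"by"`` (Benjamini-Yekutieli).  Runs of
    fewer than ``min_run`` contiguous significant points are removed to
    guard against isolated chance hits.
    """
    p = np.asarray(p, dtype=float)
    q_adj = stats.false_discovery_control(p, method=method)
    base = q_adj < q
    mask = np.zeros_like(base)
    for start, stop in _runs(base):
        if stop - start >= min_run:
            mask[start:stop] = True
    return SignificanceMask(p=p, q_adjusted=q_adj, mask=mask,
                            q_threshold=q, min_run=min_run)


def extract_onset(mask: SignificanceMask, times: np.ndarray) -> float | None:
    """Earliest significant time at or after 0 ms, or None.

    Pre-event significant points (possible under noise) are never reported
    as onsets; restrict to them explicitly if needed.
    """
    times = np.asarray(times, dtype=float)
    sel = mask.mask & (times >= 0)
    idx = np.flatnonzero(sel)
    return float(times[idx[0]]) if idx.size else None


def bootstrap_onsets(accuracy: np.ndarray, times: np.ndarray, n_boot: int = 100,
                     seed: int | np.random.Generator = 0, q: float = 0.05,
                     min_run: int = 3, chance: float = 0.5) -> OnsetDistribution:
    """Bootstrap (subjects resampled with replacement) onset distribution.

    Each resample reruns the full signed-rank -> FDR -> contiguity -> onset
    chain.  Resamples without any post-event significant run are recorded
    as missing and excluded from the summary; if every resample misses, a
    DataError signals that no effect is detectable.
    """
    accuracy = np.asarray(accuracy, dtype=float)
    if accuracy.shape[0] < 2:
        raise DataError("bootstrap needs at least 2 subjects")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_sub = accuracy.shape[0]
    onsets = np.full(n_boot, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for b in range(n_boot):
            draw = rng.integers(0, n_sub, size=n_sub)
            p = signed_rank_timecourse(accuracy[draw], chance)
            onset = extract_onset(fdr_contiguity_mask(p, q=q, min_run=min_run), times)
            if onset is not None:
                onsets[b] = onset
    n_excluded = int(np.isnan(onsets).sum())
    if n_excluded == n_boot:
        raise DataError("no bootstrap resample produced a detectable onset")
    return OnsetDistribution(onsets=onsets, n_boot=n_boot, n_excluded=n_excluded)


def compare_onsets(dist_a: OnsetDistribution, dist_b: OnsetDistribution):
    """Two-sample t test on the bootstrap onset values (a vs b)."""
    a, b = dist_a.valid, dist_b.valid
    if a.size == 0 or b.size == 0:
        raise DataError("both onset distributions must be non-empty")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


def window_average_accuracy(accuracy: np.ndarray, times: np.ndarray,
                            windows: list[tuple[float, float]]) -> pd.DataFrame:
    """Per-subject mean accuracy in each ``[start, end)`` ms window."""
    accuracy = np.asarray(accuracy, dtype=float)
    times = np.asarray(times, dtype=float)
    cols = {}
    for w in windows:
        sel = (times >= w[0]) & (times < w[1])
        if not sel.any():
            raise ConfigurationError(f"window {w} contains no time points")
        cols[f"{w[0]:g}-{w[1]:g}ms"] = accuracy[:, sel].mean(axis=1)
    return pd.DataFrame(cols)
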