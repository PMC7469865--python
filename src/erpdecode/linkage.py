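"""Between-subject brain-behavior linkage.

Per time point, a Pearson correlation (two-tailed) relates one scalar per
subject (N1 attention modulation, mean/median RT, or the RT validity
effect) to the subject's decoding accuracy.  When two cohorts measure the
same relation their per-point p values are combined with the
Liptak-Stouffer weighted-Z meta-analysis (weights sqrt(N)).  Significance
of contiguous runs of p < .05 (minimum cluster size 1) is assessed by a
cluster-size permutation test that shuffles the subject pairing within
each cohort once per iteration and applies that same shuffle at every time
point, preserving the temporal autocorrelation of the accuracy series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .group_stats import _runs

P_CLIP = 1e-12  # keep the normal quantile finite on extreme fixtures


@dataclass
class CorrelationTimecourse:
    """Pearson r and two-tailed p per time point (one cohort)."""

    times: np.ndarray
    r: np.ndarray
    p: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times, "r": self.r, "p": self.p})


@dataclass
class MetaCombineResult:
    """Liptak-Stouffer combination across cohorts, per time point."""

    z_per_dataset: np.ndarray  # datasets x time
    weights: np.ndarray        # sqrt(N) per dataset
    z_combined: np.ndarray
    p_combined: np.ndarray


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    size: int
    p: float
    p_label: str

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class PermutationResult:
    """Observed clusters and the permutation null of largest cluster sizes."""

    clusters: list[Cluster]
    null_sizes: np.ndarray
    times: np.ndarray
    p_pointwise: np.ndarray  # combined (or single-cohort) per-point p
    r_observed: list[np.ndarray]  # per cohort

    @property
    def any_significant(self) -> bool:
        return any(c.significant for c in self.clusters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"start_ms": c.start_ms, "end_ms": c.end_ms, "size": c.size,
              "p": c.p, "p_label": c.p_label} for c in self.clusters])


def _pearson_matrix(accuracy: np.ndarray, behavior: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-tailed p of ``behavior`` rows vs accuracy columns.

    ``accuracy``: subjects x time; ``behavior``: (n_variants, subjects) --
    each variant row (e.g. one permutation of the behavioral vector) is
    correlated against every time point at once.
    """
    n = accuracy.shape[0]
    acc_c = accuracy - accuracy.mean(axis=0, keepdims=True)
    acc_sd = acc_c.std(axis=0, ddof=1)
    beh_c = behavior - behavior.mean(axis=1, keepdims=True)
    beh_sd = beh_c.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (beh_c @ acc_c) / ((n - 1) * np.outer(beh_sd, acc_sd))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p[np.isnan(r)] = np.nan
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return r, p


def corr_timecourse(accuracy: np.ndarray, behavior: np.ndarray,
                    times: np.ndarray,
                    window: tuple[float, float] | None = None
                    ) -> CorrelationTimecourse:
    """Per-timepoint Pearson correlation between accuracy and a behavior scalar.

    ``window`` (ms, endpoints inclusive) restricts the analyzed interval,
    e.g. 0..1200 ms cue-locked or 0..560 ms target-locked.  Zero variance
    in either variable yields NaN r at that point (flagged by a warning).
    """
    accuracy = np.asarray(accuracy, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    times = np.asarray(times, dtype=float)
    if accuracy.ndim != 2 or accuracy.shape[0] != behavior.shape[0]:
        raise DataError("accuracy must be subjects x time, behavior one scalar per subject")
    if accuracy.shape[0] < 4:
        raise DataError("correlation needs at least 4 subjects")
    if np.isnan(accuracy).any() or np.isnan(behavior).any():
        raise DataError("missing values are not allowed")
    if window is not None:
        sel = (times >= window[0]) & (times <= window[1])
        accuracy, times = accuracy[:, sel], times[sel]
    r, p = _pearson_matrix(accuracy, behavior[None, :])
    if np.isnan(r).any():
        warnings.warn("zero variance at some time points: r undefined (NaN)",
                      RuntimeWarning, stacklevel=2)
    return CorrelationTimecourse(times=times, r=r[0], p=p[0])


def liptak_stouffer(p_lists: list[np.ndarray], ns: list[int]) -> MetaCombineResult:
    """Weighted-Z combination of per-point p values across cohorts.

    ``Z_i = Phi^-1(1 - p_i)``, weights ``w_i = sqrt(N_i)``, combined
    ``Z = sum(w_i Z_i) / sqrt(sum(w_i^2))``, combined ``p = 1 - Phi(Z)``.
    p values at exactly 0 or 1 are clipped with a warning.
    """
    ps = np.asarray(p_lists, dtype=float)
    if ps.ndim == 1:
        ps = ps[None, :]
    if ps.shape[0] != len(ns):
        raise DataError("one subject count per cohort is required")
    if ((ps <= 0) | (ps >= 1)).any():
        warnings.warn("p values at 0 or 1 clipped before the normal quantile",
                      RuntimeWarning, stacklevel=2)
    ps = np.clip(ps, P_CLIP, 1.0 - P_CLIP)
    z = stats.norm.isf(ps)
    w = np.sqrt(np.asarray(ns, dtype=float))
    z_comb = (w @ z) / np.sqrt((w ** 2).sum())
    return MetaCombineResult(z_per_dataset=z, weights=w, z_combined=z_comb,
                             p_combined=stats.norm.sf(z_comb))


def _combine_p(p_rows: np.ndarray, ns: list[int]) -> np.ndarray:
    """Liptak-Stouffer on (datasets, n_variants, time) without object churn."""
    ps = np.clip(p_rows, P_CLIP, 1.0 - P_CLIP)
    z = stats.norm.isf(ps)
    w = np.sqrt(np.asarray(ns, dtype=float))
    z_comb = np.tensordot(w, z, axes=(0, 0)) / np.sqrt((w ** 2).sum())
    return stats.norm.sf(z_comb)


def _largest_run(sig: np.ndarray) -> np.ndarray:
    """Largest run of True along the last axis, vectorized over rows."""
    sig = np.atleast_2d(sig)
    n_rows, n_t = sig.shape
    padded = np.zeros((n_rows, n_t + 2), dtype=bool)
    padded[:, 1:-1] = sig
    out = np.zeros(n_rows, dtype=int)
    for i in range(n_rows):
        d = np.diff(padded[i].astype(int))
        starts = np.flatnonzero(d == 1)
        stops = np.flatnonzero(d == -1)
        if starts.size:
            out[i] = int((stops - starts).max())
    return out


def cluster_permutation(accuracy_list: list[np.ndarray],
                        behavior_list: list[np.ndarray],
                        times: np.ndarray, n_perm: int = 1000,
                        alpha: float = 0.05,
                        seed: int | np.random.Generator = 0,
                        window: tuple[float, float] | None = None
                        ) -> PermutationResult:
    """Cluster-size permutation test with shared subject shuffles.

    Observed clusters are maximal runs of time points whose (combined,
    for >= 2 cohorts) correlation p is below ``alpha`` (minimum cluster
    size 1).  Each permutation shuffles the behavior vector within each
    cohort once, applies the identical shuffle at every time point,
    recomputes and (if applicable) combines the p values, and records the
    largest significant run (0 when none).  A cluster's p is the fraction
    of null values >= its size; when the observed size exceeds every null
    value it is labelled "<.001".
    """
    if len(accuracy_list) != len(behavior_list) or not accuracy_list:
        raise DataError("one behavior vector per cohort is required")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: unstable null tail",
                      RuntimeWarning, stacklevel=2)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    times = np.asarray(times, dtype=float)
    acc_list, ns = [], []
    if window is not None:
        sel = (times >= window[0]) & (times <= window[1])
        times = times[sel]
    for acc in accuracy_list:
        acc = np.asarray(acc, dtype=float)
        if acc.shape[1] != (len(times) if window is None else sel.size):
            raise DataError("cohort time axes must match exactly")
        acc_list.append(acc[:, sel] if window is not None else acc)
        ns.append(acc.shape[0])
    n_t = len(times)

    # observed statistic
    r_obs, p_obs = [], []
    for acc, beh in zip(acc_list, behavior_list):
        r, p = _pearson_matrix(acc, np.asarray(beh, dtype=float)[None, :])
        r_obs.append(r[0])
        p_obs.append(p[0])
    p_comb = (_combine_p(np.stack(p_obs)[:, None, :], ns)[0]
              if len(acc_list) > 1 else p_obs[0])

    # permutation null: one shuffle per cohort per iteration, shared over time
    p_null = np.empty((len(acc_list), n_perm, n_t))
    for di, (acc, beh) in enumerate(zip(acc_list, behavior_list)):
        beh = np.asarray(beh, dtype=float)
        perms = np.stack([rng.permutation(len(beh)) for _ in range(n_perm)])
        _, p_null[di] = _pearson_matrix(acc, beh[perms])
    null_p = _combine_p(p_null, ns) if len(acc_list) > 1 else p_null[0]
    null_sizes = _largest_run(null_p < alpha)

    step = times[1] - times[0] if n_t > 1 else 0.0
    clusters = []
    for start, stop in _runs(p_comb < alpha):
        size = stop - start
        exceed = int((null_sizes >= size).sum())
        p_val = exceed / n_perm
        label = "<.001" if exceed == 0 else f"{p_val:.3f}"
        clusters.append(Cluster(start_ms=float(times[start]),
                                end_ms=float(times[stop - 1] + step),
                                size=size, p=p_val, p_label=label))
    return PermutationResult(clusters=clusters, null_sizes=null_sizes,
                             times=times, p_pointwise=p_comb, r_observed=r_obs)


def univariate_corr(diff_waves: np.ndarray, behavior: np.ndarray,
                    times: np.ndarray, q: float = 0.05, n_perm: int = 1000,
                    alpha: float = 0.05,
                    seed: int | np.random.Generator = 0,
                    window: tuple[float, float] | None = None) -> dict:
    """Univariate counterpart: per-channel correlation with channel-wise FDR.

    ``diff_waves``: subjects x channels x time difference waves.  Per
    channel and time point Pearson r/p is computed; p values are BH
    FDR-corrected across channels at each time point; clusters of
    contiguous corrected p < alpha are then evaluated per channel against a
    permutation null of the maximum (over channels) largest run, using the
    same shared subject shuffle at every time point and channel.
    """
    diff_waves = np.asarray(diff_waves, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    times = np.asarray(times, dtype=float)
    if diff_waves.ndim != 3:
        raise DataError("diff_waves must be subjects x channels x time")
    if window is not None:
        sel = (times >= window[0]) & (times <= window[1])
        diff_waves, times = diff_waves[:, :, sel], times[sel]
    n_sub, n_ch, n_t = diff_waves.shape
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    def channel_p(beh_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # returns r, fdr-corrected p of shape (n_variants, n_ch, n_t)
        n_var = beh_rows.shape[0]
        r = np.empty((n_var, n_ch, n_t))
        p = np.empty((n_var, n_ch, n_t))
        for ci in range(n_ch):
            r[:, ci], p[:, ci] = _pearson_matrix(diff_waves[:, ci, :], beh_rows)
        # BH across channels at each (variant, time)
        p_adj = np.empty_like(p)
        for vi in range(n_var):
            p_adj[vi] = stats.false_discovery_control(p[vi], axis=0)
        return r, p_adj

    r_obs, p_obs = channel_p(behavior[None, :])
    perms = np.stack([rng.permutation(n_sub) for _ in range(n_perm)])
    _, p_null = channel_p(behavior[perms])
    null_sizes = _largest_run((p_null < alpha).reshape(n_perm * n_ch, n_t))
    null_sizes = null_sizes.reshape(n_perm, n_ch).max(axis=1)

    step = times[1] - times[0] if n_t > 1 else 0.0
    clusters_by_channel: list[list[Cluster]] = []
    for ci in range(n_ch):
        clusters = []
        for start, stop in _runs(p_obs[0, ci] < alpha):
            size = stop - start
            exceed = int((null_sizes >= size).sum())
            p_val = exceed / n_perm
            clusters.append(Cluster(
                start_ms=float(times[start]), end_ms=float(times[stop - 1] + step),
                size=size, p=p_val,
                p_label="<.001" if exceed == 0 else f"{p_val:.3f}"))
        clusters_by_channel.append(clusters)
    return {"times": times, "r": r_obs[0], "p_fdr": p_obs[0],
            "clusters": clusters_by_channel, "null_sizes": null_sizes}


def behavior_summaries(trials: pd.DataFrame) -> dict:
    """Per-subject behavioral scalars from a trial table.

    Expects columns ``rt`` (ms; NaN for no-response trials), ``correct``
    (bool), and optionally ``validity`` in {"valid", "invalid", "neutral"}.
    Mean and median RT are computed over correct trials with a response;
    for probabilistic designs the validity effect (invalid minus valid) is
    added for both summaries.
    """
    ok = trials["correct"].astype(bool) & trials["rt"].notna()
    if not ok.any():
        raise DataError("no correct response trials")
    rt = trials.loc[ok, "rt"].astype(float)
    out = {"mean_rt": float(rt.mean()), "median_rt": float(rt.median()),
           "n_response_trials": int(ok.sum())}
    if "validity" in trials.columns:
        val = trials.loc[ok, "validity"]
        if {"valid", "invalid"} <= set(val.unique()):
            v = rt[val == "valid"]
            iv = rt[val == "invalid"]
            out["rt_difference"] = float(iv.mean() - v.mean())
            out["median_rt_difference"] = float(iv.median() - v.median())
    return out
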