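"""End-to-end pipelines and run manifests.

Canonical analyses over a cohort of epoched recordings (synthetic or
imported): artifact screening, decoding-oriented preprocessing (8 Hz FIR
low-pass, trimming, 50 Hz downsampling, baseline correction), per-subject
trial-averaged decoding, group significance/onset statistics, and the
between-subject linkage analyses.  Every run writes CSV/JSON artifacts
plus a manifest (config hash, seeds, output checksums) so reruns with an
identical config are verifiably identical for the deterministic stages.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .artifacts import RejectionCriteria, screen_epochs
from .containers import EpochSet
from .decode import DecoderConfig, channel_subset_decode, decode_timecourse
from .erp import measure_n1
from .errors import ConfigurationError, DataError
from .group_stats import (bootstrap_onsets, extract_onset, fdr_contiguity_mask,
                          signed_rank_timecourse, window_average_accuracy)
from .io import config_hash, file_checksum, write_json
from .linkage import behavior_summaries, cluster_permutation, corr_timecourse
from .preprocess import (baseline_correct, collapse_target_conditions,
                         lowpass_epochs, trim_and_downsample)
from .simulate import SimulationConfig, generate_cohort

log = logging.getLogger("erpdecode")

_PIPELINE_KEYS = {"paradigm", "outdir", "seed", "simulation", "decoder",
                  "n_bootstrap", "screening", "windows_ms"}


@dataclass
class PipelineConfig:
    """Validated top-level configuration (unknown keys are rejected)."""

    paradigm: str = "instructional"
    outdir: str = "erpdecode_run"
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    decoder: dict = field(default_factory=dict)
    screening: bool = True
    n_bootstrap: int = 100
    windows_ms: list = field(default_factory=lambda: [[200, 700], [700, 1200]])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _PIPELINE_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return {"paradigm": self.paradigm, "outdir": self.outdir, "seed": self.seed,
                "simulation": self.simulation, "decoder": self.decoder,
                "screening": self.screening, "n_bootstrap": self.n_bootstrap,
                "windows_ms": self.windows_ms}

    def simulation_config(self) -> SimulationConfig:
        kw = dict(self.simulation)
        kw.setdefault("paradigm", self.paradigm)
        kw.setdefault("seed", self.seed)
        return SimulationConfig(**kw)

    def decoder_config(self, **extra) -> DecoderConfig:
        kw = dict(self.decoder)
        kw.setdefault("seed", self.seed)
        kw.update(extra)
        return DecoderConfig(**kw)


def _manifest(cfg: PipelineConfig, outdir: Path, stage: str) -> None:
    files = sorted(p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json")
    write_json(outdir / "manifest.json", {
        "stage": stage, "version": __version__, "seed": cfg.seed,
        "config_hash": config_hash(cfg.as_dict()),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "checksums": {p.name: file_checksum(p) for p in files}})


def preprocess_for_decoding(epochs: EpochSet, screening: bool = True,
                            collapse: bool = False) -> EpochSet:
    """Screen, low-pass, trim/downsample and baseline one epoch set."""
    if screening:
        report = screen_epochs(epochs, RejectionCriteria())
        epochs = epochs.select_trials(report.retained)
    if collapse:
        epochs = collapse_target_conditions(epochs)
    ep = lowpass_epochs(epochs, cutoff=8.0)
    ep = trim_and_downsample(ep, trim_ms=200.0, target_sfreq=50.0)
    return baseline_correct(ep, (-200.0, 0.0))


def _group_stats_outputs(acc: np.ndarray, times: np.ndarray,
                         cfg: PipelineConfig, outdir: Path, prefix: str) -> dict:
    p = signed_rank_timecourse(acc)
    mask = fdr_contiguity_mask(p)
    onset = extract_onset(mask, times)
    result = {"onset_ms": onset}
    mask.to_frame(times).to_csv(outdir / f"{prefix}_mask.csv", index=False)
    if onset is not None and acc.shape[0] >= 2:
        try:
            dist = bootstrap_onsets(acc, times, n_boot=cfg.n_bootstrap,
                                    seed=cfg.seed)
            result.update({"onset_boot_mean": dist.mean, "onset_boot_sd": dist.sd,
                           "onset_boot_excluded": dist.n_excluded})
            pd.DataFrame({"onset_ms": dist.onsets}).to_csv(
                outdir / f"{prefix}_bootstrap_onsets.csv", index=False)
        except DataError:
            result["onset_boot_mean"] = None
    windows = [tuple(w) for w in cfg.windows_ms]
    try:
        window_average_accuracy(acc, times, windows).to_csv(
            outdir / f"{prefix}_window_accuracy.csv", index=False)
    except ConfigurationError:
        pass  # configured windows may lie outside a short epoch
    return result


def run_cue_pipeline(cfg: PipelineConfig,
                     cohort: list[tuple[EpochSet, EpochSet]] | None = None) -> dict:
    """Cue-locked analysis: preprocess, decode, group statistics."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort, truth = generate_cohort(cfg.simulation_config())
        truth.to_csv(outdir / "ground_truth.csv")
    rows, acc = [], []
    times = None
    for cue_epochs, _ in cohort:
        t0 = time.time()
        ep = preprocess_for_decoding(cue_epochs, screening=cfg.screening)
        tc = decode_timecourse(ep, cfg.decoder_config())
        log.info("cue decode %s: %.1f s", tc.subject_id, time.time() - t0)
        rows.append(tc.to_frame())
        acc.append(tc.smoothed)
        times = tc.times
    acc = np.vstack(acc)
    pd.concat(rows).to_csv(outdir / "cue_accuracy.csv", index=False)
    result = _group_stats_outputs(acc, times, cfg, outdir, "cue")
    result.update({"accuracy": acc, "times": times})
    write_json(outdir / "cue_summary.json",
               {k: v for k, v in result.items() if np.isscalar(v) or v is None})
    _manifest(cfg, outdir, "cue")
    return result


def run_target_pipeline(cfg: PipelineConfig,
                        cohort: list[tuple[EpochSet, EpochSet]] | None = None) -> dict:
    """Target-locked analysis: collapse to cued/uncued, decode, stats, N1."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort, truth = generate_cohort(cfg.simulation_config())
        truth.to_csv(outdir / "ground_truth.csv")
    rows, acc, summaries = [], [], []
    times = None
    for _, tgt_epochs in cohort:
        ep_for_n1 = baseline_correct(tgt_epochs, (-200.0, 0.0))
        n1 = measure_n1(ep_for_n1)
        beh = behavior_summaries(tgt_epochs.trial_info)
        ep = preprocess_for_decoding(tgt_epochs, screening=cfg.screening,
                                     collapse=True)
        tc = decode_timecourse(ep, cfg.decoder_config())
        rows.append(tc.to_frame())
        acc.append(tc.smoothed)
        times = tc.times
        summaries.append({"subject_id": tgt_epochs.subject_id,
                          "n1_modulation_uv": n1.modulation, **beh})
    acc = np.vstack(acc)
    pd.concat(rows).to_csv(outdir / "target_accuracy.csv", index=False)
    subj = pd.DataFrame(summaries)
    subj.to_csv(outdir / "subject_summaries.csv", index=False)
    cfg_t = PipelineConfig(**{**cfg.as_dict(),
                              "windows_ms": [[200, 500], [500, 800]]})
    result = _group_stats_outputs(acc, times, cfg_t, outdir, "target")
    result.update({"accuracy": acc, "times": times, "subject_summaries": subj})
    _manifest(cfg, outdir, "target")
    return result


def run_confound_check(cfg: PipelineConfig,
                       cohort: list[tuple[EpochSet, EpochSet]] | None = None) -> dict:
    """F7/F8-only decoding as a residual eye-movement check."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort, _ = generate_cohort(cfg.simulation_config())
    acc = []
    times = None
    for cue_epochs, _ in cohort:
        ep = preprocess_for_decoding(cue_epochs, screening=cfg.screening)
        tc = channel_subset_decode(ep, ("F7", "F8"), cfg.decoder_config())
        acc.append(tc.smoothed)
        times = tc.times
    acc = np.vstack(acc)
    p = signed_rank_timecourse(acc)
    mask = fdr_contiguity_mask(p)
    mask.to_frame(times).to_csv(outdir / "confound_mask.csv", index=False)
    _manifest(cfg, outdir, "confound")
    return {"accuracy": acc, "times": times, "mask": mask}


def run_linkage(cue_results: list[dict], subject_tables: list[pd.DataFrame],
                behavior_column: str, outdir: str | Path, n_perm: int = 1000,
                seed: int = 0, window: tuple[float, float] = (0.0, 1200.0)) -> dict:
    """Between-subject linkage over one or two cohorts.

    ``cue_results``: outputs of :func:`run_cue_pipeline` (or the target
    pipeline), one per cohort; ``subject_tables`` carry the behavioral /
    neural scalar named by ``behavior_column``.  With two cohorts the
    per-point p values are Liptak-Stouffer combined inside the cluster
    permutation; with one, the single-cohort variant runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    acc_list = [r["accuracy"] for r in cue_results]
    times = cue_results[0]["times"]
    for r in cue_results[1:]:
        if not np.array_equal(r["times"], times):
            raise DataError("cohort time axes must match exactly; no interpolation")
    beh_list = [tab[behavior_column].to_numpy(dtype=float) for tab in subject_tables]
    per_cohort = []
    for acc, beh in zip(acc_list, beh_list):
        ct = corr_timecourse(acc, beh, times, window=window)
        per_cohort.append(ct)
    perm = cluster_permutation(acc_list, beh_list, times, n_perm=n_perm,
                               seed=seed, window=window)
    for i, ct in enumerate(per_cohort):
        ct.to_frame().to_csv(outdir / f"linkage_corr_cohort{i}.csv", index=False)
    perm.to_frame().to_csv(outdir / "linkage_clusters.csv", index=False)
    write_json(outdir / "linkage_summary.json", {
        "behavior": behavior_column, "n_cohorts": len(acc_list),
        "clusters": [c.__dict__ for c in perm.clusters]})
    return {"correlations": per_cohort, "permutation": perm}
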