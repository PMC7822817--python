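"""Config-driven experiment runs: the four analyses and raster export.

Each run is reproducible from an :class:`ExperimentConfig` alone: a single
master seed fans out deterministically (via :mod:`neurotactile._seeds`) to
the stimulus noise, innervation draw, nociceptor gain jitter, CV splits and
fault subsets.  Results are tidy tables (pandas) written as CSV with fixed
6-decimal formatting; every row carries the seeds and parameters that
produced it.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._seeds import derive_seed
from .classify import EvalConfig, knn_rate, knn_temporal, subpopulation_eval
from .coding import population_vp_matrix, spike_count_features
from .encoder import NociceptorSpec, PopulationResponse, encode_dataset
from .faults import robustness_sweep
from .innervation import build_innervation
from .stimuli import DEFAULT_OBJECTS, GridSpec, IndentationProfile, generate_dataset

log = logging.getLogger("neurotactile")

__all__ = [
    "ExperimentConfig",
    "DEFAULT_WINDOWS_MS",
    "run_innervation_sweep",
    "run_window_sweep",
    "run_contribution",
    "run_fault_sweep",
    "export_raster",
]

#: Cumulative decoding windows (ms from contact onset).
DEFAULT_WINDOWS_MS = (50, 100, 200, 300, 500, 1000, 1500, 2500)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    n_trials_per_object: int = 10
    onset_ms: int = 250
    hold_ms: int = 2000
    offset_ms: int = 250
    depth_mm: float = 1.4
    noise_sd: float = 20.46
    jitter_mm: float = 1.0
    mean_taxels: float = 3.0
    n_sa: int = 6
    n_ra: int = 12
    n_noc: int = 5
    noc_threshold_adc: int = 512
    q_per_ms: float = 0.05
    windows_ms: tuple = DEFAULT_WINDOWS_MS
    count_window_ms: float = 500.0
    k_neighbors: int = 5
    n_folds: int = 5
    fault_fractions: tuple = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    n_fault_seeds: int = 10
    master_seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("windows_ms", "fault_fractions"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["windows_ms"] = list(self.windows_ms)
        d["fault_fractions"] = list(self.fault_fractions)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def eval_config(self) -> EvalConfig:
        return EvalConfig(
            k_neighbors=self.k_neighbors,
            n_folds=self.n_folds,
            seed=derive_seed(self.master_seed, "split"),
        )


def _prepare(config: ExperimentConfig, mean_taxels: float | None = None, imap_index: int = 0):
    """Generate the dataset and encode it under the config's derived seeds."""
    profile = IndentationProfile(
        onset_ms=config.onset_ms,
        hold_ms=config.hold_ms,
        offset_ms=config.offset_ms,
        depth_mm=config.depth_mm,
    )
    trials = generate_dataset(
        DEFAULT_OBJECTS,
        config.n_trials_per_object,
        profile=profile,
        noise_sd=config.noise_sd,
        jitter_mm=config.jitter_mm,
        master_seed=derive_seed(config.master_seed, "stimulus"),
    )
    imap = build_innervation(
        n_sa=config.n_sa,
        n_ra=config.n_ra,
        mean_taxels=mean_taxels if mean_taxels is not None else config.mean_taxels,
        seed=derive_seed(config.master_seed, "innervation", imap_index),
    )
    noc = NociceptorSpec(threshold_adc=config.noc_threshold_adc, n_noc=config.n_noc)
    responses = encode_dataset(
        trials, imap, noc, noc_gain_seed=derive_seed(config.master_seed, "nociceptor")
    )
    labels = np.asarray([t.object.label for t in trials])
    groups = np.asarray([t.object.group for t in trials])
    return trials, imap, noc, responses, labels, groups


def _write(df: pd.DataFrame, config: ExperimentConfig, name: str) -> pd.DataFrame:
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / name, index=False, float_format="%.6f")
        log.info("wrote %s (%d rows)", out / name, len(df))
    return df


def run_innervation_sweep(
    config: ExperimentConfig, mean_taxels_grid: Sequence[float] = (1, 3, 7, 9)
) -> pd.DataFrame:
    """Accuracy and firing rate as the mean receptive-field size grows.

    For each mean field size a fresh innervation map is drawn and the
    rate-code decoder evaluated over cumulative windows; the mean SA-I/RA-I
    firing rate over the whole trial is reported alongside.
    """
    rows = []
    eval_cfg = config.eval_config()
    for i, m in enumerate(mean_taxels_grid):
        trials, imap, noc, responses, labels, _ = _prepare(config, mean_taxels=m, imap_index=i)
        duration = responses[0].duration_ms
        full_counts = spike_count_features(responses, (0, duration))
        kinds = np.asarray(responses[0].kinds)
        afferent_cols = np.isin(kinds, ["SA1", "RA1"])
        rate_hz = full_counts[:, afferent_cols].mean() / (duration / 1000.0)
        for w in config.windows_ms:
            X = spike_count_features(responses, (0, w))
            res = knn_rate(X, labels, eval_cfg, condition=f"mean_taxels={m},window={w}")
            rows.append(
                {
                    "mean_taxels": m,
                    "window_ms": w,
                    "accuracy": res.accuracy,
                    "firing_rate_hz": rate_hz,
                    "master_seed": config.master_seed,
                    "innervation_seed": imap.seed,
                }
            )
        log.info("innervation sweep: mean_taxels=%s done", m)
    return _write(pd.DataFrame(rows), config, "innervation_sweep.csv")


def run_window_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Rate-code vs temporal-code accuracy over cumulative windows,
    overall and per object group."""
    trials, imap, noc, responses, labels, groups = _prepare(config)
    eval_cfg = config.eval_config()
    scopes = {"all": np.ones(len(labels), bool), "I": groups == "I", "II": groups == "II"}
    rows = []
    for w in config.windows_ms:
        X = spike_count_features(responses, (0, w))
        D = population_vp_matrix(responses, q=config.q_per_ms, window_ms=(0, w))
        for scope, mask in scopes.items():
            idx = np.flatnonzero(mask)
            res_rate = knn_rate(X[idx], labels[idx], eval_cfg)
            res_temp = knn_temporal(D[np.ix_(idx, idx)], labels[idx], eval_cfg)
            rows.append(
                {
                    "window_ms": w,
                    "scope": scope,
                    "rate_accuracy": res_rate.accuracy,
                    "temporal_accuracy": res_temp.accuracy,
                    "q_per_ms": config.q_per_ms,
                    "master_seed": config.master_seed,
                }
            )
        log.info("window sweep: window=%s ms done", w)
    return _write(pd.DataFrame(rows), config, "window_sweep.csv")


_SUBSETS = (
    ("SA1",),
    ("RA1",),
    ("NOC",),
    ("SA1", "RA1"),
    ("NOC", "SA1"),
    ("NOC", "RA1"),
    ("NOC", "SA1", "RA1"),
)


def run_contribution(config: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contribution of each afferent kind (and combinations) to sharpness
    recognition, per object group, plus mean firing rate vs feature size."""
    trials, imap, noc, responses, labels, groups = _prepare(config)
    eval_cfg = config.eval_config()
    window = (0.0, config.count_window_ms)
    rows = []
    for scope in ("I", "II"):
        mask = groups == scope
        idx = np.flatnonzero(mask)
        sub_responses = [responses[i] for i in idx]
        for subset in _SUBSETS:
            res = subpopulation_eval(sub_responses, labels[idx], subset, window, eval_cfg)
            rows.append(
                {
                    "group": scope,
                    "subset": "+".join(subset),
                    "accuracy": res.accuracy,
                    "window_ms": config.count_window_ms,
                    "master_seed": config.master_seed,
                }
            )
    acc_df = _write(pd.DataFrame(rows), config, "contribution_accuracy.csv")

    # Mean firing rate of each kind vs object feature size (rate-vs-sharpness).
    duration = responses[0].duration_ms
    counts = spike_count_features(responses, (0, duration))
    kinds = np.asarray(responses[0].kinds)
    sizes = np.asarray([t.object.feature_size_mm for t in trials])
    rate_rows = []
    for scope in ("I", "II"):
        mask = groups == scope
        for size in sorted(set(sizes)):
            sel = mask & (sizes == size)
            for kind in ("NOC", "SA1", "RA1"):
                rate = counts[np.ix_(sel, kinds == kind)].mean() / (duration / 1000.0)
                rate_rows.append(
                    {
                        "group": scope,
                        "feature_size_mm": size,
                        "kind": kind,
                        "mean_rate_hz": rate,
                        "master_seed": config.master_seed,
                    }
                )
    rate_df = _write(pd.DataFrame(rate_rows), config, "contribution_rates.csv")
    return acc_df, rate_df


def run_fault_sweep(config: ExperimentConfig, modes: Sequence[str] = ("taxel", "channel", "both")) -> pd.DataFrame:
    """Graceful-degradation curves for damaged taxels, neurons, or both."""
    trials, imap, noc, responses, labels, groups = _prepare(config)
    eval_cfg = config.eval_config()
    rows = []
    for mode in modes:
        res = robustness_sweep(
            trials,
            imap,
            noc,
            fault_fractions=config.fault_fractions,
            mode=mode,
            n_seeds=config.n_fault_seeds,
            eval_config=eval_cfg,
            window_ms=(0.0, config.count_window_ms),
            noc_gain_seed=derive_seed(config.master_seed, "nociceptor"),
            fault_seed0=derive_seed(config.master_seed, "fault"),
        )
        for r in res:
            rows.append(
                {
                    "mode": mode,
                    "fraction": r["fraction"],
                    "mean_accuracy": r["mean_accuracy"],
                    "sd_accuracy": r["sd_accuracy"],
                    "n_seeds": r["n_seeds"],
                    "master_seed": config.master_seed,
                }
            )
        log.info("fault sweep: mode=%s done", mode)
    return _write(pd.DataFrame(rows), config, "fault_sweep.csv")


_KIND_COLORS = {"NOC": "tab:red", "SA1": "tab:orange", "RA1": "tab:blue"}


def export_raster(response: PopulationResponse, path: str | Path) -> Path:
    """Raster plot of one trial: one lane per channel, nociceptors red,
    SA-I orange, RA-I blue."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for lane, train in enumerate(response.trains):
        if len(train.times_ms):
            ax.eventplot(
                [train.times_ms],
                lineoffsets=lane,
                linelengths=0.8,
                colors=_KIND_COLORS.get(train.kind, "k"),
            )
    ax.set_xlim(0, response.duration_ms)
    ax.set_ylim(-1, len(response.trains))
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("channel")
    ax.set_yticks(range(len(response.trains)))
    ax.set_yticklabels([t.kind for t in response.trains], fontsize=6)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
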