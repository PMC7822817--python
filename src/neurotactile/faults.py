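"""Fault injection: damaged taxels and silenced neurons.

Two damage modes mirror hardware failures: taxel faults zero the output of
a random subset of sensor elements at the interface (before innervation and
before the nociceptor's NoT/MCV statistic), while channel faults silence a
random subset of the 23 digital afferents after encoding.  The damaged
subset is drawn once per experiment (persistent damage) and applied to
every trial.  A sweep over fault fractions quantifies graceful degradation
of classification accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .classify import EvalConfig, EvalResult, knn_rate
from .coding import spike_count_features
from .encoder import NociceptorSpec, PopulationResponse, SpikeTrain, encode_dataset
from .innervation import InnervationMap
from .stimuli import GridSpec, TrialRecord

__all__ = [
    "FaultSpec",
    "n_faulty",
    "taxel_fault_mask",
    "channel_fault_mask",
    "apply_taxel_faults",
    "apply_channel_faults",
    "robustness_sweep",
    "DEFAULT_FAULT_FRACTIONS",
]

DEFAULT_FAULT_FRACTIONS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class FaultSpec:
    """Which fraction of taxels / channels is damaged, and the damage seed."""

    taxel_fraction: float = 0.0
    channel_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.taxel_fraction, self.channel_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fault fractions must lie in [0, 1]")


def n_faulty(fraction: float, population: int) -> int:
    """Realized damage count: round-half-up of fraction * population."""
    return int(math.floor(fraction * population + 0.5))


def taxel_fault_mask(spec: FaultSpec, grid: GridSpec | None = None) -> np.ndarray:
    """Boolean (rows, cols) mask of damaged taxels, deterministic under seed."""
    grid = grid or GridSpec()
    k = n_faulty(spec.taxel_fraction, grid.n_taxels)
    rng = np.random.default_rng([spec.seed, 0])
    chosen = rng.choice(grid.n_taxels, size=k, replace=False)
    mask = np.zeros(grid.n_taxels, dtype=bool)
    mask[chosen] = True
    return mask.reshape(grid.rows, grid.cols)


def channel_fault_mask(spec: FaultSpec, n_channels: int = 23) -> np.ndarray:
    """Boolean mask of silenced channels, deterministic under seed."""
    k = n_faulty(spec.channel_fraction, n_channels)
    rng = np.random.default_rng([spec.seed, 1])
    chosen = rng.choice(n_channels, size=k, replace=False)
    mask = np.zeros(n_channels, dtype=bool)
    mask[chosen] = True
    return mask


def apply_taxel_faults(trial: TrialRecord, spec: FaultSpec) -> TrialRecord:
    """Zero the damaged taxels in every frame (interface-level damage).

    The same seeded subset applies to all trials sharing *spec*, modeling
    persistent sensor damage.  A zeroed taxel contributes nothing to any
    receptive field and drops out of the nociceptor's NoT count — so for a
    fixed frame the surviving suprathreshold taxels can yield a *larger*
    MCV/NoT drive, the damaged-skin analogue of innocuous touch turning
    noxious.
    """
    mask = taxel_fault_mask(spec, trial.grid)
    frames = trial.frames.copy()
    frames[:, mask] = 0
    return replace(trial, frames=frames, fault=spec)


def apply_channel_faults(response: PopulationResponse, spec: FaultSpec) -> PopulationResponse:
    """Replace the damaged channels' trains with empty ones (dead neurons)."""
    mask = channel_fault_mask(spec, len(response.trains))
    trains = tuple(
        SpikeTrain(t.channel_id, t.kind, np.empty(0, dtype=int)) if mask[i] else t
        for i, t in enumerate(response.trains)
    )
    return PopulationResponse(trains=trains, duration_ms=response.duration_ms)


def robustness_sweep(
    trials: Sequence[TrialRecord],
    imap: InnervationMap,
    noc: NociceptorSpec | None = None,
    fault_fractions: Sequence[float] = DEFAULT_FAULT_FRACTIONS,
    mode: str = "both",
    n_seeds: int = 10,
    eval_config: EvalConfig | None = None,
    window_ms: tuple[float, float] = (0.0, 500.0),
    noc_gain_seed: int = 0,
    fault_seed0: int = 0,
) -> list[dict]:
    """Classification accuracy under increasing damage.

    For each fraction and each of ``n_seeds`` damage draws: inject faults
    (taxel mode re-encodes the damaged frames; channel mode silences
    encoded trains; ``both`` applies the same fraction to each), extract
    500 ms spike counts and run the rate-code decoder.  Returns one record
    per fraction with mean and sd accuracy plus the per-seed values.
    """
    if mode not in ("taxel", "channel", "both"):
        raise ValueError("mode must be 'taxel', 'channel' or 'both'")
    if list(fault_fractions) != sorted(fault_fractions):
        raise ValueError("fault_fractions must be sorted ascending")
    noc = noc or NociceptorSpec()
    eval_config = eval_config or EvalConfig()
    labels = np.asarray([t.object.label for t in trials])

    clean_responses = encode_dataset(trials, imap, noc, noc_gain_seed=noc_gain_seed)
    results = []
    for frac in fault_fractions:
        accs = []
        for s in range(n_seeds):
            spec = FaultSpec(
                taxel_fraction=frac if mode in ("taxel", "both") else 0.0,
                channel_fraction=frac if mode in ("channel", "both") else 0.0,
                seed=fault_seed0 + s,
            )
            if frac == 0.0:
                responses = clean_responses
            else:
                if spec.taxel_fraction > 0:
                    damaged = [apply_taxel_faults(t, spec) for t in trials]
                    responses = encode_dataset(damaged, imap, noc, noc_gain_seed=noc_gain_seed)
                else:
                    responses = clean_responses
                if spec.channel_fraction > 0:
                    responses = [apply_channel_faults(r, spec) for r in responses]
            X = spike_count_features(responses, window_ms)
            res = knn_rate(X, labels, eval_config, condition=f"{mode}@{frac:g}")
            accs.append(res.accuracy)
        results.append(
            {
                "fraction": float(frac),
                "mode": mode,
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                "per_seed": [float(a) for a in accs],
                "n_seeds": n_seeds,
            }
        )
    return results
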