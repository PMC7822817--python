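"""Spiking front-end: Izhikevich SA-I / RA-I afferents and nociceptors.

The two-variable Izhikevich model (membrane potential ``v``, recovery ``u``)
is used in its hardware-friendly power-of-two rescaling: multiplying the
classic drift ``0.04 v^2 + 5v + 140`` by 0.78125 turns the coefficients into
``(1/32) v^2 + 4v + 109.375`` (the linear term rounded to 4), so an FPGA can
evaluate it with shifts.  Euler discretization at dt = 1 ms:

    v[n+1] = v[n] + ( (1/32) v[n]^2 + 4 v[n] + 109.375 - u[n] + k_s I[n] )
    u[n+1] = u[n] + a (b v[n] - u[n])
    if v[n+1] >= 30 mV:  v[n+1] <- c,  u[n+1] <- u[n] + d

Input conditioning per afferent class:

* SA-I (slowly adapting): regular-spiking dynamics driven directly by the
  receptive-field weighted sum, scaled by k1 = 1/32 — sustained response.
* RA-I (rapidly adapting): regular-spiking dynamics driven by the rectified
  temporal derivative of the weighted sum, scaled by k3 = 128 — responds
  only to onset and offset of indentation.
* Nociceptor: fast-spiking dynamics driven by MCV/NoT (max taxel value over
  the count of suprathreshold taxels), scaled by k2 = 1/8 — concentrated
  high pressure (sharp contact) yields a large input, distributed pressure
  a small or zero one.

Both a floating-point path (vectorized across neurons) and a Q13.18
fixed-point path replicating the FPGA datapath are provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import fixedpoint as fx
from .innervation import InnervationMap
from .stimuli import TaxelFrame, TrialRecord

__all__ = [
    "K1_SA",
    "K2_NOC",
    "K3_RA",
    "IzhikevichParams",
    "NeuronState",
    "NociceptorSpec",
    "SpikeTrain",
    "PopulationResponse",
    "izhikevich_step",
    "izhikevich_run",
    "ra_front_end",
    "nociceptor_input",
    "nociceptor_gains",
    "encode_trial",
    "encode_dataset",
    "save_response",
    "load_response",
]

# Input gains (all powers of two, exact in Q13.18).
K1_SA = 1 / 32
K2_NOC = 1 / 8
K3_RA = 128.0

#: Rescaled drift coefficients, shared by every afferent class.
_QUAD, _LIN, _CONST = 1 / 32, 4.0, 109.375

#: Hyperpolarization floor (mV), about the K+ reversal potential.  Also
#: guards the 1 ms Euler map: after a strong burst the recovery variable is
#: large and an unclamped membrane would undershoot far below rest, where
#: the quadratic term catapults it back over threshold in one step —
#: spurious self-sustained ringing that the floor removes.
V_FLOOR = -90.0

#: Interface ADC-to-current conversion for the SA-I / RA-I paths (counts to
#: current units, a power of two).  Calibrated so that a blunt contact's
#: per-field drive sits comfortably above the regular-spiking rheobase
#: (~6.1), making the population rate grow with contact area.
AFFERENT_CURRENT_PER_COUNT = 8.0


@dataclass(frozen=True)
class IzhikevichParams:
    """Constants of one neuron: recovery rate a, coupling b, reset c, jump d.

    ``k_scale`` multiplies the input current; ``cm`` (1 F) keeps dimensions
    consistent; spikes are cut off at ``v_thresh`` = 30 mV.
    """

    a: float
    b: float
    c: float
    d: float
    k_scale: float = 1.0
    cm: float = 1.0
    v_thresh: float = 30.0

    @classmethod
    def regular_spiking(cls, k_scale: float = K1_SA) -> "IzhikevichParams":
        """RS preset (a=0.02, b=0.2, c=-65, d=8): SA-I and RA-I afferents."""
        return cls(a=0.02, b=0.2, c=-65.0, d=8.0, k_scale=k_scale)

    @classmethod
    def fast_spiking(cls, k_scale: float = K2_NOC) -> "IzhikevichParams":
        """FS preset (a=0.1, b=0.2, c=-65, d=2): nociceptors."""
        return cls(a=0.1, b=0.2, c=-65.0, d=2.0, k_scale=k_scale)


@dataclass(frozen=True)
class NeuronState:
    v: float
    u: float


def initial_state(params: IzhikevichParams) -> NeuronState:
    """Rest initialization v = c, u = b*c."""
    return NeuronState(v=params.c, u=params.b * params.c)


def izhikevich_step(
    state: NeuronState, I: float, params: IzhikevichParams
) -> tuple[NeuronState, bool]:
    """One 1 ms Euler step; returns the new state and whether it spiked.

    The recovery update uses the pre-update membrane potential; on a spike
    the reset writes v <- c and u <- u_pre + d.
    """
    if not (math.isfinite(state.v) and math.isfinite(state.u) and math.isfinite(I)):
        raise ValueError("non-finite neuron state or input")
    v, u = state.v, state.u
    v1 = v + (_QUAD * v * v + _LIN * v + _CONST - u + params.k_scale * I / params.cm)
    u1 = u + params.a * (params.b * v - u)
    spiked = v1 >= params.v_thresh
    if spiked:
        v1 = params.c
        u1 = u + params.d
    v1 = max(v1, V_FLOOR)
    return NeuronState(v=v1, u=u1), bool(spiked)


def izhikevich_run(
    drive: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    v_thresh: float = 30.0,
) -> np.ndarray:
    """Simulate a bank of neurons from rest; vectorized across channels.

    ``drive`` has shape (n_channels, n_steps) and already includes the
    class gain (it is the full ``k_s I / C_m`` term).  Returns a boolean
    (n_channels, n_steps) spike raster; a spike at step ``n`` means the
    membrane crossed threshold at time ``n + 1`` ms.
    """
    drive = np.atleast_2d(np.asarray(drive, dtype=float))
    n, T = drive.shape
    a, b, c, d = (np.broadcast_to(np.asarray(x, float), (n,)).copy() for x in (a, b, c, d))
    v = c.copy()
    u = b * c
    spikes = np.zeros((n, T), dtype=bool)
    for t in range(T):
        v1 = v + (_QUAD * v * v + _LIN * v + _CONST - u + drive[:, t])
        u1 = u + a * (b * v - u)
        sp = v1 >= v_thresh
        spikes[:, t] = sp
        v = np.maximum(np.where(sp, c, v1), V_FLOOR)
        u = np.where(sp, u + d, u1)
    return spikes


def _izhikevich_run_fixed(
    drive: np.ndarray, params: IzhikevichParams
) -> np.ndarray:
    """Q13.18 fixed-point simulation of one channel; drive already k-scaled."""
    quad = fx.to_fixed(_QUAD)
    const = fx.to_fixed(_CONST)
    a_fx, b_fx, d_fx = fx.to_fixed(params.a), fx.to_fixed(params.b), fx.to_fixed(params.d)
    c_fx = fx.to_fixed(params.c)
    thresh = fx.to_fixed(params.v_thresh)
    floor = fx.to_fixed(V_FLOOR)
    v = c_fx
    u = fx.fx_mul(b_fx, c_fx)
    out = np.zeros(len(drive), dtype=bool)
    for t, I in enumerate(drive):
        vv = fx.fx_mul(quad, fx.fx_mul(v, v))
        lin = fx.fx_add(v << 2, const)  # 4v + 109.375; shift is exact
        dv = fx.fx_add(fx.fx_sub(fx.fx_add(vv, lin), u), fx.to_fixed(I))
        v1 = fx.fx_add(v, dv)
        u1 = fx.fx_add(u, fx.fx_mul(a_fx, fx.fx_sub(fx.fx_mul(b_fx, v), u)))
        if v1 >= thresh:
            out[t] = True
            v1 = c_fx
            u1 = fx.fx_add(u, d_fx)
        v, u = max(v1, floor), u1
    return out


def ra_front_end(drive_series: Sequence[float] | np.ndarray, k3: float = K3_RA) -> np.ndarray:
    """Rectified derivative front-end of the RA-I afferent.

    Returns ``k3 * |I[n+1] - I[n]|`` (full-wave rectification, so both onset
    and offset excite), one element shorter than the input.  Constant input
    maps to zero: RA-I is silent during the hold phase.
    """
    x = np.asarray(drive_series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("drive_series must be 1-D with at least 2 samples")
    return k3 * np.abs(np.diff(x))


@dataclass(frozen=True)
class NociceptorSpec:
    """Nociceptor input rule: MCV / NoT over suprathreshold taxels.

    ``threshold_adc`` is the count a taxel must exceed to enter NoT; the
    default (512, half of full scale) leaves blunt contacts silent while
    sharp ones — few taxels, high pressure — drive a large input.
    ``current_per_count`` is the interface circuit's ADC-to-current
    conversion for the nociceptor path (a power of two, so a shift in
    hardware), calibrated to place the MCV/NoT drive on the graded part of
    the fast-spiking f-I curve.
    """

    threshold_adc: int = 512
    n_noc: int = 5
    current_per_count: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.threshold_adc <= 1023:
            raise ValueError("threshold_adc must be in (0, 1023]")


def nociceptor_input(
    frame: TaxelFrame | np.ndarray,
    spec: NociceptorSpec | None = None,
    shift_division: bool = False,
) -> float:
    """MCV/NoT statistic of one frame; 0 when no taxel exceeds threshold.

    With ``shift_division`` the division is emulated as the FPGA's
    right-shift by ceil(log2(NoT)).
    """
    spec = spec or NociceptorSpec()
    values = frame.values if isinstance(frame, TaxelFrame) else np.asarray(frame)
    not_count = int((values > spec.threshold_adc).sum())
    if not_count == 0:
        return 0.0
    mcv = float(values.max())
    if shift_division:
        return mcv / (1 << math.ceil(math.log2(not_count)))
    return mcv / not_count


def nociceptor_gains(n_noc: int = 5, seed: int = 0, spread: float = 0.05) -> np.ndarray:
    """Per-channel input gains 1 ± spread (seeded) so the five nociceptors,
    which share one input signal, do not produce bit-identical rasters."""
    rng = np.random.default_rng(seed)
    return 1.0 + spread * rng.uniform(-1.0, 1.0, size=n_noc)


@dataclass(frozen=True)
class SpikeTrain:
    channel_id: int
    kind: str  # "SA1" | "RA1" | "NOC"
    times_ms: np.ndarray  # strictly increasing ints

    @property
    def n_spikes(self) -> int:
        return len(self.times_ms)


@dataclass(frozen=True)
class PopulationResponse:
    """One trial's spike trains, channels ordered NOC, SA-I, RA-I."""

    trains: tuple[SpikeTrain, ...]
    duration_ms: int

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(t.kind for t in self.trains)

    def by_kind(self, kinds: Sequence[str]) -> "PopulationResponse":
        keep = tuple(t for t in self.trains if t.kind in kinds)
        return PopulationResponse(trains=keep, duration_ms=self.duration_ms)


def _drive_terms(
    trial: TrialRecord,
    imap: InnervationMap,
    noc: NociceptorSpec,
    noc_gain: np.ndarray,
    shift_division: bool = False,
) -> np.ndarray:
    """(n_noc + n_sa + n_ra, T-1) pre-scaled input terms, channel order NOC, SA, RA."""
    frames = trial.frames
    if frames.shape[1:] != imap.fields[0].weights.shape:
        raise ValueError("trial grid does not match innervation map grid")
    T = frames.shape[0]
    flat = frames.reshape(T, -1).astype(float)
    W = imap.weight_stack().reshape(len(imap.fields), -1)
    drives = AFFERENT_CURRENT_PER_COUNT * (W @ flat.T)  # (n_fields, T)

    sa_term = K1_SA * drives[: imap.n_sa, : T - 1]
    ra_term = np.abs(np.diff(drives[imap.n_sa :], axis=1)) * K3_RA

    vals = flat
    not_count = (vals > noc.threshold_adc).sum(axis=1)
    mcv = vals.max(axis=1)
    if shift_division:
        shifts = np.array([1 << math.ceil(math.log2(n)) if n > 0 else 1 for n in not_count])
        base = np.where(not_count > 0, mcv / shifts, 0.0)
    else:
        base = np.where(not_count > 0, mcv / np.maximum(not_count, 1), 0.0)
    noc_term = K2_NOC * noc.current_per_count * noc_gain[:, None] * base[None, : T - 1]
    return np.vstack([noc_term, sa_term, ra_term])


def _raster_to_response(spikes: np.ndarray, kinds: list[str], duration: int) -> PopulationResponse:
    trains = tuple(
        SpikeTrain(channel_id=i, kind=k, times_ms=np.flatnonzero(spikes[i]) + 1)
        for i, k in enumerate(kinds)
    )
    return PopulationResponse(trains=trains, duration_ms=duration)


def _channel_kinds(n_noc: int, imap: InnervationMap) -> list[str]:
    return ["NOC"] * n_noc + ["SA1"] * imap.n_sa + ["RA1"] * imap.n_ra


def _channel_params(n_noc: int, imap: InnervationMap) -> tuple[np.ndarray, ...]:
    fs = IzhikevichParams.fast_spiking()
    rs = IzhikevichParams.regular_spiking()
    n_rs = imap.n_sa + imap.n_ra
    a = np.r_[np.full(n_noc, fs.a), np.full(n_rs, rs.a)]
    b = np.r_[np.full(n_noc, fs.b), np.full(n_rs, rs.b)]
    c = np.r_[np.full(n_noc, fs.c), np.full(n_rs, rs.c)]
    d = np.r_[np.full(n_noc, fs.d), np.full(n_rs, rs.d)]
    return a, b, c, d


def encode_trial(
    trial: TrialRecord,
    imap: InnervationMap,
    noc: NociceptorSpec | None = None,
    noc_gain_seed: int = 0,
    noc_gain: np.ndarray | None = None,
    fixed_point: bool = False,
) -> PopulationResponse:
    """Encode one trial into the population spike response.

    Channel order is NOC x n_noc, SA-I x n_sa, RA-I x n_ra (23 channels in
    the default configuration).  All neurons start from rest (v = c,
    u = b*c); the encoding is fully deterministic.  With ``fixed_point``
    both the MCV/NoT division (as a right shift) and the Euler updates run
    in Q13.18 arithmetic.
    """
    noc = noc or NociceptorSpec()
    if noc_gain is None:
        noc_gain = nociceptor_gains(noc.n_noc, seed=noc_gain_seed)
    terms = _drive_terms(trial, imap, noc, noc_gain, shift_division=fixed_point)
    kinds = _channel_kinds(noc.n_noc, imap)
    duration = trial.frames.shape[0] - 1
    if fixed_point:
        fs = IzhikevichParams.fast_spiking()
        rs = IzhikevichParams.regular_spiking()
        spikes = np.zeros(terms.shape, dtype=bool)
        for i, kind in enumerate(kinds):
            spikes[i] = _izhikevich_run_fixed(terms[i], fs if kind == "NOC" else rs)
    else:
        spikes = izhikevich_run(terms, *_channel_params(noc.n_noc, imap))
    return _raster_to_response(spikes, kinds, duration)


def encode_dataset(
    trials: Sequence[TrialRecord],
    imap: InnervationMap,
    noc: NociceptorSpec | None = None,
    noc_gain_seed: int = 0,
    fixed_point: bool = False,
) -> list[PopulationResponse]:
    """Encode many trials; the floating-point path batches every neuron of
    every trial into one vectorized simulation."""
    noc = noc or NociceptorSpec()
    gains = nociceptor_gains(noc.n_noc, seed=noc_gain_seed)
    if fixed_point:
        return [
            encode_trial(tr, imap, noc, noc_gain=gains, fixed_point=True) for tr in trials
        ]
    terms = [_drive_terms(tr, imap, noc, gains) for tr in trials]
    n_ch = terms[0].shape[0]
    lengths = [t.shape[1] for t in terms]
    if len(set(lengths)) == 1:
        big = np.vstack(terms)
        a, b, c, d = _channel_params(noc.n_noc, imap)
        A = np.tile(a, len(trials))
        B = np.tile(b, len(trials))
        C = np.tile(c, len(trials))
        D = np.tile(d, len(trials))
        spikes = izhikevich_run(big, A, B, C, D)
        kinds = _channel_kinds(noc.n_noc, imap)
        return [
            _raster_to_response(
                spikes[i * n_ch : (i + 1) * n_ch], kinds, trials[i].frames.shape[0] - 1
            )
            for i in range(len(trials))
        ]
    return [encode_trial(tr, imap, noc, noc_gain=gains) for tr in trials]


# --- serialization --------------------------------------------------------

def save_response(response: PopulationResponse, path: str | Path) -> Path:
    """Write one trial's spikes as a tabular event stream (CSV)."""
    rows = [
        (t.channel_id, t.kind, int(ms))
        for t in response.trains
        for ms in t.times_ms
    ]
    df = pd.DataFrame(rows, columns=["channel_id", "kind", "spike_time_ms"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_response(path: str | Path, n_channels: int = 23, duration_ms: int = 2500,
                  kinds: Sequence[str] | None = None) -> PopulationResponse:
    """Read a response written by :func:`save_response`."""
    df = pd.read_csv(path)
    kind_map = dict(zip(df["channel_id"], df["kind"]))
    trains = []
    for ch in range(n_channels):
        times = np.sort(df.loc[df["channel_id"] == ch, "spike_time_ms"].to_numpy())
        kind = kind_map.get(ch) or (kinds[ch] if kinds else "SA1")
        trains.append(SpikeTrain(channel_id=ch, kind=kind, times_ms=times.astype(int)))
    return PopulationResponse(trains=tuple(trains), duration_ms=duration_ms)
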