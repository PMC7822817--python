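"""Synthetic tactile stimuli: trapezoidal indentation of 3D-printed objects.

Emulates the robotic experiment: a 5x5 piezoresistive taxel array (2.8 mm
pitch, 10-bit ADC, 1 ms sampling) is pressed onto cones and cubes of varying
sharpness along a trapezoidal depth profile (250 ms onset, 2000 ms hold,
250 ms offset).  Sharp objects concentrate the contact force on few taxels
at high pressure; blunt objects spread it over many taxels at low pressure.

Contact mechanics are deliberately minimal: the indentation force grows
linearly with depth, is distributed uniformly over the object's geometric
footprint (a disc the apex diameter for cones; a 20 mm x width bar for the
cuboids, whose contact face is their long edge), dispersed laterally by a
Gaussian kernel standing in for the silicone cover layer, and integrated
over each taxel's cell.  No elastic skin simulation is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

__all__ = [
    "GridSpec",
    "StimulusObject",
    "IndentationProfile",
    "TaxelFrame",
    "TrialRecord",
    "DEFAULT_OBJECTS",
    "contact_footprint",
    "trapezoid_depth",
    "generate_trial",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry and quantization of the taxel array."""

    rows: int = 5
    cols: int = 5
    pitch_mm: float = 2.8
    adc_bits: int = 10

    @property
    def full_scale(self) -> int:
        return 2**self.adc_bits - 1

    @property
    def n_taxels(self) -> int:
        return self.rows * self.cols

    def taxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of taxel centers, grid centered on the origin."""
        x = (np.arange(self.cols) - (self.cols - 1) / 2) * self.pitch_mm
        y = (np.arange(self.rows) - (self.rows - 1) / 2) * self.pitch_mm
        return x, y


@dataclass(frozen=True)
class StimulusObject:
    """A 3D-printed indenter: cone (Group-I) or cube (Group-II).

    ``feature_size_mm`` is the cone apex diameter or the cube width; the
    default object set uses 1, 3, 5 and 9 mm.  Smaller feature size means a
    sharper object.  Cones (20 mm base) touch the sensor with a disc the
    size of their flattened apex; the cuboids are 20 mm long, so their
    contact face is a 20 mm x width bar across the array — at 1 mm width,
    an edge.
    """

    shape: str  # "cone" | "cube"
    feature_size_mm: float

    def __post_init__(self) -> None:
        if self.shape not in ("cone", "cube"):
            raise ValueError(f"shape must be 'cone' or 'cube', got {self.shape!r}")
        if self.feature_size_mm <= 0:
            raise ValueError("feature_size_mm must be positive")

    @property
    def group(self) -> str:
        return "I" if self.shape == "cone" else "II"

    @property
    def label(self) -> str:
        return f"{self.shape}_{self.feature_size_mm:g}mm"


DEFAULT_OBJECTS: tuple[StimulusObject, ...] = tuple(
    StimulusObject(shape, s) for shape in ("cone", "cube") for s in (1.0, 3.0, 5.0, 9.0)
)


@dataclass(frozen=True)
class IndentationProfile:
    """Trapezoidal indentation: linear onset ramp, constant hold, linear offset."""

    onset_ms: int = 250
    hold_ms: int = 2000
    offset_ms: int = 250
    depth_mm: float = 1.4

    def __post_init__(self) -> None:
        if min(self.onset_ms, self.hold_ms, self.offset_ms) < 0:
            raise ValueError("profile durations must be non-negative")
        if self.depth_mm <= 0:
            raise ValueError("depth_mm must be positive")

    @property
    def total_ms(self) -> int:
        return self.onset_ms + self.hold_ms + self.offset_ms

    def depth_at(self, t_ms: np.ndarray | float) -> np.ndarray:
        """Indentation depth (mm) at time(s) ``t_ms``; zero outside [0, total]."""
        t = np.asarray(t_ms, dtype=float)
        d = np.zeros_like(t)
        if self.onset_ms > 0:
            ramp = t / self.onset_ms
            d = np.where((t >= 0) & (t < self.onset_ms), ramp, d)
        hold_end = self.onset_ms + self.hold_ms
        d = np.where((t >= self.onset_ms) & (t <= hold_end), 1.0, d)
        if self.offset_ms > 0:
            down = (self.total_ms - t) / self.offset_ms
            d = np.where((t > hold_end) & (t <= self.total_ms), down, d)
        return self.depth_mm * d


@dataclass(frozen=True)
class TaxelFrame:
    """One 5x5 snapshot of ADC counts at a time stamp."""

    t_ms: int
    values: np.ndarray  # (rows, cols) integer counts


@dataclass
class TrialRecord:
    """One indentation trial: object, profile and the full frame sequence.

    ``frames`` is an ``(n_frames, rows, cols)`` integer array sampled at
    1 ms; ``n_frames = total_ms + 1`` (both endpoints included).
    """

    object: StimulusObject
    profile: IndentationProfile
    frames: np.ndarray
    seed: int
    grid: GridSpec = field(default_factory=GridSpec)
    fault: object | None = None  # faults.FaultSpec once faults are applied

    @property
    def duration_ms(self) -> int:
        return self.frames.shape[0] - 1

    def iter_frames(self) -> Iterator[TaxelFrame]:
        for t, v in enumerate(self.frames):
            yield TaxelFrame(t_ms=t, values=v)


# --- contact mechanics ----------------------------------------------------

#: Lateral dispersion (mm, Gaussian sigma) of the silicone cover layer.
DISPERSION_SIGMA_MM = 1.2

#: Sub-grid sampling step (mm) for footprint integration.
_SUBGRID_STEP_MM = 0.1

#: ADC counts per (mm indentation): calibrated once, from geometry alone, so
#: that the sharpest default object (1 mm cone) at 1.4 mm depth drives its
#: peak taxel to (slightly beyond) full scale — a calibrated sensor uses the
#: whole 10-bit range and saturates on the most concentrated contact, so
#: part of a sharp object's force is lost to clipping, as with a real ADC.
ADC_GAIN_COUNTS_PER_MM = 2048.0

#: Cuboid contact-face length (mm): the objects are 20 mm long, so cubes
#: touch the array as a 20 mm x width bar.
BAR_LENGTH_MM = 20.0

#: Total-force ratio of a bar contact to a cone contact at equal depth: the
#: long edge recruits far more material than a point, so displacement-
#: controlled indentation meets a stiffer contact.  Calibrated (once, from
#: geometry) so the 1 mm-wide edge also drives its peak taxels near full
#: scale.
BAR_FORCE_FACTOR = 2.5


def contact_footprint(
    obj: StimulusObject,
    depth_mm: float,
    grid: GridSpec | None = None,
    center_offset_mm: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Per-taxel pressure (ADC counts, unquantized) for a static indentation.

    The total force ``ADC_GAIN_COUNTS_PER_MM * depth_mm`` is spread uniformly
    over the object's geometric footprint, blurred by the silicone dispersion
    kernel and integrated over each 2.8 mm taxel cell.  Consequences: summed
    pressure grows with depth and is nearly independent of feature size,
    while sharper objects load fewer taxels at higher peak pressure.
    """
    grid = grid or GridSpec()
    if depth_mm < 0:
        raise ValueError("depth_mm must be non-negative")
    if depth_mm == 0:
        return np.zeros((grid.rows, grid.cols))

    ox, oy = center_offset_mm
    half_x = grid.cols * grid.pitch_mm / 2
    half_y = grid.rows * grid.pitch_mm / 2
    if obj.shape == "cone":
        rx = ry = obj.feature_size_mm / 2
    else:
        rx, ry = BAR_LENGTH_MM / 2, obj.feature_size_mm / 2
    if abs(ox) - rx > half_x or abs(oy) - ry > half_y:
        warnings.warn("contact footprint entirely off-grid; returning zero pressure")
        return np.zeros((grid.rows, grid.cols))

    # Sub-grid covering the array plus room for footprint + blur tails.
    margin = max(rx, ry) + 4 * DISPERSION_SIGMA_MM
    h = _SUBGRID_STEP_MM
    xs = np.arange(-(half_x + margin), half_x + margin + h, h)
    ys = np.arange(-(half_y + margin), half_y + margin + h, h)
    X, Y = np.meshgrid(xs, ys)

    if obj.shape == "cone":
        inside = (X - ox) ** 2 + (Y - oy) ** 2 <= rx**2
        total_force = ADC_GAIN_COUNTS_PER_MM * depth_mm
    else:
        inside = (np.abs(X - ox) <= rx) & (np.abs(Y - oy) <= ry)
        total_force = BAR_FORCE_FACTOR * ADC_GAIN_COUNTS_PER_MM * depth_mm
    if not inside.any():  # degenerate: footprint smaller than one sub-cell
        i = np.argmin((ys - oy) ** 2)
        j = np.argmin((xs - ox) ** 2)
        inside = np.zeros_like(X, dtype=bool)
        inside[i, j] = True

    density = inside / inside.sum()  # unit total, per sub-cell
    density = gaussian_filter(density, sigma=DISPERSION_SIGMA_MM / h, mode="constant")

    # Integrate the dispersed density over each taxel cell.
    cx, cy = grid.taxel_centers_mm()
    pressure = np.zeros((grid.rows, grid.cols))
    half_p = grid.pitch_mm / 2
    for i, yc in enumerate(cy):
        row_mask = (ys >= yc - half_p) & (ys < yc + half_p)
        for j, xc in enumerate(cx):
            col_mask = (xs >= xc - half_p) & (xs < xc + half_p)
            pressure[i, j] = density[np.ix_(row_mask, col_mask)].sum()
    return total_force * pressure


def trapezoid_depth(profile: IndentationProfile) -> np.ndarray:
    """Depth (mm) at each 1 ms sample, ``total_ms + 1`` entries."""
    t = np.arange(profile.total_ms + 1)
    return profile.depth_at(t)


def generate_trial(
    obj: StimulusObject,
    profile: IndentationProfile | None = None,
    grid: GridSpec | None = None,
    noise_sd: float = 0.0,
    jitter_mm: float = 1.0,
    force_scale_sd: float = 0.02,
    seed: int = 0,
) -> TrialRecord:
    """Simulate one indentation trial as a sequence of quantized ADC frames.

    Trial-to-trial variability comes from a per-trial uniform jitter of the
    contact center (default up to ±1 mm per axis, imperfect repositioning)
    and a per-trial Gaussian scaling of the contact force (default sd 2%,
    calibration drift).  ``noise_sd`` adds optional per-frame white sensor
    noise in counts; it defaults to zero because the real readout's flicker
    is sub-LSB at 1 kHz — see the package methods note.  Frames are clipped
    to the ADC range and rounded to integer counts.  Fully deterministic
    under *seed*.
    """
    profile = profile or IndentationProfile()
    grid = grid or GridSpec()
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    offset = tuple(rng.uniform(-jitter_mm, jitter_mm, size=2)) if jitter_mm > 0 else (0.0, 0.0)
    scale = max(1.0 + force_scale_sd * rng.standard_normal(), 0.1) if force_scale_sd > 0 else 1.0

    unit = contact_footprint(obj, profile.depth_mm, grid, offset) / profile.depth_mm
    depth = trapezoid_depth(profile)
    frames = scale * unit[None, :, :] * depth[:, None, None]
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    frames = np.clip(np.rint(frames), 0, grid.full_scale).astype(np.int16)
    return TrialRecord(object=obj, profile=profile, frames=frames, seed=seed, grid=grid)


def generate_dataset(
    objects: Sequence[StimulusObject] = DEFAULT_OBJECTS,
    n_trials_per_object: int = 10,
    profile: IndentationProfile | None = None,
    grid: GridSpec | None = None,
    noise_sd: float = 0.0,
    jitter_mm: float = 1.0,
    force_scale_sd: float = 0.02,
    master_seed: int = 0,
) -> list[TrialRecord]:
    """Generate the full experiment: every object touched ``n`` times.

    Per-trial seeds derive deterministically from ``master_seed``; the
    default configuration (8 objects x 10 trials) yields 80 trials.
    """
    if len(objects) == 0:
        raise ValueError("objects must be non-empty")
    if n_trials_per_object < 1:
        raise ValueError("n_trials_per_object must be >= 1")
    rng = np.random.default_rng(master_seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(objects) * n_trials_per_object)
    trials = []
    k = 0
    for obj in objects:
        for _ in range(n_trials_per_object):
            trials.append(
                generate_trial(
                    obj, profile, grid, noise_sd, jitter_mm, force_scale_sd, seed=int(seeds[k])
                )
            )
            k += 1
    return trials


# --- serialization --------------------------------------------------------

def save_dataset(trials: Sequence[TrialRecord], out_dir: str | Path) -> Path:
    """Write trials as CSV tables plus a YAML manifest into *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, tr in enumerate(trials):
        name = f"trial_{i:03d}.csv"
        flat = tr.frames.reshape(tr.frames.shape[0], -1)
        cols = [f"taxel_{r}{c}" for r in range(tr.grid.rows) for c in range(tr.grid.cols)]
        df = pd.DataFrame(flat, columns=cols)
        df.insert(0, "t_ms", np.arange(flat.shape[0]))
        df.to_csv(out / name, index=False)
        manifest.append(
            {
                "file": name,
                "shape": tr.object.shape,
                "feature_size_mm": float(tr.object.feature_size_mm),
                "seed": int(tr.seed),
                "profile": {
                    "onset_ms": tr.profile.onset_ms,
                    "hold_ms": tr.profile.hold_ms,
                    "offset_ms": tr.profile.offset_ms,
                    "depth_mm": float(tr.profile.depth_mm),
                },
                "grid": {
                    "rows": tr.grid.rows,
                    "cols": tr.grid.cols,
                    "pitch_mm": float(tr.grid.pitch_mm),
                    "adc_bits": tr.grid.adc_bits,
                },
            }
        )
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"trials": manifest}, fh, sort_keys=False)
    return out


def load_dataset(in_dir: str | Path) -> list[TrialRecord]:
    """Read a dataset written by :func:`save_dataset`."""
    src = Path(in_dir)
    with open(src / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)["trials"]
    trials = []
    for entry in manifest:
        grid = GridSpec(**entry["grid"])
        profile = IndentationProfile(**entry["profile"])
        obj = StimulusObject(entry["shape"], entry["feature_size_mm"])
        df = pd.read_csv(src / entry["file"])
        frames = df.drop(columns="t_ms").to_numpy(dtype=np.int16)
        frames = frames.reshape(-1, grid.rows, grid.cols)
        trials.append(
            TrialRecord(object=obj, profile=profile, frames=frames, seed=entry["seed"], grid=grid)
        )
    return trials
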