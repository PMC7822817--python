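"""Q13.18 fixed-point arithmetic emulating the FPGA datapath.

32-bit signed two's-complement words: 1 sign bit, 13 integer bits, 18
fractional bits.  Conversion from float rounds to the nearest representable
value; multiplication truncates the extra fractional bits (arithmetic right
shift, the usual FPGA convention); all operations saturate at the
representable range and raise a :class:`FixedPointOverflow` warning when
they do.  The Euler update of the spiking models can run entirely in this
arithmetic, which is how hardware-equivalent spike trains are produced.

All model constants of interest (109.375, 1/32, 1/8, 128) are dyadic
rationals and therefore exact in Q13.18.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "FRAC_BITS",
    "INT_BITS",
    "WORD_BITS",
    "FixedPointOverflow",
    "to_fixed",
    "from_fixed",
    "fx_add",
    "fx_sub",
    "fx_mul",
    "fx_shift_right",
]

FRAC_BITS = 18
INT_BITS = 13
WORD_BITS = 32

_SCALE = 1 << FRAC_BITS
_RAW_MAX = (1 << (WORD_BITS - 1)) - 1  # 2^31 - 1
_RAW_MIN = -(1 << (WORD_BITS - 1))


class FixedPointOverflow(UserWarning):
    """Raised (as a warning) when a value saturates the Q13.18 range."""


def _saturate(raw: int) -> int:
    if raw > _RAW_MAX:
        warnings.warn("Q13.18 overflow: saturating at +max", FixedPointOverflow)
        return _RAW_MAX
    if raw < _RAW_MIN:
        warnings.warn("Q13.18 overflow: saturating at -max", FixedPointOverflow)
        return _RAW_MIN
    return raw


def to_fixed(x: float) -> int:
    """Float -> raw Q13.18 integer, round-to-nearest (half away from zero)."""
    if not np.isfinite(x):
        raise ValueError("cannot represent non-finite value in fixed point")
    raw = int(np.floor(x * _SCALE + 0.5))
    return _saturate(raw)


def from_fixed(raw: int) -> float:
    return raw / _SCALE


def fx_add(a: int, b: int) -> int:
    return _saturate(a + b)


def fx_sub(a: int, b: int) -> int:
    return _saturate(a - b)


def fx_mul(a: int, b: int) -> int:
    # Python's >> on negative ints is an arithmetic shift (floor), matching
    # two's-complement truncation of the low fractional bits.
    return _saturate((a * b) >> FRAC_BITS)


def fx_shift_right(a: int, n: int) -> int:
    """Arithmetic right shift: division by 2**n, the FPGA's divider."""
    return a >> n
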