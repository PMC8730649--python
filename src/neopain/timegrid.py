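"""The 0.2 s coding time grid.

The coding key samples indicator presence at 200 ms resolution, so every
event boundary, epoch boundary and stored duration in this package lives on
a grid of 0.2 s. Grid arithmetic is done on integer *ticks* (1 tick =
0.2 s); a time in seconds is ``ticks / 5``, which is exact in binary
floating point whenever the second count is (e.g. 150 ticks -> 30.0).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import NegativeTimeError, OffGridTimeError

#: Seconds per grid tick.
QUANTUM_S = 0.2

#: Ticks per second (inverse of the quantum).
TICKS_PER_S = 5

#: Absolute slack (in ticks) when deciding whether a float is on-grid.
_GRID_TOL = 1e-6


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid; fixed at the 200 ms coding-key resolution."""

    quantum_s: float = QUANTUM_S

    def __post_init__(self) -> None:
        if self.quantum_s <= 0:
            raise ValueError("quantum_s must be positive")


#: The package-wide default grid.
DEFAULT_GRID = TimeGrid()


def quantize_time(t: float, grid: TimeGrid = DEFAULT_GRID) -> float:
    """Snap ``t`` (seconds) to the nearest grid point; ties round up.

    With t >= 0, "away from zero" and "up" coincide. The result moves the
    input by at most half a quantum (0.1 s on the default grid).
    """
    if t < 0:
        raise NegativeTimeError(f"time must be non-negative, got {t}")
    x = t / grid.quantum_s
    ticks = math.floor(x + 0.5)
    return ticks * grid.quantum_s if grid.quantum_s != QUANTUM_S else ticks / TICKS_PER_S


def to_ticks(t: float) -> int:
    """Convert an on-grid time in seconds to integer ticks.

    Raises :class:`OffGridTimeError` when ``t`` is not a multiple of 0.2 s
    (beyond float slack).
    """
    x = t * TICKS_PER_S
    ticks = round(x)
    if abs(x - ticks) > _GRID_TOL:
        raise OffGridTimeError(f"{t} s is not on the 0.2 s grid")
    return ticks


def from_ticks(ticks: int) -> float:
    """Ticks back to seconds (exact where the second count is representable)."""
    return ticks / TICKS_PER_S


def is_on_grid(t: float) -> bool:
    """True when ``t`` is a multiple of 0.2 s within float slack."""
    x = t * TICKS_PER_S
    return abs(x - round(x)) <= _GRID_TOL
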