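"""Abridged age grids.

An :class:`AgeGrid` is a strictly increasing sequence of exact ages that
starts a set of age intervals, the last of which is open-ended (e.g. the
standard gerontological grid 60-64, 65-69, 70-74, 75-79, 80+).  All life
table, prevalence and health-expectancy objects in this package are aligned
on such a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import GridMismatchError, ValidationError

__all__ = ["AgeGrid", "DEFAULT_STARTS"]

DEFAULT_STARTS = (60, 65, 70, 75, 80)


@dataclass(frozen=True)
class AgeGrid:
    """Exact ages opening each interval; the last interval is open-ended.

    Parameters
    ----------
    starts
        Strictly increasing exact ages.  Closed-interval widths are the
        successive differences; the terminal interval has no width.
    """

    starts: tuple = field(default=DEFAULT_STARTS)

    def __init__(self, starts: Iterable[float] = DEFAULT_STARTS) -> None:
        starts = tuple(float(s) for s in starts)
        if len(starts) < 1:
            raise ValidationError("an age grid needs at least one interval")
        diffs = np.diff(starts)
        if np.any(diffs <= 0):
            raise ValidationError(f"grid starts must be strictly increasing, got {starts}")
        object.__setattr__(self, "starts", starts)

    # -- basic geometry -------------------------------------------------
    def __len__(self) -> int:
        return len(self.starts)

    @property
    def n_intervals(self) -> int:
        return len(self.starts)

    @property
    def closed_widths(self) -> np.ndarray:
        """Widths ``n_i`` of the closed intervals (length ``len(self) - 1``)."""
        return np.diff(np.asarray(self.starts, dtype=float))

    @property
    def widths(self) -> np.ndarray:
        """Widths with ``inf`` in the terminal slot."""
        return np.append(self.closed_widths, np.inf)

    @property
    def exact_ages(self) -> np.ndarray:
        return np.asarray(self.starts, dtype=float)

    @property
    def terminal_start(self) -> float:
        return self.starts[-1]

    def labels(self) -> list[str]:
        """Human-readable interval labels, e.g. ``['60-64', ..., '80+']``."""
        out = []
        for s, w in zip(self.starts[:-1], self.closed_widths):
            if float(s).is_integer() and float(w).is_integer():
                out.append(f"{int(s)}-{int(s + w) - 1}")
            else:
                out.append(f"[{s:g},{s + w:g})")
        last = self.starts[-1]
        out.append(f"{int(last)}+" if float(last).is_integer() else f"{last:g}+")
        return out

    # -- behaviour ------------------------------------------------------
    def assert_same(self, other: "AgeGrid", what: str = "grids") -> None:
        if self.starts != other.starts:
            raise GridMismatchError(f"{what} differ: {self.starts} vs {other.starts}")

    def group_index(self, ages: Sequence[float]) -> np.ndarray:
        """Interval index for each age; ``-1`` for ages below the first start.

        Intervals are left-closed: age 65.0 belongs to 65-69, the terminal
        interval absorbs everything from its start upward.
        """
        ages = np.asarray(ages, dtype=float)
        idx = np.searchsorted(self.exact_ages, ages, side="right") - 1
        return idx.astype(int)

    @classmethod
    def default(cls) -> "AgeGrid":
        return cls(DEFAULT_STARTS)
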