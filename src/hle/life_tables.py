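"""Abridged period life tables with sampling variances (Chiang method).

The central death rate in each interval, ``m_i = D_i / P_i``, is converted
to a conditional probability of dying with the a-fraction formula

    q_i = n_i * m_i / (1 + (n_i - a_i) * m_i)

where ``a_i`` is the average fraction of the interval lived by those who die
in it (default ``n_i / 2``, the standard assumption at adult ages).  The
terminal open-ended interval has ``q = 1`` and person-years ``L = l / m``.
Sampling variances follow the classical binomial/delta-method treatment:

    var(q_i) = q_i^2 (1 - q_i) / D_i
    var(e_x) = sum_{j >= x} l_j^2 [(n_j - a_j) + e_{j+1}]^2 var(q_j) / l_x^2

with an optional Poisson term ``l_w^2 e_w^2 / D_w`` for the open interval
(treating ``e_w = 1/m_w`` with Poisson-distributed deaths).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateTableError, ValidationError
from .grids import AgeGrid
from .comparison import GroupComparison, wald_difference

__all__ = [
    "MortalityInput",
    "LifeTable",
    "average_deaths",
    "build_abridged_life_table",
    "life_expectancy_difference",
]

logger = logging.getLogger(__name__)

DEFAULT_RADIX = 100_000.0
Z95 = 1.96


@dataclass
class MortalityInput:
    """Death and mid-period population counts on an abridged age grid.

    ``deaths`` may be non-integer (e.g. a multi-year average); ``population``
    is the single mid-period count used as person-years of exposure.
    """

    grid: AgeGrid
    deaths: np.ndarray
    population: np.ndarray
    sex: str = ""
    period: str = ""

    def __post_init__(self) -> None:
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.population = np.asarray(self.population, dtype=float)
        k = len(self.grid)
        if self.deaths.shape != (k,) or self.population.shape != (k,):
            raise ValidationError(
                f"deaths/population must have length {k} to match the grid, "
                f"got {self.deaths.shape} and {self.population.shape}"
            )
        if np.any(self.deaths < 0):
            raise ValidationError("death counts must be non-negative")
        if np.any(self.population <= 0):
            raise ValidationError("population counts must be strictly positive")

    @property
    def rates(self) -> np.ndarray:
        """Central death rates m_i = D_i / P_i (per person-year)."""
        return self.deaths / self.population


@dataclass
class LifeTable:
    """Chiang abridged life table columns plus variance columns.

    All arrays are aligned with ``grid``; the last entry belongs to the
    open-ended interval.  ``ci_low``/``ci_high`` bound the life expectancy
    at each exact age.
    """

    grid: AgeGrid
    sex: str
    radix: float
    m: np.ndarray
    a: np.ndarray  # a-fraction, years; terminal slot holds 1/m (not used in formulas)
    q: np.ndarray
    l: np.ndarray
    d: np.ndarray
    L: np.ndarray
    T: np.ndarray
    e: np.ndarray
    var_q: np.ndarray
    var_e: np.ndarray
    se_e: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    deaths: np.ndarray = field(default=None)  # observed counts behind var_q

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_group": self.grid.labels(),
                "age": self.grid.exact_ages,
                "m": self.m,
                "a": self.a,
                "q": self.q,
                "l": self.l,
                "d": self.d,
                "L": self.L,
                "T": self.T,
                "e": self.e,
                "var_q": self.var_q,
                "var_e": self.var_e,
                "se_e": self.se_e,
                "e_ci_low": self.ci_low,
                "e_ci_high": self.ci_high,
            }
        )


def average_deaths(yearly_deaths: Sequence) -> np.ndarray | MortalityInput:
    """Arithmetic mean of per-year death counts on a common grid.

    Accepts either a sequence of arrays (returns an array) or a sequence of
    :class:`MortalityInput` (returns a ``MortalityInput`` whose population is
    the shared mid-period count).  Used to average a triennium of registered
    deaths around the census/survey year.
    """
    items = list(yearly_deaths)
    if not items:
        raise ValidationError("at least one year of deaths is required")
    if isinstance(items[0], MortalityInput):
        grid = items[0].grid
        for it in items[1:]:
            grid.assert_same(it.grid, "mortality-input grids")
            if not np.allclose(it.population, items[0].population):
                raise ValidationError("mid-period populations differ between years")
        mean = np.mean([it.deaths for it in items], axis=0)
        periods = sorted(p for p in (it.period for it in items) if p)
        return MortalityInput(
            grid=grid,
            deaths=mean,
            population=items[0].population,
            sex=items[0].sex,
            period="-".join((periods[0], periods[-1])) if periods else "",
        )
    arrays = [np.asarray(a, dtype=float) for a in items]
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise ValidationError("yearly death vectors live on different grids")
    if any(np.any(a < 0) for a in arrays):
        raise ValidationError("death counts must be non-negative")
    return np.mean(arrays, axis=0)


def build_abridged_life_table(
    mortality: MortalityInput,
    a: float | Sequence[float] | None = None,
    radix: float = DEFAULT_RADIX,
    z: float = Z95,
    terminal_variance: bool = True,
) -> LifeTable:
    """Construct a Chiang abridged life table from death/population counts.

    Parameters
    ----------
    mortality
        Counts on an abridged grid (last interval open-ended).
    a
        a-fraction for the closed intervals: scalar (years) or one value per
        closed interval.  Default ``n_i / 2``.
    radix
        Survivors at the first exact age; every identity is radix-invariant.
    z
        Normal quantile for the life-expectancy confidence interval.
    terminal_variance
        Include the Poisson delta-method term for the open interval in
        ``var(e)``; switch off to reproduce the purely binomial treatment.
    """
    grid = mortality.grid
    k = len(grid)
    n = grid.closed_widths  # length k-1
    m = mortality.rates
    D = mortality.deaths

    if a is None:
        a_closed = n / 2.0
    else:
        a_closed = np.broadcast_to(np.asarray(a, dtype=float), (k - 1,)).copy()
        if np.any(a_closed <= 0) or np.any(a_closed > n):
            raise ValidationError("a-fractions must lie in (0, n_i] for every closed interval")

    if np.any(D == 0):
        logger.warning(
            "zero deaths in interval(s) %s: q and var_q set to 0 there",
            [grid.labels()[i] for i in np.flatnonzero(D == 0)],
        )

    # probabilities of death
    q = np.empty(k)
    mc = m[:-1]
    q[:-1] = n * mc / (1.0 + (n - a_closed) * mc)
    if np.any(q[:-1] > 1.0):
        logger.warning("q > 1 produced by extreme rates; clipped to 1")
        q[:-1] = np.minimum(q[:-1], 1.0)
    q[-1] = 1.0

    # survivorship and person-years
    l = np.empty(k)
    l[0] = radix
    for i in range(k - 1):
        l[i + 1] = l[i] * (1.0 - q[i])
    d = l * q
    L = np.empty(k)
    L[:-1] = n * l[1:] + a_closed * d[:-1]
    if l[-1] > 1e-12 * radix:
        if m[-1] <= 0:
            raise DegenerateTableError(
                "terminal interval has zero mortality while survivors reach it"
            )
        L[-1] = l[-1] / m[-1]
    else:
        L[-1] = l[-1] / m[-1] if m[-1] > 0 else 0.0

    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, 0.0)

    # sampling variances
    var_q = np.zeros(k)
    closed = slice(0, k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vq = np.where(D[closed] > 0, q[closed] ** 2 * (1.0 - q[closed]) / D[closed], 0.0)
    var_q[closed] = vq

    # per-interval contribution to var(e): closed intervals via var(q),
    # open interval (optionally) via Poisson deaths on e_w = 1/m_w
    contrib = np.zeros(k)
    e_next = np.append(e[1:], 0.0)  # e_{j+1} for closed j
    contrib[closed] = l[closed] ** 2 * ((n - a_closed) + e_next[closed]) ** 2 * var_q[closed]
    if terminal_variance and D[-1] > 0:
        contrib[-1] = l[-1] ** 2 * e[-1] ** 2 / D[-1]
    tail = np.cumsum(contrib[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        var_e = np.where(l > 0, tail / l**2, 0.0)
    se_e = np.sqrt(var_e)

    a_full = np.empty(k)
    a_full[:-1] = a_closed
    a_full[-1] = 1.0 / m[-1] if m[-1] > 0 else np.nan

    return LifeTable(
        grid=grid,
        sex=mortality.sex,
        radix=radix,
        m=m,
        a=a_full,
        q=q,
        l=l,
        d=d,
        L=L,
        T=T,
        e=e,
        var_q=var_q,
        var_e=var_e,
        se_e=se_e,
        ci_low=e - z * se_e,
        ci_high=e + z * se_e,
        deaths=D,
    )


def life_expectancy_difference(
    table_a: LifeTable, table_b: LifeTable, z: float = Z95
) -> GroupComparison:
    """Difference in life expectancy at each exact age, b minus a.

    Variances are summed (independent populations) and a normal interval is
    attached; the difference is significant when the interval excludes 0.
    """
    table_a.grid.assert_same(table_b.grid, "life-table grids")
    return wald_difference(
        quantity="LE",
        ages=table_a.grid.exact_ages,
        value_a=table_a.e,
        value_b=table_b.e,
        var_a=table_a.var_e,
        var_b=table_b.var_e,
        group_a=table_a.sex or "a",
        group_b=table_b.sex or "b",
        z=z,
    )
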