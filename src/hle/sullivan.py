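"""Sullivan decomposition of life expectancy into healthy and unhealthy years.

Age-specific prevalence of an unhealthy state, taken from a cross-sectional
survey, partitions the person-years of a period life table:

    HLE_x  = (1/l_x) * sum_{i >= x} (1 - pi_i) * L_i
    UHLE_x = (1/l_x) * sum_{i >= x} pi_i * L_i

so HLE + UHLE equals total life expectancy at every exact age, and the
proportion of remaining life spent unhealthy is 100 * UHLE_x / e_x.  At the
open-ended exact age this proportion reduces analytically to the terminal
prevalence itself, whatever the life table.

Confidence intervals follow the delta-method treatment of Jagger and
colleagues: by default only the prevalence sampling variance is propagated,

    var(HLE_x) = (1/l_x^2) * sum_{i >= x} L_i^2 * var(pi_i),

which is symmetric in pi vs. 1-pi (var UHLE = var HLE).  A combined mode
adds the life-table (mortality) component using health-weighted survivorship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .comparison import GroupComparison, wald_difference
from .exceptions import ValidationError
from .grids import AgeGrid
from .life_tables import LifeTable, Z95
from .prevalence import PrevalenceTable

__all__ = [
    "HealthExpectancyTable",
    "sullivan_decompose",
    "hle_variance",
    "compare_groups",
]

VARIANCE_MODES = ("prevalence_only", "plus_mortality")


@dataclass
class HealthExpectancyTable:
    """Healthy/unhealthy life expectancy per exact age for one group."""

    grid: AgeGrid
    sex: str
    indicator: str
    hle: np.ndarray
    uhle: np.ndarray
    prop_uhle: np.ndarray  # percent of e_x
    var_hle: np.ndarray
    var_uhle: np.ndarray
    hle_ci_low: np.ndarray
    hle_ci_high: np.ndarray
    uhle_ci_low: np.ndarray
    uhle_ci_high: np.ndarray
    life_table: LifeTable = None
    prevalence: PrevalenceTable = None

    @property
    def e(self) -> np.ndarray:
        return self.hle + self.uhle

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.grid.exact_ages,
                "e": self.e,
                "hle": self.hle,
                "uhle": self.uhle,
                "prop_uhle": self.prop_uhle,
                "var_hle": self.var_hle,
                "var_uhle": self.var_uhle,
                "hle_ci_low": self.hle_ci_low,
                "hle_ci_high": self.hle_ci_high,
                "uhle_ci_low": self.uhle_ci_low,
                "uhle_ci_high": self.uhle_ci_high,
            }
        )


def _check_alignment(lt: LifeTable, prev: PrevalenceTable) -> None:
    lt.grid.assert_same(prev.grid, "life-table and prevalence grids")
    if np.any((prev.prevalence < 0) | (prev.prevalence > 1)):
        raise ValidationError("prevalences must lie in [0, 1]")


def hle_variance(lt: LifeTable, prev: PrevalenceTable, mode: str = "prevalence_only") -> np.ndarray:
    """Variance of HLE at each exact age.

    ``prevalence_only`` propagates the survey sampling variance of the
    age-group prevalences through the (fixed) person-years.  In
    ``plus_mortality`` the life-table uncertainty is added by rerunning the
    Chiang e-variance recursion on the healthy person-years, i.e. each
    closed interval contributes
    ``l_j^2 [(n_j - a_j)(1 - pi_j) + HLE_{j+1}]^2 var(q_j)`` and the open
    interval ``l_w^2 (1 - pi_w)^2 e_w^2 / D_w``, the two sampling sources
    being treated as independent.
    """
    _check_alignment(lt, prev)
    if mode not in VARIANCE_MODES:
        raise ValidationError(f"unknown variance mode {mode!r}; choose from {VARIANCE_MODES}")
    if np.any(~np.isfinite(prev.variance)):
        raise ValidationError("prevalence variances are missing; cannot attach CIs")

    l, L = lt.l, lt.L
    k = len(lt.grid)
    if prev.covariance is not None:
        # full design-based covariance of the age-group prevalences:
        # var(HLE_x) = sum_{i,j >= x} L_i L_j cov(pi_i, pi_j) / l_x^2
        tail_prev = np.array(
            [L[x:] @ prev.covariance[x:, x:] @ L[x:] for x in range(k)]
        )
    else:
        tail_prev = np.cumsum((L**2 * prev.variance)[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(l > 0, tail_prev / l**2, 0.0)

    if mode == "plus_mortality":
        n = lt.grid.closed_widths
        a = lt.a[:-1]
        pi = prev.prevalence
        healthy_tail = np.cumsum(((1.0 - pi) * L)[::-1])[::-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            hle = np.where(l > 0, healthy_tail / l, 0.0)
        hle_next = np.append(hle[1:], 0.0)
        contrib = np.zeros(k)
        contrib[:-1] = l[:-1] ** 2 * ((n - a) * (1.0 - pi[:-1]) + hle_next[:-1]) ** 2 * lt.var_q[:-1]
        D_w = lt.deaths[-1] if lt.deaths is not None else 0.0
        if D_w > 0:
            contrib[-1] = l[-1] ** 2 * (1.0 - pi[-1]) ** 2 * lt.e[-1] ** 2 / D_w
        tail_mort = np.cumsum(contrib[::-1])[::-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            var = var + np.where(l > 0, tail_mort / l**2, 0.0)
    return var


def sullivan_decompose(
    lt: LifeTable,
    prev: PrevalenceTable,
    variance_mode: str = "prevalence_only",
    z: float = Z95,
) -> HealthExpectancyTable:
    """Split the life table's expectancies into healthy and unhealthy years."""
    _check_alignment(lt, prev)
    l, L = lt.l, lt.L
    pi = prev.prevalence
    unhealthy_tail = np.cumsum((pi * L)[::-1])[::-1]
    healthy_tail = np.cumsum(((1.0 - pi) * L)[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        hle = np.where(l > 0, healthy_tail / l, 0.0)
        uhle = np.where(l > 0, unhealthy_tail / l, 0.0)
        e = hle + uhle
        prop = np.where(e > 0, 100.0 * uhle / e, 0.0)

    var_hle = hle_variance(lt, prev, mode=variance_mode)
    if variance_mode == "prevalence_only":
        var_uhle = var_hle  # complement symmetry: var(1 - pi) = var(pi)
    else:
        complement = PrevalenceTable.from_estimates(
            prev.indicator, prev.grid, prev.sex, 1.0 - pi, prev.variance, prev.n
        )
        complement.covariance = prev.covariance
        var_uhle = hle_variance(lt, complement, mode=variance_mode)
    se_h, se_u = np.sqrt(var_hle), np.sqrt(var_uhle)
    return HealthExpectancyTable(
        grid=lt.grid,
        sex=lt.sex or prev.sex,
        indicator=prev.indicator,
        hle=hle,
        uhle=uhle,
        prop_uhle=prop,
        var_hle=var_hle,
        var_uhle=var_uhle,
        hle_ci_low=hle - z * se_h,
        hle_ci_high=hle + z * se_h,
        uhle_ci_low=uhle - z * se_u,
        uhle_ci_high=uhle + z * se_u,
        life_table=lt,
        prevalence=prev,
    )


def compare_groups(
    het_a: HealthExpectancyTable,
    het_b: HealthExpectancyTable,
    quantity: str = "HLE",
    z: float = Z95,
) -> GroupComparison:
    """Between-group (b minus a) difference in HLE or UHLE with a Wald CI."""
    het_a.grid.assert_same(het_b.grid, "health-expectancy grids")
    if het_a.indicator != het_b.indicator:
        raise ValidationError(
            f"indicator mismatch: {het_a.indicator!r} vs {het_b.indicator!r}"
        )
    if quantity == "HLE":
        va, vb = het_a.var_hle, het_b.var_hle
        xa, xb = het_a.hle, het_b.hle
    elif quantity == "UHLE":
        va, vb = het_a.var_uhle, het_b.var_uhle
        xa, xb = het_a.uhle, het_b.uhle
    else:
        raise ValidationError(f"quantity must be 'HLE' or 'UHLE', got {quantity!r}")
    return wald_difference(
        quantity=quantity,
        ages=het_a.grid.exact_ages,
        value_a=xa,
        value_b=xb,
        var_a=va,
        var_b=vb,
        group_a=het_a.sex or "a",
        group_b=het_b.sex or "b",
        z=z,
        indicator=het_a.indicator,
    )
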