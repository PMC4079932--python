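"""Wald comparison of a life-table quantity between two groups.

Differences (group b minus group a, conventionally women minus men) are
tested with the variance of the difference taken as the sum of the two
group variances — the groups come from independent samples — and a normal
95% interval.  A difference is flagged significant when its interval
excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GroupComparison", "wald_difference"]


@dataclass
class GroupComparison:
    """Per-exact-age difference in a quantity between two groups."""

    quantity: str  # "LE", "HLE" or "UHLE"
    ages: np.ndarray
    group_a: str
    group_b: str
    diff: np.ndarray  # group_b - group_a
    variance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray  # bool, CI excludes 0
    indicator: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "diff": self.diff,
                "variance": self.variance,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "significant": self.significant,
            }
        )


def wald_difference(
    quantity: str,
    ages: np.ndarray,
    value_a: np.ndarray,
    value_b: np.ndarray,
    var_a: np.ndarray,
    var_b: np.ndarray,
    group_a: str = "a",
    group_b: str = "b",
    z: float = 1.96,
    indicator: str | None = None,
) -> GroupComparison:
    diff = np.asarray(value_b, dtype=float) - np.asarray(value_a, dtype=float)
    var = np.asarray(var_a, dtype=float) + np.asarray(var_b, dtype=float)
    se = np.sqrt(var)
    lo, hi = diff - z * se, diff + z * se
    sig = (lo > 0) | (hi < 0)
    return GroupComparison(
        quantity=quantity,
        ages=np.asarray(ages, dtype=float),
        group_a=group_a,
        group_b=group_b,
        diff=diff,
        variance=var,
        ci_low=lo,
        ci_high=hi,
        significant=sig,
        indicator=indicator,
    )
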