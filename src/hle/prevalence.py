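"""Health-state classification and design-based prevalence estimation.

Survey respondents are classified into four dichotomous health states:

* ``poor_srh`` — self-rated health "fair" or "poor" (vs. excellent / very
  good / good);
* ``severe`` — health limits walking one hundred yards and/or bathing or
  dressing (the two hardest physical-functioning items);
* ``mild_moderate`` — limited in walking more than a mile and/or several
  hundred yards, while *not* limited in either of the severe items, so the
  two limitation grades are mutually exclusive;
* ``global`` — limited in any of the four items (= mild_moderate OR severe).

Prevalence is estimated with sampling weights; its variance either by
Taylor linearization over primary sampling units (with-replacement PSU
approximation, the default) or by inflating the binomial variance with a
user-supplied design effect.  A design-adjusted (Rao-Scott second-order)
chi-square compares prevalence across sexes or age groups; a classical
Pearson test on unweighted counts is available as an option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .grids import AgeGrid

__all__ = [
    "INDICATORS",
    "SRH_LEVELS",
    "classify",
    "classify_record",
    "CellEstimate",
    "weighted_prevalence",
    "PrevalenceTable",
    "estimate_prevalence",
    "ChisqResult",
    "prevalence_chisq",
]

logger = logging.getLogger(__name__)

INDICATORS = ("poor_srh", "global", "mild_moderate", "severe")

SRH_LEVELS = ("excellent", "very_good", "good", "fair", "poor")
POOR_SRH_LEVELS = frozenset({"fair", "poor"})

ITEM_COLUMNS = ("lim_g", "lim_h", "lim_i", "lim_j")  # >1 mile, several hundred yards,
# one hundred yards, bathing/dressing
BINARY_LEVELS = ("limited", "not_limited")
THREE_LEVELS = ("limited_a_lot", "limited_a_little", "not_limited")
_LIMITED_3 = frozenset({"limited_a_lot", "limited_a_little"})

Z95 = 1.96


def _item_to_bool(series: pd.Series, item_scale: str) -> pd.Series:
    """Map item responses to nullable booleans (True = limited)."""
    s = series.astype("string").str.strip().str.lower().str.replace(" ", "_")
    if item_scale == "binary":
        valid = set(BINARY_LEVELS)
        limited = s == "limited"
    elif item_scale == "three_level":
        valid = set(THREE_LEVELS)
        limited = s.isin(_LIMITED_3)
    else:
        raise ValidationError(f"unknown item scale {item_scale!r}")
    bad = s.notna() & ~s.isin(valid)
    if bad.any():
        raise ValidationError(
            f"out-of-domain item response(s) {sorted(s[bad].unique())} in {series.name}"
        )
    out = limited.astype("boolean")
    out[s.isna()] = pd.NA
    return out


def classify(records: pd.DataFrame, item_scale: str = "binary") -> pd.DataFrame:
    """Attach the four indicator columns to a survey data frame.

    Missing responses propagate as missing flags (Kleene logic), so e.g. a
    respondent with an unknown walking-a-mile answer but a "limited" answer
    on bathing is still classified severe and global.  Indicator columns are
    nullable booleans; downstream estimation is complete-case per indicator.
    """
    df = records.copy()
    srh = df["srh"].astype("string").str.strip().str.lower().str.replace(" ", "_")
    bad = srh.notna() & ~srh.isin(SRH_LEVELS)
    if bad.any():
        raise ValidationError(f"out-of-domain self-rated-health value(s) {sorted(srh[bad].unique())}")
    poor = srh.isin(POOR_SRH_LEVELS).astype("boolean")
    poor[srh.isna()] = pd.NA
    df["poor_srh"] = poor

    g, h, i, j = (_item_to_bool(df[c], item_scale) for c in ITEM_COLUMNS)
    severe = i | j
    mild = (g | h) & ~severe
    glob = g | h | i | j
    df["severe"] = severe
    df["mild_moderate"] = mild
    df["global"] = glob
    return df


def classify_record(srh: str, lim_g: str, lim_h: str, lim_i: str, lim_j: str,
                    item_scale: str = "binary") -> dict:
    """Classify a single respondent; returns the four indicator flags."""
    df = classify(
        pd.DataFrame(
            [{"srh": srh, "lim_g": lim_g, "lim_h": lim_h, "lim_i": lim_i, "lim_j": lim_j}]
        ),
        item_scale=item_scale,
    )
    row = df.iloc[0]
    return {k: (None if pd.isna(row[k]) else bool(row[k])) for k in INDICATORS}


# ---------------------------------------------------------------------------
# weighted prevalence with design-based variance
# ---------------------------------------------------------------------------

@dataclass
class CellEstimate:
    """Weighted prevalence in one sex x age-group cell."""

    prevalence: float
    variance: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    n_psu: int
    deff: float
    method: str


def _taylor_variance(y: np.ndarray, w: np.ndarray, psu: np.ndarray, pi: float) -> tuple[float, int]:
    """With-replacement PSU linearization variance of a weighted proportion."""
    codes, _ = pd.factorize(psu)
    n_psu = codes.max() + 1
    if n_psu < 2:
        raise ValidationError("Taylor variance needs at least two PSUs")
    zc = np.bincount(codes, weights=w * (y - pi), minlength=n_psu)
    W = w.sum()
    var = n_psu / (n_psu - 1) * float(np.sum(zc**2)) / W**2
    return var, int(n_psu)


def weighted_prevalence(
    y,
    w,
    psu=None,
    method: str = "taylor",
    deff0: float = 2.0,
    z: float = Z95,
    ci_scale: str = "linear",
) -> CellEstimate:
    """Estimate a weighted proportion with a design-based variance.

    ``method="taylor"`` uses the between-PSU linearization (falls back to the
    deff-inflated binomial, with a warning, when the cell holds a single
    PSU); ``method="deff"`` always uses ``deff0 * pi(1-pi)/n``.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.size == 0:
        raise ValidationError("empty cell: no records to estimate from")
    if np.any(w <= 0):
        raise ValidationError("sampling weights must be strictly positive")
    n = y.size
    pi = float(np.sum(w * y) / np.sum(w))

    binom = pi * (1.0 - pi) / n
    used = method
    n_psu = n
    if method == "taylor":
        if psu is None:
            raise ValidationError("Taylor variance requires PSU identifiers")
        try:
            var, n_psu = _taylor_variance(y, w, np.asarray(psu), pi)
        except ValidationError:
            warnings.warn(
                "single PSU in cell: Taylor variance undefined, "
                f"falling back to deff-inflated binomial (deff0={deff0})",
                stacklevel=2,
            )
            var, used = deff0 * binom, "deff"
    elif method == "deff":
        var = deff0 * binom
    else:
        raise ValidationError(f"unknown variance method {method!r}")

    se = float(np.sqrt(var))
    deff = var / binom if binom > 0 else np.nan

    if ci_scale == "logit" and 0.0 < pi < 1.0 and se > 0:
        lgt = np.log(pi / (1 - pi))
        se_l = se / (pi * (1 - pi))
        lo = 1.0 / (1.0 + np.exp(-(lgt - z * se_l)))
        hi = 1.0 / (1.0 + np.exp(-(lgt + z * se_l)))
    else:
        lo = max(0.0, pi - z * se)
        hi = min(1.0, pi + z * se)
    return CellEstimate(pi, float(var), se, float(lo), float(hi), n, int(n_psu), float(deff), used)


@dataclass
class PrevalenceTable:
    """Weighted prevalence of one indicator on an age grid, for one group.

    ``covariance`` (optional) is the joint design-based covariance matrix of
    the age-group prevalence estimates.  Shared PSUs make estimates in
    different age groups correlated; downstream health-expectancy variances
    use the full matrix when it is available and fall back to the diagonal
    (independent-groups) approximation otherwise.
    """

    indicator: str
    grid: AgeGrid
    sex: str
    n: np.ndarray
    prevalence: np.ndarray
    variance: np.ndarray
    deff: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    covariance: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = len(self.grid)
        for name in ("n", "prevalence", "variance", "deff", "ci_low", "ci_high"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (k,):
                raise ValidationError(f"{name} must have one value per age group")
            setattr(self, name, arr)
        if np.any((self.prevalence < 0) | (self.prevalence > 1)):
            raise ValidationError("prevalences must lie in [0, 1]")
        if np.any(self.variance < 0):
            raise ValidationError("variances must be non-negative")
        if self.covariance is not None:
            k = len(self.grid)
            self.covariance = np.asarray(self.covariance, dtype=float)
            if self.covariance.shape != (k, k):
                raise ValidationError("covariance must be a k x k matrix over the age groups")

    @classmethod
    def from_estimates(
        cls,
        indicator: str,
        grid: AgeGrid,
        sex: str,
        prevalence,
        variance=None,
        n=None,
        z: float = Z95,
    ) -> "PrevalenceTable":
        """Build a table from externally supplied (e.g. published) estimates."""
        prevalence = np.asarray(prevalence, dtype=float)
        k = len(grid)
        variance = np.zeros(k) if variance is None else np.asarray(variance, dtype=float)
        n = np.full(k, np.nan) if n is None else np.asarray(n, dtype=float)
        se = np.sqrt(variance)
        return cls(
            indicator=indicator,
            grid=grid,
            sex=sex,
            n=n,
            prevalence=prevalence,
            variance=variance,
            deff=np.full(k, np.nan),
            ci_low=np.clip(prevalence - z * se, 0, 1),
            ci_high=np.clip(prevalence + z * se, 0, 1),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_group": self.grid.labels(),
                "age": self.grid.exact_ages,
                "n": self.n,
                "prevalence": self.prevalence,
                "variance": self.variance,
                "deff": self.deff,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def estimate_prevalence(
    records: pd.DataFrame,
    indicator: str,
    sex: str,
    grid: AgeGrid | None = None,
    method: str = "taylor",
    deff0: float = 2.0,
    z: float = Z95,
    ci_scale: str = "linear",
    item_scale: str = "binary",
) -> PrevalenceTable:
    """Weighted prevalence of one indicator per age group for one sex.

    Records with a missing indicator flag are dropped from that indicator
    only (complete-case); ages below the first grid start are excluded.
    """
    if indicator not in INDICATORS:
        raise ValidationError(f"unknown indicator {indicator!r}; choose from {INDICATORS}")
    if grid is None:
        grid = AgeGrid.default()
    df = records if indicator in records.columns else classify(records, item_scale=item_scale)
    df = df[df["sex"] == sex]
    idx = grid.group_index(df["age"].to_numpy(dtype=float))
    df = df[idx >= 0]
    idx = idx[idx >= 0]

    k = len(grid)
    n = np.zeros(k)
    pi = np.zeros(k)
    var = np.zeros(k)
    deff = np.full(k, np.nan)
    lo = np.zeros(k)
    hi = np.zeros(k)
    flags = df[indicator]
    n_missing = int(flags.isna().sum())
    if n_missing:
        logger.info("%s/%s: %d record(s) dropped (missing %s)", sex, indicator, n_missing, indicator)
    for i in range(k):
        cell = df[(idx == i) & flags.notna().to_numpy()]
        if len(cell) == 0:
            raise ValidationError(
                f"no usable records for {sex}, {grid.labels()[i]}, indicator {indicator}"
            )
        est = weighted_prevalence(
            cell[indicator].to_numpy(dtype=float),
            cell["weight"].to_numpy(dtype=float),
            cell["psu"].to_numpy(),
            method=method,
            deff0=deff0,
            z=z,
            ci_scale=ci_scale,
        )
        n[i], pi[i], var[i] = est.n, est.prevalence, est.variance
        deff[i], lo[i], hi[i] = est.deff, est.ci_low, est.ci_high

    cov = None
    if method == "taylor":
        cov = _joint_taylor_covariance(df, indicator, idx, pi, k)
    return PrevalenceTable(indicator, grid, sex, n, pi, var, deff, lo, hi, covariance=cov)


def _joint_taylor_covariance(
    df: pd.DataFrame, indicator: str, idx: np.ndarray, pi: np.ndarray, k: int
) -> np.ndarray | None:
    """Joint between-PSU covariance of the k age-group prevalence estimates.

    Respondents from the same PSU appear in several age groups, so the
    group-wise estimates are correlated; the linearized PSU totals capture
    that.  Returns None when fewer than two PSUs are observed.
    """
    keep = df[indicator].notna().to_numpy()
    sub = df[keep]
    sidx = idx[keep]
    y = sub[indicator].to_numpy(dtype=float)
    w = sub["weight"].to_numpy(dtype=float)
    codes, _ = pd.factorize(sub["psu"])
    n_psu = codes.max() + 1
    if n_psu < 2:
        return None
    W = np.bincount(sidx, weights=w, minlength=k)
    Z = np.zeros((n_psu, k))
    np.add.at(Z, (codes, sidx), w * (y - pi[sidx]) / W[sidx])
    return n_psu / (n_psu - 1) * (Z.T @ Z)


# ---------------------------------------------------------------------------
# chi-square tests
# ---------------------------------------------------------------------------

@dataclass
class ChisqResult:
    statistic: float
    df: float
    p: float
    method: str
    n: int
    pearson: float  # unadjusted weighted Pearson statistic
    delta_bar: float = np.nan  # mean generalized design effect
    a2: float = np.nan  # squared CV of the design effects


def _factor_column(records: pd.DataFrame, factor: str, grid: AgeGrid) -> pd.Series:
    if factor == "sex":
        return records["sex"].astype(str)
    if factor == "age_group":
        idx = grid.group_index(records["age"].to_numpy(dtype=float))
        labels = grid.labels()
        if np.any(idx < 0):
            raise ValidationError("records below the first grid age; filter before testing")
        return pd.Series([labels[i] for i in idx], index=records.index)
    raise ValidationError(f"unknown factor {factor!r}; use 'sex' or 'age_group'")


def prevalence_chisq(
    records: pd.DataFrame,
    indicator: str,
    factor: str = "sex",
    grid: AgeGrid | None = None,
    method: str = "rao_scott",
    item_scale: str = "binary",
) -> ChisqResult:
    """Test whether an indicator's prevalence differs across factor levels.

    ``method="rao_scott"`` runs a second-order (Satterthwaite) Rao-Scott
    adjusted Pearson test on the weighted 2 x k table, referring the
    adjusted statistic to an F distribution with ``n_psu - 1`` denominator
    clusters; ``method="pearson"`` is the classical Pearson chi-square on
    unweighted counts.
    """
    if grid is None:
        grid = AgeGrid.default()
    df = records if indicator in records.columns else classify(records, item_scale=item_scale)
    keep = df[indicator].notna().to_numpy()
    df = df[keep]
    y = df[indicator].to_numpy(dtype=float).astype(int)
    fac, fac_levels = pd.factorize(_factor_column(df, factor, grid))
    r, c = 2, len(fac_levels)
    if c < 2:
        raise ValidationError("the factor must have at least two observed levels")
    counts = np.zeros((r, c))
    np.add.at(counts, (y, fac), 1)
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValidationError("empty row or column in the contingency table")

    if method == "pearson":
        stat, p, dof, _ = stats.chi2_contingency(counts, correction=False)
        return ChisqResult(float(stat), float(dof), float(p), "pearson", int(counts.sum()),
                           pearson=float(stat))
    if method != "rao_scott":
        raise ValidationError(f"unknown chi-square method {method!r}")

    w = df["weight"].to_numpy(dtype=float)
    n = len(df)
    W = w.sum()
    # weighted cell proportions, cells indexed (i, j) flattened row-major
    cell = y * c + fac
    phat = np.bincount(cell, weights=w, minlength=r * c) / W
    P = phat.reshape(r, c)
    prow, pcol = P.sum(axis=1), P.sum(axis=0)
    expected = np.outer(prow, pcol)
    with np.errstate(divide="ignore", invalid="ignore"):
        x2 = n * float(np.nansum((P - expected) ** 2 / expected))

    # design covariance of phat via PSU linearization (with replacement)
    psu_codes, _ = pd.factorize(df["psu"])
    n_psu = psu_codes.max() + 1
    if n_psu < 2:
        raise ValidationError("Rao-Scott adjustment needs at least two PSUs")
    X = np.zeros((n, r * c))
    X[np.arange(n), cell] = 1.0
    resid = (X - phat) * w[:, None]
    zc = np.zeros((n_psu, r * c))
    np.add.at(zc, psu_codes, resid)
    V = n_psu / (n_psu - 1) * (zc.T @ zc) / W**2
    # multinomial covariance at the same point
    P0 = (np.diag(phat) - np.outer(phat, phat)) / n

    # Jacobian of h_ij = p_ij - p_i. * p_.j on the contrast cells
    d = (r - 1) * (c - 1)
    J = np.zeros((d, r * c))
    rowix = 0
    for i in range(r - 1):
        for j in range(c - 1):
            for a_ in range(r):
                for b_ in range(c):
                    J[rowix, a_ * c + b_] = (
                        float(a_ == i and b_ == j)
                        - float(a_ == i) * pcol[j]
                        - float(b_ == j) * prow[i]
                    )
            rowix += 1
    Vh = J @ V @ J.T
    V0h = J @ P0 @ J.T
    delta = np.linalg.eigvals(np.linalg.solve(V0h, Vh)).real
    delta = np.maximum(delta, 1e-12)
    delta_bar = float(delta.mean())
    a2 = float(np.sum((delta - delta_bar) ** 2) / (d * delta_bar**2))

    x2_adj = x2 / (delta_bar * (1.0 + a2))
    df_s = d / (1.0 + a2)
    fstat = x2_adj / df_s
    p = float(stats.f.sf(fstat, df_s, df_s * (n_psu - 1)))
    return ChisqResult(float(x2_adj), float(df_s), p, "rao_scott", n,
                       pearson=float(x2), delta_bar=delta_bar, a2=a2)
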