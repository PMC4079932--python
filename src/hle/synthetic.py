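"""Synthetic mortality registries and clustered survey microdata.

The generator emulates the two data sources a Sullivan-method study needs,
with known ground truth so every pipeline stage can be validated:

* a vital-registration extract: deaths by sex and 5-year age group drawn as
  independent Poisson counts around Gompertz hazards (female advantage in
  the baseline hazard), plus fixed mid-period population counts;
* a two-stage cluster household survey: respondents nested in primary
  sampling units (default 50, emulating census tracts), with a latent
  three-level severity (none / mild-moderate / severe) generated from an
  ordered-logistic age-sex model with a normal PSU random intercept, item
  answers consistent with the classification rules, and a separate age-flat
  model for poor self-rated health.

``true_values`` integrates the same continuous model on a fine mesh to give
exact life expectancies, prevalences and healthy/unhealthy expectancies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .grids import AgeGrid
from .life_tables import MortalityInput

__all__ = [
    "GompertzMortality",
    "OrderedLimitationModel",
    "SrhModel",
    "SyntheticScenario",
    "GroundTruth",
    "default_scenario",
    "true_values",
    "expected_mortality",
    "generate_mortality",
    "generate_survey",
]

SEXES = ("men", "women")
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(40)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _as_rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GompertzMortality:
    """Adult hazard mu(x) = alpha * exp(beta * (x - origin))."""

    alpha: float  # hazard at the origin age, per year
    beta: float  # log-slope, per year

    def hazard(self, t):
        return self.alpha * np.exp(self.beta * np.asarray(t, dtype=float))

    def survival(self, t):
        """S(t) from the origin age; closed-form Gompertz integral."""
        t = np.asarray(t, dtype=float)
        if self.beta == 0.0:
            return np.exp(-self.alpha * t)
        return np.exp(-self.alpha / self.beta * (np.exp(self.beta * t) - 1.0))


@dataclass(frozen=True)
class OrderedLimitationModel:
    """Proportional-odds model for the latent limitation severity.

    On the logit scale, with t = age - 60 and f = 1 for women:
    P(severity >= mild)  = expit(intercept_global + slope*t + offset*f + u)
    P(severity = severe) = expit(intercept_severe + slope*t + offset*f + u)
    where u ~ N(0, sigma^2) is shared within a PSU.  The common slope/offset
    keep the two curves ordered, which guarantees mild + severe <= 1 and the
    mutual exclusivity the classification rules assume.
    """

    intercept_global: float = -1.30
    intercept_severe: float = -3.13
    age_slope: float = 0.065  # per year of age
    female_offset: float = 0.45
    icc: float = 0.034  # latent-scale intraclass correlation

    def __post_init__(self):
        if self.intercept_severe >= self.intercept_global:
            raise ValidationError("severe threshold must sit above the global one")
        if not 0.0 <= self.icc < 1.0:
            raise ValidationError("icc must lie in [0, 1)")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.icc / (1.0 - self.icc) * np.pi**2 / 3.0))

    def linear(self, t, female):
        return self.age_slope * np.asarray(t, float) + self.female_offset * female


@dataclass(frozen=True)
class SrhModel:
    """Logistic model for poor self-rated health (age-flat by default)."""

    intercept: float = -1.99  # expit(-1.99) ~ 0.12 at age 60
    age_slope: float = 0.0
    female_offset: float = 0.0
    icc: float = 0.034
    # splits within the dichotomy, matching published category frequencies:
    split_poor: tuple = (0.9, 0.1)  # fair, poor
    split_good: tuple = (0.10, 0.18, 0.72)  # excellent, very_good, good

    def __post_init__(self):
        if not 0.0 <= self.icc < 1.0:
            raise ValidationError("icc must lie in [0, 1)")
        if abs(sum(self.split_poor) - 1) > 1e-9 or abs(sum(self.split_good) - 1) > 1e-9:
            raise ValidationError("category splits must sum to 1")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.icc / (1.0 - self.icc) * np.pi**2 / 3.0))


# survey cell counts shaped like a real urban household survey of the 60+
# population (~1,500 respondents, women over-represented and older)
_DEFAULT_CELL_COUNTS = {
    "men": (218, 132, 117, 82, 66),
    "women": (256, 214, 164, 136, 134),
}


@dataclass(frozen=True)
class SyntheticScenario:
    """Full description of the simulated study; defaults emulate a large
    Brazilian city's 60+ population and its household health survey."""

    grid: AgeGrid = field(default_factory=AgeGrid.default)
    mortality: dict = field(
        default_factory=lambda: {
            # calibrated so true e60 ~ 19.2 y (men) and 23.7 y (women)
            "men": GompertzMortality(alpha=0.0130, beta=0.09),
            "women": GompertzMortality(alpha=0.0078, beta=0.09),
        }
    )
    population: dict = field(
        default_factory=lambda: {
            "men": (19000, 15000, 11500, 8000, 6500),
            "women": (22000, 18500, 14500, 10500, 8500),
        }
    )
    n_psus: int = 50
    respondents_per_psu: int = 30
    limitation_model: OrderedLimitationModel = field(default_factory=OrderedLimitationModel)
    srh_model: SrhModel = field(default_factory=SrhModel)
    cell_counts: dict = field(default_factory=lambda: dict(_DEFAULT_CELL_COUNTS))
    weight_cv: float = 0.0  # coefficient of variation of the sampling weights
    terminal_age_scale: float = 4.5  # mean years above the terminal start
    max_survey_age: float = 100.0
    max_age: float = 110.0  # integration horizon

    def __post_init__(self):
        k = len(self.grid)
        for sex in SEXES:
            if sex not in self.mortality or sex not in self.population:
                raise ValidationError(f"scenario must define mortality and population for {sex!r}")
            mort = self.mortality[sex]
            if mort.alpha <= 0 or mort.beta < 0:
                raise ValidationError("Gompertz alpha must be > 0 and beta >= 0")
            pop = np.asarray(self.population[sex], dtype=float)
            if pop.shape != (k,):
                raise ValidationError(f"population for {sex!r} must have one count per interval")
            if np.any(pop <= 0):
                raise ValidationError("population counts must be strictly positive")
            counts = np.asarray(self.cell_counts[sex], dtype=float)
            if counts.shape != (k,) or np.any(counts < 0) or counts.sum() == 0:
                raise ValidationError("cell counts must be non-negative with a positive total")
        if self.n_psus < 2 or self.respondents_per_psu < 1:
            raise ValidationError("need at least 2 PSUs and 1 respondent per PSU")
        if self.weight_cv < 0:
            raise ValidationError("weight_cv must be non-negative")

    @property
    def n_respondents(self) -> int:
        return self.n_psus * self.respondents_per_psu

    def with_(self, **kwargs) -> "SyntheticScenario":
        return replace(self, **kwargs)


def default_scenario(**overrides) -> SyntheticScenario:
    return SyntheticScenario().with_(**overrides) if overrides else SyntheticScenario()


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Exact model quantities at the grid's exact ages / age groups."""

    grid: AgeGrid
    e: dict  # sex -> array over exact ages
    pi: dict  # indicator -> sex -> array over age groups
    hle: dict  # indicator -> sex -> array over exact ages
    uhle: dict


def _marginal_prob(mu, sigma):
    """E[expit(mu + sigma*Z)], Z ~ N(0,1), by Gauss-Hermite quadrature."""
    mu = np.asarray(mu, dtype=float)[..., None]
    vals = _expit(mu + sigma * np.sqrt(2.0) * _GH_NODES)
    return (vals * _GH_WEIGHTS).sum(axis=-1) / np.sqrt(np.pi)


def _age_density_weights(scenario: SyntheticScenario, ages_t: np.ndarray, group: int) -> np.ndarray:
    """Unnormalized within-group density of respondent ages (t = age - origin)."""
    grid = scenario.grid
    origin = grid.starts[0]
    starts = np.asarray(grid.starts) - origin
    if group < len(grid) - 1:
        lo, hi = starts[group], starts[group + 1]
        return ((ages_t >= lo) & (ages_t < hi)).astype(float)
    lo = starts[-1]
    hi = scenario.max_survey_age - origin
    w = np.exp(-(ages_t - lo) / scenario.terminal_age_scale)
    w[(ages_t < lo) | (ages_t > hi)] = 0.0
    return w


def _group_prevalences(scenario: SyntheticScenario, sex: str) -> dict:
    """True prevalence of each indicator per age group for one sex."""
    grid = scenario.grid
    female = 1.0 if sex == "women" else 0.0
    lim = scenario.limitation_model
    srh = scenario.srh_model
    out = {ind: np.empty(len(grid)) for ind in ("poor_srh", "global", "mild_moderate", "severe")}
    for gidx in range(len(grid)):
        lo = grid.starts[gidx] - grid.starts[0]
        hi = (grid.starts[gidx + 1] - grid.starts[0]) if gidx < len(grid) - 1 else (
            scenario.max_survey_age - grid.starts[0]
        )
        t = np.linspace(lo, hi, 201)
        dens = _age_density_weights(scenario, t, gidx)
        dens = dens / np.trapezoid(dens, t)
        eta = lim.linear(t, female)
        p_glob = _marginal_prob(lim.intercept_global + eta, lim.sigma)
        p_sev = _marginal_prob(lim.intercept_severe + eta, lim.sigma)
        p_poor = _marginal_prob(
            srh.intercept + srh.age_slope * t + srh.female_offset * female, srh.sigma
        )
        out["global"][gidx] = np.trapezoid(p_glob * dens, t)
        out["severe"][gidx] = np.trapezoid(p_sev * dens, t)
        out["mild_moderate"][gidx] = out["global"][gidx] - out["severe"][gidx]
        out["poor_srh"][gidx] = np.trapezoid(p_poor * dens, t)
    return out


def true_values(scenario: SyntheticScenario, mesh: float = 0.01) -> GroundTruth:
    """Exact e_x, prevalences and HLE/UHLE by fine-mesh integration.

    Life expectancy integrates the closed-form Gompertz survival; HLE
    integrates (1 - pi(x)) * S(x) with pi step-constant on the age groups
    (the resolution at which the survey observes health).
    """
    grid = scenario.grid
    origin = grid.starts[0]
    horizon = scenario.max_age - origin
    t = np.arange(0.0, horizon + mesh, mesh)
    e, pi, hle, uhle = {}, {}, {}, {}
    starts_t = np.asarray(grid.starts, dtype=float) - origin
    grp = np.clip(np.searchsorted(starts_t, t, side="right") - 1, 0, len(grid) - 1)
    for sex in SEXES:
        S = scenario.mortality[sex].survival(t)
        tail = _tail_integral(S, t)
        idx = np.searchsorted(t, starts_t)
        Sx = S[idx]
        e[sex] = tail[idx] / Sx
        prevs = _group_prevalences(scenario, sex)
        for ind, p in prevs.items():
            pi.setdefault(ind, {})[sex] = p
            healthy_tail = _tail_integral((1.0 - p[grp]) * S, t)
            h = healthy_tail[idx] / Sx
            hle.setdefault(ind, {})[sex] = h
            uhle.setdefault(ind, {})[sex] = e[sex] - h
    return GroundTruth(grid=grid, e=e, pi=pi, hle=hle, uhle=uhle)


def _tail_integral(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """I(t_k) = integral from t_k to t_end of y, by trapezoid."""
    seg = 0.5 * (y[1:] + y[:-1]) * np.diff(t)
    out = np.empty_like(y)
    out[-1] = 0.0
    out[:-1] = seg[::-1].cumsum()[::-1]
    return out


# ---------------------------------------------------------------------------
# mortality registry
# ---------------------------------------------------------------------------

def interval_rates(scenario: SyntheticScenario, sex: str) -> np.ndarray:
    """True central death rates on the grid: Gompertz at the midpoints of
    closed intervals; 1 / e(terminal start) for the open interval, so the
    open group is internally consistent with the continuous model."""
    grid = scenario.grid
    origin = grid.starts[0]
    mids = np.asarray(grid.starts[:-1], dtype=float) - origin + grid.closed_widths / 2.0
    mort = scenario.mortality[sex]
    m = np.empty(len(grid))
    m[:-1] = mort.hazard(mids)
    t_term = grid.starts[-1] - origin
    mesh = np.arange(t_term, scenario.max_age - origin + 0.01, 0.01)
    S = mort.survival(mesh)
    e_term = np.trapezoid(S, mesh) / S[0]
    m[-1] = 1.0 / e_term
    return m


def expected_mortality(scenario: SyntheticScenario) -> dict:
    """Noise-free registry: expected death counts m_i * P_i per sex."""
    out = {}
    for sex in SEXES:
        m = interval_rates(scenario, sex)
        P = np.asarray(scenario.population[sex], dtype=float)
        out[sex] = MortalityInput(
            grid=scenario.grid, deaths=m * P, population=P, sex=sex, period="expected"
        )
    return out


def generate_mortality(
    scenario: SyntheticScenario, years: int = 3, seed=None, rng=None
) -> dict:
    """Per-year Poisson death counts around the true rates, per sex.

    Returns ``{sex: [MortalityInput for each year]}``; populations repeat the
    single mid-period count.  Deterministic under a fixed seed.
    """
    if years < 1:
        raise ValidationError("at least one year must be generated")
    rng = _as_rng(seed, rng)
    out = {}
    for sex in SEXES:
        m = interval_rates(scenario, sex)
        P = np.asarray(scenario.population[sex], dtype=float)
        lam = m * P
        if np.any(lam > 1e12):
            raise ValidationError("expected death counts overflow the Poisson sampler")
        out[sex] = [
            MortalityInput(
                grid=scenario.grid,
                deaths=rng.poisson(lam).astype(float),
                population=P,
                sex=sex,
                period=f"year{y + 1}",
            )
            for y in range(years)
        ]
    return out


# ---------------------------------------------------------------------------
# household survey
# ---------------------------------------------------------------------------

def _sample_ages(scenario: SyntheticScenario, groups: np.ndarray, rng) -> np.ndarray:
    grid = scenario.grid
    starts = np.asarray(grid.starts, dtype=float)
    widths = grid.closed_widths
    ages = np.empty(groups.size)
    closed = groups < len(grid) - 1
    u = rng.uniform(size=groups.size)
    ages[closed] = starts[groups[closed]] + u[closed] * widths[groups[closed]]
    # open group: truncated exponential above the terminal start
    term = ~closed
    if term.any():
        span = scenario.max_survey_age - starts[-1]
        scale = scenario.terminal_age_scale
        cap = 1.0 - np.exp(-span / scale)
        ages[term] = starts[-1] - scale * np.log1p(-u[term] * cap)
    return ages


def generate_survey(scenario: SyntheticScenario, seed=None, rng=None) -> pd.DataFrame:
    """One clustered survey: columns id, sex, age, weight, psu, srh, lim_g-j.

    Item answers are generated conditionally on the latent severity so the
    classification rules recover it exactly: severe respondents are limited
    in walking one hundred yards and/or bathing-dressing; mild-moderate
    respondents in the two easier walking items only.
    """
    rng = _as_rng(seed, rng)
    grid = scenario.grid
    n = scenario.n_respondents
    psu = np.repeat(np.arange(scenario.n_psus), scenario.respondents_per_psu)

    counts = np.concatenate(
        [np.asarray(scenario.cell_counts[sex], dtype=float) for sex in SEXES]
    )
    cell = rng.choice(counts.size, size=n, p=counts / counts.sum())
    k = len(grid)
    female = (cell >= k).astype(float)
    groups = cell % k
    ages = _sample_ages(scenario, groups, rng)
    t = ages - grid.starts[0]

    lim = scenario.limitation_model
    u_lim = rng.normal(0.0, lim.sigma, scenario.n_psus)
    eta = lim.linear(t, female) + u_lim[psu]
    p_glob = _expit(lim.intercept_global + eta)
    p_sev = _expit(lim.intercept_severe + eta)
    u = rng.uniform(size=n)
    severe = u < p_sev
    mild = (~severe) & (u < p_glob)

    not_l, ltd = "not_limited", "limited"
    items = {c: np.full(n, not_l, dtype=object) for c in ("lim_g", "lim_h", "lim_i", "lim_j")}
    if severe.any():
        i_l = rng.uniform(size=n) < 0.85
        j_l = rng.uniform(size=n) < 0.50
        i_l |= ~j_l  # at least one of the two severe items
        items["lim_i"][severe & i_l] = ltd
        items["lim_j"][severe & j_l] = ltd
        items["lim_g"][severe & (rng.uniform(size=n) < 0.95)] = ltd
        items["lim_h"][severe & (rng.uniform(size=n) < 0.90)] = ltd
    if mild.any():
        g_l = rng.uniform(size=n) < 0.90
        h_l = rng.uniform(size=n) < 0.70
        g_l |= ~h_l
        items["lim_g"][mild & g_l] = ltd
        items["lim_h"][mild & h_l] = ltd

    srh_m = scenario.srh_model
    u_srh = rng.normal(0.0, srh_m.sigma, scenario.n_psus)
    p_poor = _expit(
        srh_m.intercept + srh_m.age_slope * t + srh_m.female_offset * female + u_srh[psu]
    )
    poor = rng.uniform(size=n) < p_poor
    srh = np.empty(n, dtype=object)
    n_poor = int(poor.sum())
    srh[poor] = rng.choice(["fair", "poor"], size=n_poor, p=srh_m.split_poor)
    srh[~poor] = rng.choice(
        ["excellent", "very_good", "good"], size=n - n_poor, p=srh_m.split_good
    )

    if scenario.weight_cv > 0:
        sigma2 = np.log1p(scenario.weight_cv**2)
        w = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), n)
    else:
        w = np.ones(n)

    return pd.DataFrame(
        {
            "id": np.arange(n),
            "sex": np.where(female == 1.0, "women", "men"),
            "age": ages,
            "weight": w,
            "psu": psu,
            "srh": srh,
            **items,
        }
    )
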