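"""Indicator classification and design-based prevalence estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hle import (
    ValidationError,
    classify,
    classify_record,
    estimate_prevalence,
    prevalence_chisq,
    weighted_prevalence,
)

L, N = "limited", "not_limited"


class TestClassification:
    @pytest.mark.parametrize(
        "items, expect",
        [
            # (g, h, i, j) -> (mild_moderate, severe, global)
            ((L, N, N, N), (True, False, True)),  # easy walking item only
            ((N, L, N, N), (True, False, True)),
            ((L, L, N, N), (True, False, True)),
            ((N, N, L, N), (False, True, True)),  # hundred yards
            ((N, N, N, L), (False, True, True)),  # bathing/dressing only
            ((L, N, L, L), (False, True, True)),  # severe dominates
            ((N, N, N, N), (False, False, False)),
        ],
    )
    def test_limitation_hierarchy(self, items, expect):
        g, h, i, j = items
        flags = classify_record("good", g, h, i, j)
        assert (flags["mild_moderate"], flags["severe"], flags["global"]) == expect
        # mutual exclusivity and the union identity hold record-wise
        assert not (flags["mild_moderate"] and flags["severe"])
        assert flags["global"] == (flags["mild_moderate"] or flags["severe"])

    @pytest.mark.parametrize(
        "srh, expect", [("excellent", False), ("very_good", False), ("good", False),
                        ("fair", True), ("poor", True)]
    )
    def test_poor_srh_dichotomy(self, srh, expect):
        assert classify_record(srh, N, N, N, N)["poor_srh"] is expect

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValidationError):
            classify_record("awesome", N, N, N, N)
        with pytest.raises(ValidationError):
            classify_record("good", "maybe", N, N, N)

    def test_three_level_items_dichotomized(self):
        flags = classify_record("good", "limited_a_little", "not_limited",
                                "not_limited", "limited_a_lot", item_scale="three_level")
        assert flags["severe"] and flags["global"] and not flags["mild_moderate"]

    def test_missing_items_propagate_conservatively(self):
        # unknown mile-walking answer cannot undo an observed severe limitation
        df = classify(pd.DataFrame([
            {"srh": "good", "lim_g": None, "lim_h": N, "lim_i": N, "lim_j": L},
            {"srh": None, "lim_g": L, "lim_h": N, "lim_i": N, "lim_j": N},
            {"srh": "good", "lim_g": None, "lim_h": N, "lim_i": N, "lim_j": N},
        ]))
        assert bool(df.loc[0, "severe"]) and bool(df.loc[0, "global"])
        assert pd.isna(df.loc[1, "poor_srh"]) and bool(df.loc[1, "mild_moderate"])
        assert pd.isna(df.loc[2, "global"])  # could be mild, could be nothing


class TestWeightedPrevalence:
    def test_equal_weights_reduce_to_sample_proportion(self):
        est = weighted_prevalence([1, 0, 0, 0, 0, 0, 0, 0], np.ones(8), psu=np.arange(8))
        assert est.prevalence == pytest.approx(0.125)

    def test_weighted_mean(self):
        est = weighted_prevalence([1, 0], [2.0, 1.0], method="deff")
        assert est.prevalence == pytest.approx(2 / 3)

    def test_taylor_reduces_to_binomial_for_independent_records(self):
        """With every record its own PSU and equal weights the linearized
        variance is the binomial one times the with-replacement n/(n-1)."""
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 80)
        est = weighted_prevalence(y, np.ones(80), psu=np.arange(80))
        p = y.mean()
        assert est.variance == pytest.approx(p * (1 - p) / 80 * (80 / 79), rel=1e-9)

    def test_single_psu_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="single PSU"):
            est = weighted_prevalence([1, 0, 1, 0], np.ones(4), psu=np.zeros(4), deff0=2.0)
        assert est.method == "deff"
        assert est.variance == pytest.approx(2.0 * 0.25 / 4)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValidationError):
            weighted_prevalence([], [], method="deff")

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.integers(0, 1), min_size=2, max_size=50))
    def test_equal_weights_match_mean_and_ci_stays_in_unit_interval(self, ys):
        est = weighted_prevalence(ys, np.ones(len(ys)), method="deff")
        assert est.prevalence == pytest.approx(np.mean(ys))
        assert 0.0 <= est.ci_low <= est.ci_high <= 1.0

    def test_taylor_variance_tracks_resampling_oracle(self, scenario):
        """Analytic Taylor variance of a clustered cell agrees with the
        empirical variance of the estimate over replicate samples."""
        from hle import generate_survey

        rng = np.random.default_rng(11)
        pis, avars = [], []
        for _ in range(250):
            df = classify(generate_survey(scenario, rng=rng))
            cell = df[(df["sex"] == "women") & (df["age"] >= 60) & (df["age"] < 70)]
            est = weighted_prevalence(
                cell["global"].to_numpy(dtype=float),
                cell["weight"].to_numpy(),
                cell["psu"].to_numpy(),
            )
            pis.append(est.prevalence)
            avars.append(est.variance)
        emp = np.var(pis, ddof=1)
        assert np.mean(avars) == pytest.approx(emp, rel=0.25)


class TestPrevalenceTable:
    def test_additivity_of_limitation_grades(self, survey, grid):
        """Weighted global prevalence equals mild/moderate + severe exactly
        in every sex x age-group cell (mutual exclusivity)."""
        for sex in ("men", "women"):
            tabs = {
                ind: estimate_prevalence(survey, ind, sex, grid)
                for ind in ("global", "mild_moderate", "severe")
            }
            assert np.allclose(
                tabs["global"].prevalence,
                tabs["mild_moderate"].prevalence + tabs["severe"].prevalence,
                atol=1e-12,
            )

    def test_estimates_lie_in_unit_interval_with_joint_covariance(self, survey, grid):
        tab = estimate_prevalence(survey, "poor_srh", "men", grid)
        assert np.all((tab.prevalence >= 0) & (tab.prevalence <= 1))
        assert tab.covariance.shape == (5, 5)
        assert np.allclose(tab.covariance, tab.covariance.T)
        assert np.all(np.diag(tab.covariance) >= 0)

    def test_unknown_indicator_rejected(self, survey):
        with pytest.raises(ValidationError):
            estimate_prevalence(survey, "frailty", "men")


class TestChiSquare:
    def test_identical_distributions_give_zero_statistic(self):
        base = pd.DataFrame(
            {
                "sex": ["men"] * 8 + ["women"] * 8,
                "age": [65.0] * 16,
                "weight": np.ones(16),
                "psu": list(range(8)) * 2,
                "poor_srh": [True, False, True, False] * 4,
            }
        )
        res = prevalence_chisq(base, "poor_srh", "sex")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_balanced_pearson_table_is_null(self):
        df = pd.DataFrame(
            {
                "sex": ["men"] * 20 + ["women"] * 20,
                "age": [65.0] * 40,
                "weight": np.ones(40),
                "psu": np.arange(40),
                "poor_srh": ([True] * 10 + [False] * 10) * 2,
            }
        )
        res = prevalence_chisq(df, "poor_srh", "sex", method="pearson")
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 1

    def test_empty_margin_rejected(self):
        df = pd.DataFrame(
            {
                "sex": ["men"] * 4,
                "age": [65.0] * 4,
                "weight": np.ones(4),
                "psu": [0, 1, 2, 3],
                "poor_srh": [True, False, True, False],
            }
        )
        with pytest.raises(ValidationError):
            prevalence_chisq(df, "poor_srh", "sex")  # only one sex present

    def test_design_adjustment_reported(self, survey):
        res = prevalence_chisq(survey, "global", "age_group")
        assert res.method == "rao_scott"
        assert res.df <= 4.0 + 1e-9
        assert 0.0 <= res.p <= 1.0
        assert res.delta_bar > 0
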