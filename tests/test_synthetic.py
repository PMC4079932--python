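"""Synthetic-data generator: determinism, calibration and ground truth."""

import numpy as np
import pytest

from hle import (
    GompertzMortality,
    ValidationError,
    average_deaths,
    build_abridged_life_table,
    classify,
    default_scenario,
    estimate_prevalence,
    generate_mortality,
    generate_survey,
    sullivan_decompose,
    true_values,
)


class TestScenarioValidation:
    def test_zero_population_rejected(self):
        with pytest.raises(ValidationError):
            default_scenario(population={"men": (0, 1, 1, 1, 1), "women": (1, 1, 1, 1, 1)})

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValidationError):
            default_scenario(mortality={
                "men": GompertzMortality(alpha=-0.01, beta=0.09),
                "women": GompertzMortality(alpha=0.008, beta=0.09),
            })

    def test_unordered_limitation_thresholds_rejected(self):
        from hle import OrderedLimitationModel

        with pytest.raises(ValidationError):
            OrderedLimitationModel(intercept_global=-3.0, intercept_severe=-1.0)


class TestDeterminism:
    def test_identical_seeds_reproduce_everything(self, scenario):
        m1 = generate_mortality(scenario, seed=99)
        m2 = generate_mortality(scenario, seed=99)
        for sex in ("men", "women"):
            for a, b in zip(m1[sex], m2[sex]):
                assert np.array_equal(a.deaths, b.deaths)
        s1 = generate_survey(scenario, seed=99)
        s2 = generate_survey(scenario, seed=99)
        assert s1.to_csv(index=False) == s2.to_csv(index=False)

    def test_different_seeds_differ(self, scenario):
        s1 = generate_survey(scenario, seed=1)
        s2 = generate_survey(scenario, seed=2)
        assert s1.to_csv(index=False) != s2.to_csv(index=False)


class TestMortalityGenerator:
    def test_poisson_mean_matches_rate_times_population(self):
        """Flat hazard 0.02 on 1,000 people: mean deaths over many draws
        within 3 standard errors of 20."""
        sc = default_scenario(
            mortality={
                "men": GompertzMortality(alpha=0.02, beta=0.0),
                "women": GompertzMortality(alpha=0.02, beta=0.0),
            },
            population={"men": (1000,) * 5, "women": (1000,) * 5},
        )
        draws = generate_mortality(sc, years=1000, seed=4)["men"]
        first = np.array([y.deaths[0] for y in draws])
        se = np.sqrt(20.0 / 1000)
        assert abs(first.mean() - 20.0) < 3 * se

    def test_terminal_rate_consistent_with_constant_hazard(self):
        # with beta = 0 the open-interval rate must equal the flat hazard
        sc = default_scenario(
            mortality={
                "men": GompertzMortality(alpha=0.05, beta=0.0),
                "women": GompertzMortality(alpha=0.05, beta=0.0),
            },
            max_age=400.0,  # flat hazards need a long integration horizon
        )
        from hle.synthetic import interval_rates

        assert np.allclose(interval_rates(sc, "men"), 0.05, rtol=1e-4)


class TestSurveyGenerator:
    def test_classification_consistency_by_construction(self, survey):
        glob = survey["global"].to_numpy(dtype=bool)
        mild = survey["mild_moderate"].to_numpy(dtype=bool)
        sev = survey["severe"].to_numpy(dtype=bool)
        assert np.array_equal(glob, mild | sev)
        assert not np.any(mild & sev)

    def test_respondent_structure(self, scenario, survey):
        assert len(survey) == scenario.n_respondents
        assert survey["psu"].nunique() == scenario.n_psus
        assert survey["age"].min() >= 60.0
        assert set(survey["sex"]) == {"men", "women"}

    def test_prevalence_recovery_in_large_samples(self):
        """Estimated weighted prevalences converge to the model truth when
        clustering is switched off and the sample is large."""
        import dataclasses

        sc = default_scenario(n_psus=400, respondents_per_psu=50)
        sc = sc.with_(limitation_model=dataclasses.replace(sc.limitation_model, icc=0.0))
        df = classify(generate_survey(sc, seed=31))
        gt = true_values(sc)
        for sex in ("men", "women"):
            tab = estimate_prevalence(df, "global", sex, sc.grid)
            assert np.allclose(tab.prevalence, gt.pi["global"][sex], atol=0.03)

    def test_independent_psus_have_unit_design_effect(self):
        """With icc = 0 the empirical variance over replicates matches the
        binomial variance (design effect ~ 1)."""
        import dataclasses

        sc = default_scenario(n_psus=25, respondents_per_psu=40)
        sc = sc.with_(limitation_model=dataclasses.replace(sc.limitation_model, icc=0.0))
        rng = np.random.default_rng(17)
        pis, binoms = [], []
        for _ in range(300):
            df = classify(generate_survey(sc, rng=rng))
            cell = df[df["sex"] == "women"]
            y = cell["global"].to_numpy(dtype=float)
            pis.append(y.mean())
            binoms.append(y.mean() * (1 - y.mean()) / len(y))
        deff = np.var(pis, ddof=1) / np.mean(binoms)
        assert deff == pytest.approx(1.0, abs=0.2)

    def test_clustered_design_effect_near_target(self, scenario):
        """Default icc is sized for a whole-sample design effect of ~2 at 50
        PSUs x 30 respondents (deff ~ 1 + (m-1) * rho)."""
        rng = np.random.default_rng(23)
        pis, binoms = [], []
        for _ in range(300):
            df = classify(generate_survey(scenario, rng=rng))
            y = df["global"].to_numpy(dtype=float)
            pis.append(y.mean())
            binoms.append(y.mean() * (1 - y.mean()) / len(y))
        deff = np.var(pis, ddof=1) / np.mean(binoms)
        assert 1.5 < deff < 2.6


class TestGroundTruth:
    def test_constant_hazard_expectancies(self):
        sc = default_scenario(
            mortality={
                "men": GompertzMortality(alpha=0.1, beta=0.0),
                "women": GompertzMortality(alpha=0.1, beta=0.0),
            },
            max_age=300.0,  # keep the truncation error of exp(-0.1 t) negligible
        )
        gt = true_values(sc)
        assert np.allclose(gt.e["men"], 10.0, atol=1e-4)

    def test_truth_conserves_health_partition(self, ground_truth):
        for ind in ("poor_srh", "global", "mild_moderate", "severe"):
            for sex in ("men", "women"):
                assert np.allclose(
                    ground_truth.hle[ind][sex] + ground_truth.uhle[ind][sex],
                    ground_truth.e[sex],
                    rtol=1e-9,
                )

    def test_abridged_pipeline_matches_integral_oracle(self, scenario, ground_truth):
        """e60 from the abridged machinery on the true rates is within
        0.05 y of the fine-mesh integral of the Gompertz survival."""
        from hle import expected_mortality

        em = expected_mortality(scenario)
        for sex in ("men", "women"):
            lt = build_abridged_life_table(em[sex])
            assert abs(lt.e[0] - ground_truth.e[sex][0]) < 0.05

    def test_default_truth_matches_study_scale(self, ground_truth):
        # the default scenario is calibrated to a female advantage of ~4.5 y
        assert ground_truth.e["men"][0] == pytest.approx(19.2, abs=0.1)
        assert ground_truth.e["women"][0] == pytest.approx(23.7, abs=0.1)


class TestPipelineRecovery:
    def test_hle_recovered_at_large_scale(self):
        """Full pipeline on a very large registry and survey converges to
        the ground-truth HLE within 0.1 years."""
        sc = default_scenario(
            population={
                "men": tuple(np.array((19, 15, 11.5, 8, 6.5)) * 1e5),
                "women": tuple(np.array((22, 18.5, 14.5, 10.5, 8.5)) * 1e5),
            },
            n_psus=500,
            respondents_per_psu=200,
        )
        gt = true_values(sc)
        rng = np.random.default_rng(41)
        mort = generate_mortality(sc, years=3, rng=rng)
        df = classify(generate_survey(sc, rng=rng))
        for sex in ("men", "women"):
            lt = build_abridged_life_table(average_deaths(mort[sex]))
            prev = estimate_prevalence(df, "global", sex, sc.grid)
            het = sullivan_decompose(lt, prev)
            assert het.hle[0] == pytest.approx(gt.hle["global"][sex][0], abs=0.1)
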