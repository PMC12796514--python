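"""Sterilisation scenarios, disease adjustment, costs and target search."""

import numpy as np
import pytest
from scipy.stats import beta as beta_dist

from koalapop.demography import DensityFeedback, StochasticRates, project
from koalapop.management import (
    CostModel,
    SterilisationScenario,
    apply_sterilisation,
    beta_binomial_posterior,
    cost_of_programme,
    find_min_effort,
    infertility_fraction,
    sensitivity_to_target,
)


class TestScenarioMechanics:
    def test_zero_proportion_no_change(self, rng):
        sc = SterilisationScenario("adult_females_only", 0.0)
        B, S = np.full(13, 10.0), np.zeros(13)
        B2, S2, treated = apply_sterilisation(B, S, sc, rng)
        np.testing.assert_array_equal(B2, B)
        assert treated == 0.0

    def test_full_effort_sterilises_all_adults(self, rng):
        sc = SterilisationScenario("adult_females_only", 1.0)
        B, S = np.full(13, 10.0), np.zeros(13)
        B2, S2, treated = apply_sterilisation(B, S, sc, rng, first_adult=2)
        assert np.all(B2[2:] == 0.0)
        np.testing.assert_array_equal(B2[:2], B[:2])  # juveniles untouched
        assert treated == pytest.approx(110.0)
        assert S2[2:].sum() == pytest.approx(110.0)

    def test_back_young_expected_treated_matches_micro_simulation(self):
        # 1000 eligible mothers, p = 0.14, each carrying a female joey with
        # probability q: expected treated = 140 * (1 + q). Oracle:
        # individual-based Bernoulli simulation.
        p, q, n_mothers = 0.14, 0.35, 1000
        rng = np.random.default_rng(0)
        totals = []
        for _ in range(2000):
            treated_mothers = rng.random(n_mothers) < p
            has_joey = rng.random(n_mothers) < q
            totals.append(treated_mothers.sum() + (treated_mothers & has_joey).sum())
        oracle = np.mean(totals)

        sc = SterilisationScenario("females_plus_back_young", p)
        B = np.zeros((1, 13))
        B[0, 3] = n_mothers
        B[0, 0] = q * n_mothers  # female joeys at back
        _, _, _, treated = sc.apply(B, np.zeros_like(B), np.zeros_like(B), np.zeros_like(B), 2, rng)
        assert treated[0] == pytest.approx(p * n_mothers * (1 + q), rel=1e-9)
        assert treated[0] == pytest.approx(oracle, rel=0.02)

    def test_back_young_spares_infertile_pool(self, rng):
        sc = SterilisationScenario("females_plus_back_young", 0.5)
        B = np.zeros((1, 13))
        I = np.zeros((1, 13))
        B[0, 4], I[0, 4] = 100.0, 50.0
        B2, I2, S2, treated = sc.apply(B, I, np.zeros_like(B), np.zeros_like(B), 2, rng)
        np.testing.assert_array_equal(I2, I)  # infertile females never treated
        assert treated[0] == pytest.approx(50.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            SterilisationScenario("cull", 0.1)
        with pytest.raises(ValueError):
            SterilisationScenario("adult_females_only", 1.5)

    def test_sterilised_pool_non_decreasing_in_time(self, reference_leslie):
        sc = SterilisationScenario("adult_females_only", 0.1)
        res = project(5000.0, reference_leslie, rates=StochasticRates(0, 0), years=15, n_iter=1, seed=0, scenario=sc)
        cum_treated = np.cumsum(res.treated[0])
        assert np.all(np.diff(cum_treated) >= 0)
        assert np.all(res.sterilised[0, 1:] > 0)


class TestChlamydia:
    def test_printed_product(self):
        assert infertility_fraction(0.47, 0.11, 0.85) == pytest.approx(0.043945)
        assert round(infertility_fraction(0.47, 0.11, 0.85), 2) == 0.04

    def test_degenerate_products(self):
        assert infertility_fraction(0.0, 0.5, 0.5) == 0.0
        assert infertility_fraction(1.0, 1.0, 1.0) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            infertility_fraction(1.2, 0.5, 0.5)

    def test_uniform_prior_no_data(self):
        out = beta_binomial_posterior(0, 0)
        assert out["mean"] == pytest.approx(0.5)

    def test_survey_counts_match_numerical_oracle(self):
        # k=3 of n=75 with a uniform prior: Beta(4, 73); quantile oracle
        out = beta_binomial_posterior(3, 75)
        ref = beta_dist(4, 73)
        assert out["mean"] == pytest.approx(4 / 77, rel=1e-12)
        assert out["ci95"][0] == pytest.approx(ref.ppf(0.025), rel=1e-9)
        assert out["ci95"][1] == pytest.approx(ref.ppf(0.975), rel=1e-9)
        # consistent with the published 5.2% (1.45%-11.11%) summaries
        assert out["mean"] == pytest.approx(0.052, abs=0.001)
        assert out["ci95"][0] == pytest.approx(0.0145, abs=0.001)
        assert out["ci95"][1] == pytest.approx(0.1111, abs=0.002)

    def test_mean_inside_interval_property(self):
        for k, n in [(0, 10), (5, 10), (10, 10), (1, 100)]:
            out = beta_binomial_posterior(k, n)
            assert out["ci95"][0] <= out["mean"] <= out["ci95"][1]

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            beta_binomial_posterior(5, 3)


class TestCosts:
    def test_unit_cost_arithmetic(self):
        assert CostModel().unit_cost == pytest.approx(51.9)

    def test_programme_cost_examples(self):
        yearly, total = cost_of_programme([1.0])
        assert total == pytest.approx(51.9)
        yearly, total = cost_of_programme(np.full(25, 1000.0))
        assert total == pytest.approx(1_297_500.0)
        assert np.allclose(yearly, 51900.0)
        assert cost_of_programme([0.0])[1] == 0.0

    def test_cost_identity_exact(self, rng):
        treated = rng.uniform(0, 500, 25)
        yearly, total = cost_of_programme(treated)
        assert total == pytest.approx(51.9 * treated.sum(), rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            cost_of_programme([-1.0])


@pytest.fixture(scope="module")
def search_setup(reference_leslie):
    N0 = 20000.0
    fb = DensityFeedback(K=1.2 * N0).calibrate(reference_leslie)
    return reference_leslie, N0, fb


class TestTargetSearch:
    def test_growing_baseline_misses_tight_target_at_zero_effort(self, search_setup):
        leslie, N0, fb = search_setup
        outcomes, minimal = find_min_effort(
            "adult_females_only", N0, leslie, N0, feedback=fb, rates=StochasticRates(0, 0),
            sweep=[0.0], years=25, n_iter=1, seed=0,
        )
        assert minimal is None and not outcomes[0].met_target

    def test_minimal_effort_and_monotonicity(self, search_setup):
        leslie, N0, fb = search_setup
        sweep = np.arange(0.0, 0.21, 0.04)
        outcomes, minimal = find_min_effort(
            "adult_females_only", 0.9 * N0, leslie, N0, feedback=fb, rates=StochasticRates(),
            sweep=sweep, years=25, n_iter=200, seed=1, infertile_fraction=0.04,
        )
        finals = [o.final_total_median for o in outcomes]
        assert np.all(np.diff(finals) <= 0)  # more effort, smaller population
        assert minimal is not None and 0 < minimal.annual_proportion <= 0.2
        costs = [o.total_cost for o in outcomes]
        sterilised = [o.cumulative_sterilised_females for o in outcomes]
        # treatments accumulate with effort while the population persists;
        # beyond the crash point higher effort can treat fewer animals
        low_effort = [s for s, o in zip(sterilised, outcomes) if o.annual_proportion <= minimal.annual_proportion]
        assert np.all(np.diff(low_effort) >= 0)
        np.testing.assert_allclose(costs, np.asarray(sterilised) * 51.9, rtol=1e-9)

    def test_back_young_needs_no_more_effort(self, search_setup):
        leslie, N0, fb = search_setup
        sweep = np.arange(0.0, 0.25, 0.04)
        kwargs = dict(feedback=fb, rates=StochasticRates(), sweep=sweep, years=25, n_iter=300, seed=2, infertile_fraction=0.04)
        _, m1 = find_min_effort("adult_females_only", 0.8 * N0, leslie, N0, **kwargs)
        _, m2 = find_min_effort("females_plus_back_young", 0.8 * N0, leslie, N0, **kwargs)
        assert m1 is not None and m2 is not None
        assert m2.annual_proportion <= m1.annual_proportion

    def test_sensitivity_ordering_across_targets(self, search_setup):
        leslie, N0, fb = search_setup
        out = sensitivity_to_target(
            "adult_females_only", 0.85 * N0, leslie, N0,
            targets_per_ha=(0.5, 0.7, 1.0), feedback=fb, rates=StochasticRates(),
            sweep=np.arange(0.0, 0.31, 0.05), n_iter=150, seed=3, infertile_fraction=0.04,
        )
        out = out.sort_values("target_per_ha")
        # a stricter density target never needs less sterilisation effort
        p = out["min_proportion"].to_numpy()
        assert p[0] >= p[1] >= p[2]
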