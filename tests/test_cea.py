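"""Cost-effectiveness engine: identities, distributions, solvers."""

import dataclasses

import numpy as np
import pytest

from lungscreen import cea

PROGRAMS = ["lung14", "lung70", "breast", "colorectal"]


@pytest.fixture(scope="module")
def lung14():
    return cea.load_program("lung14")


class TestCostPerLife:
    @pytest.mark.parametrize(
        "cost,lives,expected",
        [
            (2.1e9, 20_500, 102.0),
            (2.1e9, 103_000, 20.4),
            (12.8e9, 99_700, 128.0),
            (9.5e9, 10_700, 890.0),
            (12.6e9, 13_700, 920.0),
            (0.0, 1_000, 0.0),
        ],
    )
    def test_published_arithmetic(self, cost, lives, expected):
        assert cea.cost_per_life(cost, lives) == expected

    def test_zero_lives_undefined(self):
        with pytest.raises(ValueError):
            cea.cost_per_life(1e9, 0)


class TestIcer:
    def test_unit_case(self, lung14):
        params = dataclasses.replace(
            lung14,
            qaly_weight_mean=1.0,
            discount_rate=0.0,
            life_years_per_death_averted=1.0,
        )
        assert cea.icer(50_000.0, 1.0, params) == pytest.approx(50_000.0)

    def test_linear_in_cost(self, lung14):
        one = cea.icer(1e9, 20_500, lung14)
        two = cea.icer(2e9, 20_500, lung14)
        assert two == pytest.approx(2 * one)

    def test_backsolved_life_years_reproduce_lung_icer(self, lung14):
        cell = lung14.calibration[0]
        assert cea.icer(
            cell.annual_cost.mean, cell.lives_cancer.mean, lung14
        ) == pytest.approx(85_000.0, rel=1e-9)

    def test_zero_deaths_undefined(self, lung14):
        with pytest.raises(ValueError):
            cea.icer(1e9, 0.0, lung14)

    def test_discounting_shrinks_stream(self):
        assert cea.discounted_years(10.0, 0.03) < 10.0
        assert cea.discounted_years(10.0, 0.0) == 10.0


class TestRunCea:
    def test_lung14_point_estimates(self, lung14):
        res = cea.run_cea(lung14, n_iter=10_000, seed=7)
        assert round(res.annual_cost.mean / 1e9, 1) == 2.1
        assert res.lives_saved_cancer.mean == pytest.approx(20_500, rel=0.02)
        assert cea.cost_per_life(
            res.annual_cost.mean, res.lives_saved_cancer.mean
        ) == pytest.approx(102.0, abs=2.0)
        assert res.icer_per_qaly.mean == pytest.approx(85_000, rel=0.02)

    def test_seeded_reproducibility(self, lung14):
        a = cea.run_cea(lung14, n_iter=2_000, seed=5)
        b = cea.run_cea(lung14, n_iter=2_000, seed=5)
        assert a.annual_cost == b.annual_cost
        assert np.array_equal(a.samples["icer"], b.samples["icer"])

    @pytest.mark.parametrize("name", PROGRAMS)
    def test_cost_identity_all_programs(self, name):
        """Point-estimate cost per life x lives equals annual cost."""
        res = cea.run_cea(cea.load_program(name), n_iter=2_000, seed=3)
        implied = res.cost_per_life_saved.mean * 1000.0 * res.lives_saved_cancer.mean
        assert implied == pytest.approx(res.annual_cost.mean, rel=1e-9)

    def test_zero_participation(self, lung14):
        params = dataclasses.replace(lung14, participation=0.0)
        res = cea.run_cea(params, n_iter=500, seed=1)
        assert res.lives_saved_cancer.mean == 0.0
        assert res.annual_cost.mean == params.fixed_costs

    def test_participation_monotone_cost(self, lung14):
        costs = []
        for p in (0.1, 0.3, 0.5, 0.7):
            res = cea.run_cea(
                dataclasses.replace(lung14, participation=p), n_iter=500, seed=2
            )
            costs.append(res.annual_cost.mean)
        assert all(a < b for a, b in zip(costs, costs[1:]))

    def test_degenerate_distribution_collapses_ci(self, lung14):
        cell = lung14.calibration[0]
        frozen = dataclasses.replace(
            cell,
            annual_cost=cea.Uncertain(2.1e9, 2.1e9, 2.1e9),
            lives_cancer=cea.Uncertain(20_500, 20_500, 20_500),
        )
        params = dataclasses.replace(
            lung14, calibration=(frozen,), participation=cell.participation,
            qaly_weight_sd=0.0,
        )
        res = cea.run_cea(params, n_iter=200, seed=1)
        assert res.annual_cost.lo == res.annual_cost.hi == 2.1e9

    def test_ci_contracts_with_iterations(self, lung14):
        """Monte Carlo error on the mean shrinks ~ 1/sqrt(n)."""
        reps_small = [
            cea.run_cea(lung14, 100, seed=s).annual_cost.mean for s in range(12)
        ]
        reps_big = [
            cea.run_cea(lung14, 6_400, seed=s).annual_cost.mean for s in range(12)
        ]
        ratio = np.std(reps_small) / np.std(reps_big)
        assert 3.0 < ratio < 22.0  # expect ~8x


class TestProbSuperior:
    def test_identical_samples_split_ties(self, lung14):
        res = cea.run_cea(lung14, n_iter=1_000, seed=4)
        assert cea.prob_superior(res, res) == pytest.approx(0.5)

    def test_disjoint_distributions(self, lung14):
        a = cea.run_cea(lung14, n_iter=1_000, seed=4)
        b = cea.run_cea(cea.load_program("breast"), n_iter=1_000, seed=5)
        assert cea.prob_superior(a, b) == 1.0

    def test_lung_vs_comparators(self, lung14):
        a = cea.run_cea(lung14, n_iter=10_000, seed=6)
        for name in ("breast", "colorectal"):
            b = cea.run_cea(cea.load_program(name), n_iter=10_000, seed=7)
            assert cea.prob_superior(a, b) > 0.95

    def test_mismatched_lengths_rejected(self, lung14):
        a = cea.run_cea(lung14, n_iter=100, seed=1)
        b = cea.run_cea(lung14, n_iter=200, seed=1)
        with pytest.raises(ValueError):
            cea.prob_superior(a, b)


class TestCostNeutrality:
    def test_default_near_published(self, lung14):
        assert cea.cost_neutral_participation(lung14) == pytest.approx(0.76, abs=0.03)

    def test_zero_savings_no_root(self, lung14):
        params = dataclasses.replace(lung14, savings_scale=0.0)
        with pytest.raises(ValueError, match="positive"):
            cea.cost_neutral_participation(params)

    def test_doubled_savings_smaller_root(self, lung14):
        base = cea.cost_neutral_participation(lung14)
        doubled = cea.cost_neutral_participation(
            dataclasses.replace(lung14, savings_scale=2.0)
        )
        assert doubled < base

    def test_requires_savings_calibration(self):
        with pytest.raises(ValueError):
            cea.cost_neutral_participation(cea.load_program("breast"))
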