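"""Competing-risks marginal attack rates against a microsimulation oracle.

The oracle simulates individuals exposed to simultaneous constant hazards and
measures, for each factor, the fraction it would have killed acting alone —
the definition of the marginal rate — entirely independently of the
closed-form correction under test.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biopra import (
    LifeTableCohort,
    apparent_mortality,
    marginal_attack_rate,
    marginal_rates_from_life_table,
)
from biopra.mortality import load_life_table


def microsim_marginals(apparent_by_factor, n=200_000, seed=7):
    """Simulate competing constant hazards calibrated to the given apparent
    mortalities; return (simulated apparent rates, simulated marginal rates).

    Each factor's stand-alone kill indicator is whether its own exponential
    event time lands inside the interval, ignoring the competition.
    """
    d = sum(apparent_by_factor)
    assert 0 < d < 1
    total_hazard = -math.log(1.0 - d)
    hazards = np.array([total_hazard * di / d for di in apparent_by_factor])
    rng = np.random.default_rng(seed)
    times = rng.exponential(1.0, size=(n, len(hazards))) / hazards
    alone_kill = times < 1.0                      # factor would kill acting alone
    died = alone_kill.any(axis=1)
    cause = np.argmin(times, axis=1)              # first event wins the competition
    apparent = np.array(
        [np.mean(died & (cause == j)) for j in range(len(hazards))]
    )
    marginal = alone_kill.mean(axis=0)
    return apparent, marginal


class TestApparentMortality:
    @pytest.mark.parametrize(
        "deaths,size,expected", [(0, 50, 0.0), (50, 50, 1.0), (13, 52, 0.25)]
    )
    def test_proportion(self, deaths, size, expected):
        assert apparent_mortality(deaths, size) == expected

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            apparent_mortality(5, 4)
        with pytest.raises(ValueError):
            apparent_mortality(0, 0)


class TestMarginalAttackRate:
    def test_zero_factor_contributes_nothing(self):
        assert marginal_attack_rate(0.0, 0.5) == 0.0
        assert marginal_attack_rate(0.0, 0.0) == 0.0

    def test_sole_factor_marginal_equals_apparent(self):
        assert marginal_attack_rate(0.5, 0.5) == pytest.approx(0.5)

    def test_two_factor_closed_form(self):
        # 1 - (1 - 0.5) ** (0.2 / 0.5)
        assert marginal_attack_rate(0.2, 0.5) == pytest.approx(0.2421417167, abs=1e-9)

    def test_matches_microsimulation_oracle(self):
        sim_apparent, sim_marginal = microsim_marginals([0.2, 0.3])
        d = sim_apparent.sum()
        n = 200_000
        for d_i, m_sim in zip(sim_apparent, sim_marginal):
            m_formula = marginal_attack_rate(float(d_i), float(d))
            se = math.sqrt(m_sim * (1 - m_sim) / n)
            assert abs(m_formula - m_sim) < 3 * se

    def test_oracle_agreement_over_grid(self):
        for i, (d_i, d) in enumerate([(0.05, 0.1), (0.1, 0.6), (0.4, 0.8), (0.25, 0.3)]):
            sim_apparent, sim_marginal = microsim_marginals([d_i, d - d_i], seed=100 + i)
            m_formula = marginal_attack_rate(float(sim_apparent[0]), float(sim_apparent.sum()))
            se = math.sqrt(max(sim_marginal[0] * (1 - sim_marginal[0]), 1e-9) / 200_000)
            assert abs(m_formula - sim_marginal[0]) < 3 * se

    def test_total_mortality_with_partial_factor_is_refused(self):
        with pytest.raises(ValueError, match="undefined"):
            marginal_attack_rate(0.5, 1.0)

    def test_factor_exceeding_total_is_refused(self):
        with pytest.raises(ValueError):
            marginal_attack_rate(0.6, 0.5)

    @given(
        d=st.floats(0.001, 0.999),
        frac=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_dominance_marginal_at_least_apparent(self, d, frac):
        d_i = min(d * frac, d)
        m = marginal_attack_rate(d_i, d)
        assert m >= d_i - 1e-12
        # strict dominance away from the endpoints (underflow-safe margin)
        if 1e-9 < d_i < d - 1e-9:
            assert m > d_i

    def test_monotone_in_factor_and_total(self):
        grid = np.linspace(0.05, 0.45, 9)
        ms = [marginal_attack_rate(x, 0.5) for x in grid]
        assert all(a < b for a, b in zip(ms, ms[1:]))
        ms_d = [marginal_attack_rate(0.2, d) for d in np.linspace(0.25, 0.9, 8)]
        assert all(a < b for a, b in zip(ms_d, ms_d[1:]))


class TestLifeTable:
    def test_single_factor(self):
        cohort = LifeTableCohort(100, {"f": 30}, 70)
        assert marginal_rates_from_life_table(cohort) == {"f": pytest.approx(0.30)}

    def test_two_factor_values_and_conservation(self):
        cohort = LifeTableCohort(100, {"A": 20, "B": 30}, 50)
        m = marginal_rates_from_life_table(cohort)
        assert m["A"] == pytest.approx(0.2421417167, abs=1e-6)
        # 1 - (1 - 0.5) ** (0.3 / 0.5)
        assert m["B"] == pytest.approx(0.3402459937, abs=1e-6)
        assert (1 - m["A"]) * (1 - m["B"]) == pytest.approx(0.5, abs=1e-12)

    def test_no_deaths_gives_all_zero(self):
        cohort = LifeTableCohort(100, {"A": 0, "B": 0}, 100)
        assert marginal_rates_from_life_table(cohort) == {"A": 0.0, "B": 0.0}

    def test_no_survivors_is_refused(self):
        cohort = LifeTableCohort(10, {"A": 10}, 0)
        with pytest.raises(ValueError, match="survivors"):
            marginal_rates_from_life_table(cohort)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            LifeTableCohort(100, {"A": 20}, 50)

    @given(
        deaths=st.lists(st.integers(0, 30), min_size=1, max_size=4),
        survivors=st.integers(1, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_conservation_product_equals_survival(self, deaths, survivors):
        size = survivors + sum(deaths)
        cohort = LifeTableCohort(
            size, {f"f{i}": d for i, d in enumerate(deaths)}, survivors
        )
        m = marginal_rates_from_life_table(cohort)
        product = math.prod(1 - v for v in m.values())
        assert product == pytest.approx(survivors / size, abs=1e-12)

    def test_load_life_table_csv(self, tmp_path):
        path = tmp_path / "lt.csv"
        path.write_text("factor,deaths\ncohort_size,100\nA,20\nB,30\n", encoding="utf-8")
        cohort = load_life_table(path)
        assert cohort.cohort_size == 100
        assert cohort.survivors == 50
        assert cohort.deaths_by_factor == {"A": 20, "B": 30}
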