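"""Scheduler semantics: module order, mortality, characteristics, movement."""

import numpy as np
import pytest

from conftest import force_table, make_world, zeroed_params
from denialsim.dynamics import (
    _SUBMODULES,
    age_and_mortality,
    move_agents,
    run_simulation,
    step,
    update_characteristics,
)
from denialsim.params import default_parameter_set, logit
from denialsim.population import initialize_population


class TestStepBasics:
    def test_zero_probability_world_only_ages(self, tiny_world_factory):
        ps, w = tiny_world_factory(n=300)
        ages = w.age.copy()
        lg = step(w, ps)
        assert lg.deaths_all_cause == 0
        assert lg.deaths_suicide == 0
        assert lg.deaths_homicide == 0
        assert lg.incidents == 0
        assert sum(lg.arrests.values()) == 0
        assert np.array_equal(w.age, ages + 1)

    def test_population_constant_across_steps(self):
        ps = default_parameter_set(seed=0, scale=1 / 160)
        w = make_world(ps, seed=2)
        for _ in range(5):
            lg = step(w, ps)
            assert lg.population == ps.population_size
            assert int(w.alive.sum()) == ps.population_size

    def test_module_order_is_load_bearing(self, tiny_world_factory):
        # permuting the documented sub-module order changes outputs:
        # running rebirth after the characteristics update leaves reborn
        # agents with cleared states that module 3 would have filled
        ps = zeroed_params(n=2000, seed=0)
        force_table(ps, "drinking_light", 0.6)
        ps.mortality_table = [[float(a), 0.3, 0.3] for a in range(18, 130)]
        w1 = make_world(ps, seed=5)
        w2 = make_world(ps, seed=5)
        step(w1, ps)
        order = list(_SUBMODULES)
        order[1], order[2] = order[2], order[1]  # characteristics before rebirth
        step(w2, ps, _order=tuple(order))
        assert not np.array_equal(w1.drinking, w2.drinking)

    def test_rng_streams_are_isolated(self, tiny_world_factory):
        # consuming extra draws in one module's stream leaves the others'
        # sequences untouched (common-random-numbers contract)
        ps, w1 = tiny_world_factory(n=500, seed=3)
        _, w2 = tiny_world_factory(n=500, seed=3)
        w2.rng["movement"].random(12345)  # burn extra numbers in one stream
        step(w1, ps)
        step(w2, ps)
        assert np.array_equal(w1.drinking, w2.drinking)
        assert np.array_equal(w1.owns, w2.owns)
        assert w1.rng["risk"].random() == w2.rng["risk"].random()


class TestMortality:
    def test_zero_schedule_no_deaths(self, tiny_world_factory):
        ps, w = tiny_world_factory(n=400)
        assert len(age_and_mortality(w, ps)) == 0

    def test_certain_death_full_replacement(self, tiny_world_factory):
        ps, w = tiny_world_factory(n=400)
        ps.mortality_table = [[float(a), 1.0, 1.0] for a in range(18, 130)]
        w.victimization_history[:] = True
        deaths = age_and_mortality(w, ps)
        assert len(deaths) == 400
        assert (w.age == 18).all()
        assert not w.victimization_history.any()
        assert w.alive.all()

    def test_flat_hazard_matches_binomial_oracle(self):
        ps = default_parameter_set(seed=0, scale=1 / 16)  # 50,000 agents
        ps.mortality_table = [[float(a), 0.01, 0.01] for a in range(18, 130)]
        w = initialize_population(ps, seed=8)
        deaths = age_and_mortality(w, ps)
        n, p = ps.population_size, 0.01
        se = np.sqrt(n * p * (1 - p))
        assert abs(len(deaths) - n * p) < 3 * se

    def test_rebirth_agents_start_clean_at_18(self, tiny_world_factory):
        ps, w = tiny_world_factory(n=300)
        ps.mortality_table = [[float(a), 0.5, 0.5] for a in range(18, 130)]
        w.felony_ever[:] = True
        w.prohibited_until[:] = 10**7
        deaths = age_and_mortality(w, ps)
        assert len(deaths) > 0
        assert (w.age[deaths] == 18).all()
        assert not w.felony_ever[deaths].any()
        assert (w.prohibited_until[deaths] < 0).all()


class TestCharacteristics:
    def test_felon_never_owns_despite_certain_draw(self, tiny_world_factory):
        ps, w = tiny_world_factory(n=200)
        force_table(ps, "ownership", 1.0)
        w.felony_ever[:100] = True
        update_characteristics(w, ps)
        assert not w.owns[:100].any()
        assert w.owns[100:].all()

    def test_prohibited_agent_cannot_own(self, tiny_world_factory):
        ps, w = tiny_world_factory(n=100)
        force_table(ps, "ownership", 1.0)
        w.year = 5
        w.prohibited_until[:50] = 5  # active this year
        w.prohibited_until[50:60] = 4  # expired
        update_characteristics(w, ps)
        assert not w.owns[:50].any()
        assert w.owns[50:].all()

    def test_aud_requires_drinking(self, tiny_world_factory):
        ps, w = tiny_world_factory(n=2000)
        force_table(ps, "alcohol_use_disorder", 1.0)
        force_table(ps, "drinking_light", 0.4)
        update_characteristics(w, ps)
        assert (w.aud == (w.drinking > 0)).all()

    def test_dud_requires_drug_use(self, tiny_world_factory):
        ps, w = tiny_world_factory(n=2000)
        force_table(ps, "drug_use_disorder", 1.0)
        force_table(ps, "drug_use", 0.3)
        update_characteristics(w, ps)
        assert (w.dud == w.drug_use).all()

    def test_intercept_only_ownership_prevalence(self):
        # binomial oracle around the 22% ownership anchor
        ps = zeroed_params(n=50_000)
        ps.tables["ownership"].intercept = logit(0.22)
        w = make_world(ps, seed=1)
        update_characteristics(w, ps)
        se = np.sqrt(0.22 * 0.78 / 50_000)
        assert abs(w.owns.mean() - 0.22) < 3 * se

    def test_drinking_residual_is_nondrinker(self, tiny_world_factory):
        ps, w = tiny_world_factory(n=30_000)
        force_table(ps, "drinking_light", 0.5)
        force_table(ps, "drinking_heavy", 0.1)
        update_characteristics(w, ps)
        shares = np.bincount(w.drinking, minlength=3) / w.n
        assert shares[0] == pytest.approx(0.4, abs=0.02)
        assert shares[1] == pytest.approx(0.5, abs=0.02)
        assert shares[2] == pytest.approx(0.1, abs=0.02)


class TestMovement:
    def test_zero_probability_no_movers(self, tiny_world_factory):
        ps, w = tiny_world_factory(n=300)
        dur = w.residence_duration.copy()
        assert move_agents(w, ps) == 0
        assert np.array_equal(w.residence_duration, dur + 1)

    def test_certain_movement_moves_everyone(self, tiny_world_factory):
        ps, w = tiny_world_factory(n=300, n_neighborhoods=5)
        force_table(ps, "movement", 1.0)
        old_nb = w.neighborhood.copy()
        assert move_agents(w, ps) == 300
        assert (w.residence_duration == 0).all()
        assert (w.neighborhood != old_nb).all()  # always a different one

    def test_victims_move_more(self):
        # two-proportion oracle: positive victimization coefficient raises
        # the empirical move rate among last-year victims
        ps = zeroed_params(n=50_000, n_neighborhoods=10)
        ps.tables["movement"].intercept = logit(0.05)
        ps.tables["movement"].terms = [("victimized_last_year", 1.0)]
        w = make_world(ps, seed=4)
        w.victimized_last_year[: w.n // 2] = True
        move_agents(w, ps)
        moved = w.residence_duration == 0
        p1 = moved[: w.n // 2].mean()
        p2 = moved[w.n // 2 :].mean()
        se = np.sqrt(p1 * (1 - p1) / (w.n / 2) + p2 * (1 - p2) / (w.n / 2))
        assert p1 - p2 > 3 * se


class TestRunSimulation:
    def test_burn_in_discarded(self):
        ps = default_parameter_set(seed=0, scale=1 / 400)
        _, logs = run_simulation(ps, years=4, burn_in=3, seed=0)
        assert len(logs) == 4
        assert logs[0].year == 4

    def test_deterministic_given_seed(self):
        ps = default_parameter_set(seed=0, scale=1 / 400)
        _, a = run_simulation(ps, years=3, burn_in=1, seed=12)
        _, b = run_simulation(ps, years=3, burn_in=1, seed=12)
        for la, lb in zip(a, b):
            assert la.as_row() == lb.as_row()
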