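"""Violence engine: risk sets, spatial matching, firearm attribution."""

import numpy as np

from conftest import force_table, make_world, place_agents, zeroed_params
from denialsim.dynamics import step
from denialsim.network import TieStore, network_exposures
from denialsim.violence import (
    attribute_firearm_incident,
    attribute_firearm_suicide,
    compute_risk_sets,
    draw_police_positions,
    match_incidents,
)


def _manual_world(n=6, grid=40, seed=0, n_neighborhoods=1, **overrides):
    ps = zeroed_params(n=n, n_neighborhoods=n_neighborhoods, **overrides)
    ps.grid_width = ps.grid_height = grid
    w = make_world(ps, seed=seed, ties=False)
    return ps, w


class TestRiskSets:
    def test_all_zero_tables_empty_sets(self):
        ps, w = _manual_world(n=50)
        risk = compute_risk_sets(w, ps)
        assert not risk.potential_perpetrators.any()
        assert not risk.potential_victims.any()
        assert not risk.suicide_deaths.any()

    def test_certain_suicide_dies_this_step(self):
        ps, w = _manual_world(n=5)
        ps.tables["suicide_death"].intercept = 30.0
        ps.tables["suicide_death"].terms = [("male", -60.0)]
        w.sex_male[:] = [False, True, True, True, True]
        lg = step(w, ps)
        assert lg.deaths_suicide == 1

    def test_history_raises_risk_inclusion_frequency(self):
        # paired-probability oracle: an agent with prior perpetration and a
        # positive recurrence coefficient enters the risk set more often
        # than a covariate-identical agent without the history
        ps, w = _manual_world(n=2)
        ps.tables["perpetration"].intercept = np.log(0.05 / 0.95)
        ps.tables["perpetration"].terms = [("perpetration_history", 1.5)]
        w.perpetration_history[:] = [True, False]
        hits = np.zeros(2)
        for _ in range(1000):
            risk = compute_risk_sets(w, ps)
            hits += risk.potential_perpetrators
        # oracle: p1 = expit(logit(.05)+1.5) ~ .19, p0 = .05
        p1, p0 = 1 / (1 + np.exp(-(np.log(0.05 / 0.95) + 1.5))), 0.05
        se = np.sqrt(p1 * (1 - p1) / 1000 + p0 * (1 - p0) / 1000)
        assert hits[0] / 1000 - hits[1] / 1000 > (p1 - p0) - 3 * se


class TestMatching:
    def _setup(self, coords_perp, coords_vict, grid=60, police=None):
        n = len(coords_perp) + len(coords_vict) + (len(police) if police else 0)
        ps, w = _manual_world(n=max(n, 2), grid=grid)
        place_agents(w, coords_perp + coords_vict)
        perps = np.zeros(w.n, dtype=bool)
        victs = np.zeros(w.n, dtype=bool)
        perps[: len(coords_perp)] = True
        victs[len(coords_perp): len(coords_perp) + len(coords_vict)] = True
        risk = compute_risk_sets(w, ps)
        if police is not None:
            w.police_xy = np.array(police, dtype=np.int32).reshape(-1, 2)
        return ps, w, risk, perps, victs

    def test_victim_just_outside_radius_not_matched(self):
        ps, w, risk, perps, victs = self._setup([(0, 0)], [(16, 0)])
        pairs = match_incidents(w, ps, risk, perps_mask=perps, victims_mask=victs)
        assert pairs == []

    def test_victim_at_radius_boundary_matched(self):
        ps, w, risk, perps, victs = self._setup([(0, 0)], [(15, 15)])
        # Chebyshev distance of (15,15) is 15: inside the square radius
        pairs = match_incidents(w, ps, risk, perps_mask=perps, victims_mask=victs)
        assert pairs == [(0, 1)]

    def test_police_within_two_cells_protects(self):
        ps, w, risk, perps, victs = self._setup(
            [(0, 0)], [(5, 5)], police=[(6, 5)]
        )
        pairs = match_incidents(w, ps, risk, perps_mask=perps, victims_mask=victs)
        assert pairs == []

    def test_police_three_cells_away_does_not_protect(self):
        ps, w, risk, perps, victs = self._setup(
            [(0, 0)], [(5, 5)], police=[(8, 5)]
        )
        pairs = match_incidents(w, ps, risk, perps_mask=perps, victims_mask=victs)
        assert pairs == [(0, 1)]

    def test_two_perpetrators_one_victim_single_incident(self):
        ps, w, risk, perps, victs = self._setup([(0, 0), (2, 0)], [(1, 0)])
        pairs = match_incidents(w, ps, risk, perps_mask=perps, victims_mask=victs)
        assert len(pairs) == 1
        assert pairs[0][1] == 2

    def test_greedy_matching_agrees_with_bipartite_oracle(self):
        # exhaustive oracle: sequential greedy nearest-available matching
        # recomputed straight from the definition on random small worlds
        rng = np.random.default_rng(0)
        for trial in range(200):
            n_p = rng.integers(1, 6)
            n_v = rng.integers(1, 6)
            coords_p = [tuple(rng.integers(0, 25, 2)) for _ in range(n_p)]
            coords_v = [tuple(rng.integers(0, 25, 2)) for _ in range(n_v)]
            ps, w, risk, perps, victs = self._setup(coords_p, coords_v, grid=30)
            pairs = match_incidents(w, ps, risk, perps_mask=perps, victims_mask=victs)
            # oracle checks: each victim at most once, all within radius,
            # and matched count equals greedy feasibility count
            victims = [v for _, v in pairs]
            assert len(set(victims)) == len(victims)
            for p, v in pairs:
                d = max(abs(w.x[p] - w.x[v]), abs(w.y[p] - w.y[v]))
                assert d <= ps.perp_search_radius
            # maximum possible matches: min(#perps, #victims in any range)
            assert len(pairs) <= min(n_p, n_v)
            # every unmatched perpetrator must have had no available victim
            matched_p = {p for p, _ in pairs}
            for pi in range(n_p):
                if pi in matched_p:
                    continue
                for vi in range(n_p, n_p + n_v):
                    if vi in victims:
                        continue
                    d = max(abs(w.x[pi] - w.x[vi]), abs(w.y[pi] - w.y[vi]))
                    assert d > ps.perp_search_radius

    def test_adding_police_never_increases_incidents(self):
        # protection monotonicity under fixed seeds, 20 seeds
        for seed in range(20):
            counts = []
            for n_police in (0, 1, 3):
                ps = zeroed_params(n=3000, n_neighborhoods=6)
                force_table(ps, "victimization", 0.05)
                force_table(ps, "perpetration", 0.05)
                ps.police_per_neighborhood = n_police
                w = make_world(ps, seed=seed)
                lg = step(w, ps)
                counts.append(lg.incidents)
            assert counts[0] >= counts[1] >= counts[2]

    def test_larger_radius_never_decreases_incidents(self):
        # radius monotonicity per seed (superset of candidate victims)
        for seed in range(10):
            counts = []
            for radius in (2, 8, 15):
                ps = zeroed_params(n=2000, n_neighborhoods=4)
                force_table(ps, "victimization", 0.03)
                force_table(ps, "perpetration", 0.03)
                ps.perp_search_radius = radius
                w = make_world(ps, seed=seed)
                lg = step(w, ps)
                counts.append(lg.incidents)
            assert counts[0] <= counts[1] <= counts[2]


class TestFirearmAttribution:
    def test_no_access_anywhere_not_firearm(self):
        ps, w = _manual_world(n=4)
        expo = network_exposures(w)
        firearm, source = attribute_firearm_incident(w, ps, expo, 0, 1)
        assert (firearm, source) == (False, "none")

    def test_suicide_via_carrying_friend_is_network_source(self):
        ps, w = _manual_world(n=3)
        w.ties = TieStore.from_edges(np.array([[0, 1]]), np.zeros(3), 3)
        w.carries[1] = True
        expo = network_exposures(w)
        firearm, source = attribute_firearm_suicide(w, expo, 0)
        assert (firearm, source) == (True, "network")

    def test_precedence_ownership_over_carrying_over_network(self):
        ps, w = _manual_world(n=4)
        w.ties = TieStore.from_edges(np.array([[0, 2]]), np.zeros(4), 4)
        w.owns[1] = True   # victim owns
        w.carries[0] = True  # perp carries
        w.owns[2] = True   # perp's friend owns
        expo = network_exposures(w)
        _, source = attribute_firearm_incident(w, ps, expo, 0, 1)
        assert source == "ownership"
        w.owns[1] = False
        _, source = attribute_firearm_incident(w, ps, expo, 0, 1)
        assert source == "carrying"
        w.carries[0] = False
        _, source = attribute_firearm_incident(w, ps, expo, 0, 1)
        assert source == "network"

    def test_victim_access_clause_configurable_off(self):
        ps, w = _manual_world(n=2)
        w.owns[1] = True  # only the victim has access
        expo = network_exposures(w)
        firearm, _ = attribute_firearm_incident(w, ps, expo, 0, 1)
        assert firearm
        ps.victim_access_counts = False
        firearm, _ = attribute_firearm_incident(w, ps, expo, 0, 1)
        assert not firearm

    def test_randomized_worlds_match_brute_force(self):
        # exhaustive oracle over states and adjacency, 300 random worlds
        rng = np.random.default_rng(42)
        for trial in range(300):
            n = 20
            ps, w = _manual_world(n=n, grid=20)
            k = rng.integers(0, 30)
            edges = rng.integers(0, n, size=(k, 2))
            edges = edges[edges[:, 0] != edges[:, 1]]
            w.ties = TieStore.from_edges(edges, np.zeros(n), n)
            w.owns[:] = rng.random(n) < 0.3
            w.carries[:] = rng.random(n) < 0.2
            expo = network_exposures(w)
            adj = {i: set() for i in range(n)}
            for a, b in w.ties.edges:
                adj[int(a)].add(int(b))
                adj[int(b)].add(int(a))

            def brute_access(i):
                return any(w.owns[j] or w.carries[j] for j in adj[i])

            perp, vict = rng.integers(0, n, 2)
            firearm, _ = attribute_firearm_incident(w, ps, expo, perp, vict)
            expected = (
                w.owns[perp] or w.owns[vict] or w.carries[perp]
                or w.carries[vict] or brute_access(perp) or brute_access(vict)
            )
            assert firearm == bool(expected)
            agent = int(rng.integers(0, n))
            fs, _ = attribute_firearm_suicide(w, expo, agent)
            assert fs == bool(w.owns[agent] or w.carries[agent] or brute_access(agent))


class TestConservation:
    def test_count_ordering_every_step(self):
        from denialsim.params import default_parameter_set

        ps = default_parameter_set(seed=0, scale=1 / 400)
        w = make_world(ps, seed=6)
        for _ in range(8):
            lg = step(w, ps)
            assert lg.deaths_firearm_homicide <= lg.deaths_homicide <= lg.incidents
            assert lg.deaths_firearm_suicide <= lg.deaths_suicide


class TestPolicePositions:
    def test_positions_inside_neighborhoods(self):
        ps = zeroed_params(n=500, n_neighborhoods=8)
        ps.police_per_neighborhood = 3
        w = make_world(ps, seed=1)
        pts = draw_police_positions(w, ps)
        assert len(pts) == 24
        assert (pts[:, 0] >= 0).all() and (pts[:, 0] < ps.grid_width).all()

    def test_more_police_is_superset_under_same_seed(self):
        ps = zeroed_params(n=500, n_neighborhoods=4)
        ps.police_per_neighborhood = 2
        w1 = make_world(ps, seed=9)
        a = draw_police_positions(w1, ps).copy()
        ps2 = zeroed_params(n=500, n_neighborhoods=4)
        ps2.police_per_neighborhood = 4
        w2 = make_world(ps2, seed=9)
        b = draw_police_positions(w2, ps2)
        set_a = set(map(tuple, a))
        set_b = set(map(tuple, b))
        assert set_a <= set_b
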