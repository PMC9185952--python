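"""Annual timestep scheduler: the seven ordered sub-modules plus burn-in.

Each simulated year runs, in fixed order: (1) aging, (2) all-cause death
and rebirth, (3) recalculation of agent characteristics (substance use,
mental health, suicidality histories, firearm ownership then carrying),
(4) residential movement, (5) violence risk sets and suicide deaths,
(6) incident matching and resolution, (7) arrests, sentencing, and policy
bookkeeping.  Agents killed by homicide or suicide are replaced at the end
of the same step so the population size is constant at every step boundary.

Within module 3 every equation reads the same pre-update snapshot of the
state (synchronous update), with two documented exceptions that mirror the
model's stated structure: substance use disorders are conditional on the
*current* use state, and carrying reads the *current* ownership state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import justice as justice_mod
from . import policy as policy_mod
from . import violence as violence_mod
from .params import ARREST_TYPES, ParameterSet, sigmoid
from .population import MENTAL_DISORDERS, World, compute_features


@dataclass
class StepLog:
    """Per-year counts plus low-variance expected-count statistics."""

    year: int
    population: int
    deaths_all_cause: int = 0
    deaths_suicide: int = 0
    deaths_firearm_suicide: int = 0
    deaths_homicide: int = 0
    deaths_firearm_homicide: int = 0
    incidents: int = 0
    ipv_incidents: int = 0
    firearm_incidents: int = 0
    arrests: dict = field(default_factory=dict)
    misdemeanor_convictions: dict = field(default_factory=dict)
    felony_convictions: dict = field(default_factory=dict)
    movers: int = 0
    prohibitions_started: int = 0
    firearms_removed: int = 0
    owners: int = 0
    carriers: int = 0
    n_incarcerated: int = 0
    #: conditional expectations of event counts given the simulated state
    expected: dict = field(default_factory=dict)
    #: per (criterion, trigger): [person-years, firearm homicides,
    #: firearm suicides, expected firearm homicides, expected firearm suicides]
    subgroup: dict = field(default_factory=dict)

    def validate(self) -> None:
        counts = [
            self.deaths_all_cause, self.deaths_suicide, self.deaths_homicide,
            self.deaths_firearm_suicide, self.deaths_firearm_homicide,
            self.incidents, self.movers, self.prohibitions_started,
        ]
        assert all(c >= 0 for c in counts), "negative count in StepLog"
        assert self.deaths_firearm_homicide <= self.deaths_homicide
        assert self.deaths_firearm_suicide <= self.deaths_suicide
        assert self.deaths_homicide <= self.incidents

    def as_row(self) -> dict:
        row = {
            "year": self.year,
            "population": self.population,
            "deaths_all_cause": self.deaths_all_cause,
            "deaths_suicide": self.deaths_suicide,
            "deaths_firearm_suicide": self.deaths_firearm_suicide,
            "deaths_homicide": self.deaths_homicide,
            "deaths_firearm_homicide": self.deaths_firearm_homicide,
            "incidents": self.incidents,
            "ipv_incidents": self.ipv_incidents,
            "firearm_incidents": self.firearm_incidents,
            "movers": self.movers,
            "prohibitions_started": self.prohibitions_started,
            "firearms_removed": self.firearms_removed,
            "owners": self.owners,
            "carriers": self.carriers,
            "n_incarcerated": self.n_incarcerated,
        }
        for t in ARREST_TYPES:
            row[f"arrests_{t}"] = self.arrests.get(t, 0)
            row[f"misdemeanor_convictions_{t}"] = self.misdemeanor_convictions.get(t, 0)
            row[f"felony_convictions_{t}"] = self.felony_convictions.get(t, 0)
        return row


def logs_to_dataframe(logs: list[StepLog]) -> pd.DataFrame:
    return pd.DataFrame([lg.as_row() for lg in logs])


# --------------------------------------------------------------------------
# Sub-modules.  Each operates on a shared per-step context dict so the
# scheduler's ordering is explicit and testable.
# --------------------------------------------------------------------------


def _mod1_aging(world, params, policy, ctx):
    world.age += 1


def _mod2_mortality(world, params, policy, ctx):
    deaths = age_and_mortality(world, params)
    ctx["log"].deaths_all_cause = len(deaths)


def _mod3_characteristics(world, params, policy, ctx):
    ctx["log"].firearms_removed += update_characteristics(world, params)


def _mod4_movement(world, params, policy, ctx):
    ctx["log"].movers = move_agents(world, params)


def _mod5_risk(world, params, policy, ctx):
    violence_mod.draw_police_positions(world, params)
    feats = compute_features(world)
    ctx["feats"] = feats
    ctx["risk"] = violence_mod.compute_risk_sets(world, params, feats)


def _mod6_incidents(world, params, policy, ctx):
    log = ctx["log"]
    risk = ctx["risk"]
    expo = risk.exposures
    already = world.victimized_this_year
    already[:] = False
    pairs = violence_mod.match_incidents(
        world, params, risk, already_victimized=already
    )
    ipv_mask_p = risk.potential_ipv_perpetrators
    ipv_mask_v = risk.potential_ipv_victims
    ipv_pairs = violence_mod.match_incidents(
        world, params, risk, perps_mask=ipv_mask_p, victims_mask=ipv_mask_v,
        already_victimized=already, ipv=True,
    )
    incidents = []
    exp_fh = 0.0
    for plist, is_ipv in ((pairs, False), (ipv_pairs, True)):
        for perp, victim in plist:
            rec = violence_mod.resolve_incident(world, params, risk, perp, victim, is_ipv)
            incidents.append(rec)
            p_fh = float(risk.p_homicide_potential[victim]) * rec.firearm
            exp_fh += p_fh
            if p_fh:
                _add_subgroup_expected(world, victim, p_fh, 3, ctx)
            world.victimization_history[victim] = True
            world.perpetration_history[perp] = True
            if is_ipv:
                world.ipv_victimization_history[victim] = True
                world.ipv_perpetration_history[perp] = True
            if rec.firearm:
                world.gun_violence_history[perp] = True
                world.gun_violence_history[victim] = True
            if rec.homicide:
                world.alive[victim] = False
                log.deaths_homicide += 1
                if rec.firearm:
                    log.deaths_firearm_homicide += 1
                    _count_subgroup_death(world, victim, "fh", ctx)
    # suicide deaths (membership drawn in module 5)
    access_own = world.owns | world.carries | expo["firearm_access"]
    sui_idx = np.flatnonzero(risk.suicide_deaths)
    for a in sui_idx:
        firearm, source = violence_mod.attribute_firearm_suicide(world, expo, a)
        world.alive[a] = False
        log.deaths_suicide += 1
        if firearm:
            log.deaths_firearm_suicide += 1
            _count_subgroup_death(world, int(a), "fs", ctx)
    log.incidents = len(incidents)
    log.ipv_incidents = sum(1 for r in incidents if r.ipv)
    log.firearm_incidents = sum(1 for r in incidents if r.firearm)
    alive_p = np.where(world.alive | risk.suicide_deaths, risk.p_suicide, 0.0)
    exp_fs_vec = alive_p * access_own
    log.expected["firearm_suicide"] = float(exp_fs_vec.sum())
    log.expected["firearm_homicide"] = exp_fh
    for key, flags in world.ever_qualified.items():
        v = float(exp_fs_vec[flags].sum())
        if v:
            rec = log.subgroup.setdefault(key, [0, 0, 0, 0.0, 0.0])
            rec[4] += v
    ctx["incidents"] = incidents
    if ctx.get("incident_sink") is not None:
        ctx["incident_sink"].extend(incidents)


def _mod7_justice(world, params, policy, ctx):
    log = ctx["log"]
    justice_mod.release_and_decrement(world)
    feats = compute_features(world)
    events, expected = justice_mod.assign_arrests(world, params, feats)
    expo_gv = ctx["risk"].exposures["gun_violence"]
    events = justice_mod.charge_and_convict(events, world, params, feats, expo_gv)
    for e in events:
        log.arrests[e.arrest_type] = log.arrests.get(e.arrest_type, 0) + 1
        if e.convicted:
            d = log.misdemeanor_convictions if e.charge == "misdemeanor" else log.felony_convictions
            d[e.arrest_type] = d.get(e.arrest_type, 0) + 1
    log.expected.update(expected)
    hits = policy_mod.record_criterion_events(world, events)
    started, removed = policy_mod.check_and_apply(world, policy, hits)
    log.prohibitions_started = started
    log.firearms_removed += removed
    ctx["events"] = events
    if ctx.get("justice_sink") is not None:
        ctx["justice_sink"].extend(events)


_SUBMODULES = (
    _mod1_aging,
    _mod2_mortality,
    _mod3_characteristics,
    _mod4_movement,
    _mod5_risk,
    _mod6_incidents,
    _mod7_justice,
)


def _count_subgroup_death(world, agent, kind, ctx):
    sg = ctx["log"].subgroup
    for key, flags in world.ever_qualified.items():
        if flags[agent]:
            rec = sg.setdefault(key, [0, 0, 0, 0.0, 0.0])
            rec[1 if kind == "fh" else 2] += 1


def _add_subgroup_expected(world, agent, value, slot, ctx):
    sg = ctx["log"].subgroup
    for key, flags in world.ever_qualified.items():
        if flags[agent]:
            rec = sg.setdefault(key, [0, 0, 0, 0.0, 0.0])
            rec[slot] += value


def step(world: World, params: ParameterSet | None = None,
         policy: "policy_mod.PolicySpec | None" = None,
         incident_sink: list | None = None,
         justice_sink: list | None = None,
         _order: tuple = _SUBMODULES) -> StepLog:
    """Advance the world one year through the seven ordered sub-modules.

    ``_order`` exists only so tests can pin the dependence of results on
    the documented module order; production code never overrides it.
    """
    params = params if params is not None else world.params
    world.year += 1
    log = StepLog(year=world.year, population=world.n)
    ctx = {"log": log, "incident_sink": incident_sink, "justice_sink": justice_sink}
    for mod in _order:
        mod(world, params, policy, ctx)
    # end-of-step bookkeeping: replace violence deaths, roll yearly flags
    dead = np.flatnonzero(~world.alive)
    if len(dead):
        rebirth(world, dead)
    vic = world.victimized_this_year.copy()
    world.victimized_last_year[:] = vic
    world.victimized_last_year[dead] = False
    _update_neighborhood_violence(world, ctx.get("incidents", []))
    # subgroup person-years among ever-qualified survivors
    for key, flags in world.ever_qualified.items():
        py = int((flags & world.alive).sum())
        if py or key in log.subgroup:
            rec = log.subgroup.setdefault(key, [0, 0, 0, 0.0, 0.0])
            rec[0] = py
    log.owners = int(world.owns.sum())
    log.carriers = int(world.carries.sum())
    log.n_incarcerated = int(world.incarcerated.sum())
    log.expected["owners"] = float(log.owners)
    log.expected["carriers"] = float(log.carriers)
    log.validate()
    assert int(world.alive.sum()) == world.n, "population not conserved"
    return log


# --------------------------------------------------------------------------
# Module operations
# --------------------------------------------------------------------------


def age_and_mortality(world: World, params: ParameterSet) -> np.ndarray:
    """All-cause deaths from the age-sex schedule; immediate rebirth."""
    qf, qm, min_age = params.mortality_arrays()
    idx = np.clip(world.age - min_age, 0, len(qf) - 1)
    q = np.where(world.sex_male, qm[idx], qf[idx])
    u = world.rng["mortality"].random(world.n)
    deaths = np.flatnonzero((u < q) & world.alive)
    if len(deaths):
        rebirth(world, deaths)
    return deaths


def rebirth(world: World, idx: np.ndarray) -> None:
    """Replace dead agents in place: age 18, fresh demographics, clean
    histories, same neighborhood/cell and tie slots."""
    rng = world.rng["rebirth"]
    world.sample_demographics(idx, rng, age18=True)
    world.clear_state(idx)


def update_characteristics(world: World, params: ParameterSet) -> int:
    """Module 3: resample behavior states from the coefficient tables.

    Returns the number of firearms removed by force (ban while owning).
    """
    t = params.tables
    rng = world.rng["characteristics"]
    n = world.n
    feats = compute_features(world)  # synchronous snapshot
    feats.touch_tables(
        t[name] for name in (
            "drinking_light", "drinking_heavy", "alcohol_use_disorder",
            "drug_use", "drug_use_disorder", *MENTAL_DISORDERS,
            "mh_treatment", "suicidal_ideation", "suicide_attempt",
            "ownership", "carrying",
        )
    )

    # drinking status: two logistic probabilities, residual is non-drinker
    p_l = t["drinking_light"].prob(feats)
    p_h = t["drinking_heavy"].prob(feats)
    tot = p_l + p_h
    over = tot > 1.0
    if over.any():
        p_l = np.where(over, p_l / tot, p_l)
        p_h = np.where(over, p_h / tot, p_h)
    u = rng.random(n)
    world.drinking[:] = np.where(u < p_h, 2, np.where(u < p_h + p_l, 1, 0))

    # use disorders conditional on current use
    world.aud[:] = (world.drinking > 0) & (
        rng.random(n) < t["alcohol_use_disorder"].prob(feats)
    )
    world.drug_use[:] = rng.random(n) < t["drug_use"].prob(feats)
    world.dud[:] = world.drug_use & (rng.random(n) < t["drug_use_disorder"].prob(feats))

    for d in MENTAL_DISORDERS:
        world.mental[d][:] = rng.random(n) < t[d].prob(feats)
    world.mh_treatment[:] = rng.random(n) < t["mh_treatment"].prob(feats)
    world.mh_hospitalization[:] = world.mh_treatment & (rng.random(n) < 0.15)

    ideation = rng.random(n) < t["suicidal_ideation"].prob(feats)
    world.ideation_history |= ideation
    attempt = ideation & (rng.random(n) < t["suicide_attempt"].prob(feats))
    world.attempt_history |= attempt

    # firearm ownership, then carrying predicted by current ownership
    banned = (
        world.felony_ever
        | policy_mod.is_prohibited(world)
        | world.incarcerated
    )
    p_own = t["ownership"].prob(feats)
    draw_own = rng.random(n) < p_own
    removed = int((world.owns & banned).sum())
    world.owns[:] = draw_own & ~banned & world.alive
    world.ownership_history |= world.owns
    own_term = dict(t["carrying"].terms).get("owns_firearm", 0.0)
    lp = t["carrying"].linpred(feats) + own_term * (
        world.owns.astype(float) - feats["owns_firearm"]
    )
    p_carry = sigmoid(lp)
    world.carries[:] = (rng.random(n) < p_carry) & ~world.incarcerated & world.alive
    world.carrying_history |= world.carries
    return removed


def move_agents(world: World, params: ParameterSet) -> int:
    """Module 4: relocation to a uniformly chosen different neighborhood."""
    t = params.tables
    rng = world.rng["movement"]
    feats = compute_features(world)
    p = t["movement"].prob(feats)
    movers = (rng.random(world.n) < p) & world.alive & ~world.incarcerated
    idx = np.flatnonzero(movers)
    world.residence_duration[~movers] += 1
    if len(idx):
        n_nb = params.n_neighborhoods
        if n_nb > 1:
            shift = rng.integers(1, n_nb, size=len(idx))
            new_nb = (world.neighborhood[idx] + shift) % n_nb
        else:
            new_nb = world.neighborhood[idx]
        world.neighborhood[idx] = new_nb
        b = world.nb_bounds[new_nb]
        u = rng.random((len(idx), 2))
        world.x[idx] = (b[:, 0] + u[:, 0] * (b[:, 1] - b[:, 0])).astype(np.int32)
        world.y[idx] = (b[:, 2] + u[:, 1] * (b[:, 3] - b[:, 2])).astype(np.int32)
        world.residence_duration[idx] = 0
    return len(idx)


def _update_neighborhood_violence(world: World, incidents) -> None:
    counts = np.zeros(world.params.n_neighborhoods)
    for rec in incidents:
        counts[world.neighborhood[rec.victim]] += 1
    pop = np.maximum(np.bincount(world.neighborhood, minlength=world.params.n_neighborhoods), 1)
    # last-year violent incidents per 100 residents (a percent-scale covariate)
    world.nbhd_violence = counts / pop * 100.0


def run_simulation(params: ParameterSet, policy=None, years: int = 30,
                   burn_in: int | None = None, seed: int = 0,
                   incident_sink: list | None = None,
                   justice_sink: list | None = None,
                   build_network: bool = True,
                   world: World | None = None) -> tuple[World, list[StepLog]]:
    """Initialize, burn in, and run; returns post-burn-in logs only.

    The policy (if any) is active during burn-in as well, so observed years
    reflect its steady state.  ``world`` may supply a pre-built pristine
    World (e.g. a deep copy of a cached one) to skip initialization; it
    must be exactly as produced by ``initialize_population`` +
    ``build_social_network`` for the same (params, seed), or determinism
    guarantees are void.
    """
    from .network import build_social_network
    from .population import initialize_population

    burn_in = params.burn_in if burn_in is None else burn_in
    if world is None:
        world = initialize_population(params, seed)
        if build_network:
            build_social_network(world, params)
    logs = []
    for y in range(years + burn_in):
        lg = step(world, params, policy,
                  incident_sink=incident_sink if y >= burn_in else None,
                  justice_sink=justice_sink if y >= burn_in else None)
        if y >= burn_in:
            logs.append(lg)
    return world, logs
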