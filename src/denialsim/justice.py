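"""Arrests, charges, convictions, incarceration, felony firearm bans.

Four arrest types (violent, alcohol, drug, other) are drawn independently
per agent per year.  Each arrest is charged misdemeanor or felony from the
split equation (arrest-type indicators), then convicted or not from the
conviction equation (agent demographics, a borough-proxy covariate, the
charge class, and a per-type calibrated offset).  A felony conviction sets
the permanent ownership ban, removes any owned firearm, and draws
incarceration with a sentence length scaled by the agent's network
gun-violence exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ARREST_TYPES, ParameterSet
from .population import World


@dataclass
class JusticeEvent:
    year: int
    agent: int
    arrest_type: str  # violent | alcohol | drug | other
    charge: str = ""  # misdemeanor | felony (set after charging)
    convicted: bool = False
    sentence: int = 0  # years, 0 if none


def _event_features(world: World, feats, idx: np.ndarray, atype: str,
                    needed, felony: np.ndarray | None = None) -> dict[str, np.ndarray]:
    ev = {name: feats[name][idx] for name in needed if name in feats}
    k = len(idx)
    for t in ARREST_TYPES:
        ev[f"arrest_type_{t}"] = np.full(k, 1.0 if t == atype else 0.0)
    ev["charge_felony"] = felony.astype(float) if felony is not None else np.zeros(k)
    return ev


def assign_arrests(world: World, params: ParameterSet, feats: dict
                   ) -> tuple[list[JusticeEvent], dict[str, float]]:
    """Draw the four arrest types for every active agent.

    Returns the arrest-stage events plus expected per-type arrest and
    misdemeanor-conviction counts (sums of per-agent probabilities given
    the current state), which the calibration layer uses as low-variance
    rate statistics.
    """
    t = params.tables
    rng = world.rng["justice"]
    active = world.alive & ~world.incarcerated
    events: list[JusticeEvent] = []
    expected: dict[str, float] = {}
    offsets = params.conviction_type_offsets
    # snapshot everything this stage reads before arrest histories mutate
    feats.touch_tables(
        params.tables[n] for n in
        ("arrest_violent", "arrest_alcohol", "arrest_drug", "arrest_other",
         "misdemeanor_split", "conviction", "incarceration")
    )
    # split agent-level from event-level terms once (cheap expected counts)
    def split_linpred(table):
        agent_lp = np.zeros(world.n)
        event_coefs = {}
        for name, coef in table.terms:
            if name in feats:
                agent_lp = agent_lp + coef * feats[name]
            else:
                event_coefs[name] = coef
        return agent_lp + table.intercept, event_coefs
    mis_lp, mis_ev = split_linpred(t["misdemeanor_split"])
    conv_lp, conv_ev = split_linpred(t["conviction"])
    for atype in ARREST_TYPES:
        p = t[f"arrest_{atype}"].prob(feats)
        p = np.where(active, p, 0.0)
        draws = rng.random(world.n) < p
        expected[f"arrest_{atype}"] = float(p.sum())
        # expected misdemeanor convictions for this type given current state
        p_mis = 1.0 / (1.0 + np.exp(-(mis_lp + mis_ev.get(f"arrest_type_{atype}", 0.0))))
        p_conv = 1.0 / (1.0 + np.exp(-(conv_lp + conv_ev.get(f"arrest_type_{atype}", 0.0)
                                       + offsets.get(atype, 0.0))))
        expected[f"misdemeanor_conviction_{atype}"] = float((p * p_mis * p_conv).sum())
        for i in np.flatnonzero(draws):
            events.append(JusticeEvent(year=world.year, agent=int(i), arrest_type=atype))
        world.arrest_history[atype][draws] = True
    return events, expected


def charge_and_convict(events: list[JusticeEvent], world: World,
                       params: ParameterSet, feats: dict,
                       gun_violence_exposure: np.ndarray) -> list[JusticeEvent]:
    """Charge each arrest, draw convictions, apply felony consequences."""
    t = params.tables
    rng = world.rng["justice"]
    if not events:
        return events
    offsets = params.conviction_type_offsets
    w = params.network_influence_weight
    by_type: dict[str, list[JusticeEvent]] = {a: [] for a in ARREST_TYPES}
    for e in events:
        by_type[e.arrest_type].append(e)
    needed = {
        name
        for tbl in (t["misdemeanor_split"], t["conviction"], t["incarceration"])
        for name, _ in tbl.terms
    }
    for atype in ARREST_TYPES:
        evs = by_type[atype]
        if not evs:
            continue
        idx = np.array([e.agent for e in evs])
        evf = _event_features(world, feats, idx, atype, needed)
        p_mis = t["misdemeanor_split"].prob(evf)
        felony = rng.random(len(evs)) >= p_mis
        evf = _event_features(world, feats, idx, atype, needed, felony=felony)
        p_conv = t["conviction"].prob(evf, offset=offsets.get(atype, 0.0))
        convicted = rng.random(len(evs)) < p_conv
        p_inc = t["incarceration"].prob(evf)
        inc_draw = rng.random(len(evs)) < p_inc
        extra_years = rng.poisson(params.sentence_mean_extra_years, size=len(evs))
        for j, e in enumerate(evs):
            e.charge = "felony" if felony[j] else "misdemeanor"
            e.convicted = bool(convicted[j])
            if not e.convicted:
                continue
            if e.charge == "felony":
                a = e.agent
                world.felony_ever[a] = True
                world.owns[a] = False  # removed immediately and permanently
                if inc_draw[j]:
                    factor = 1.0 + w * float(gun_violence_exposure[a])
                    e.sentence = max(1, int(round((1 + extra_years[j]) * factor)))
                    world.incarcerated[a] = True
                    world.sentence_left[a] = e.sentence
    return events


def release_and_decrement(world: World) -> int:
    """Serve one year of every active sentence; release at zero."""
    serving = world.incarcerated & world.alive
    world.sentence_left[serving] -= 1
    released = serving & (world.sentence_left <= 0)
    world.incarcerated[released] = False
    world.sentence_left[released] = 0
    return int(released.sum())


def count_convictions(events: list[JusticeEvent]) -> dict[tuple[str, str], int]:
    """Convictions by (charge, arrest_type)."""
    out: dict[tuple[str, str], int] = {}
    for e in events:
        if e.convicted:
            key = (e.charge, e.arrest_type)
            out[key] = out.get(key, 0) + 1
    return out
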