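"""Firearm purchase-disqualification policies.

Twelve interventions: four qualifying criteria (alcohol-related misdemeanor
conviction, alcohol-related arrest, drug-related misdemeanor conviction,
drug-related arrest) crossed with three trigger/duration forms — one event
with a 5-year prohibition, one event with a 10-year prohibition, and two
events of the same kind within a 5-year window with a 10-year prohibition.

A qualifying agent has any owned firearm removed and cannot legally
purchase for the prohibition period; carrying (the illicit-market proxy) is
untouched.  Re-qualification resets the prohibition window.  The permanent
felony ban dominates any temporary prohibition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import CRITERIA, TRIGGERS, World

_ARREST_CRITERIA = {"alcohol_arrest": "alcohol", "drug_arrest": "drug"}
_CONVICTION_CRITERIA = {
    "alcohol_misdemeanor_conviction": "alcohol",
    "drug_misdemeanor_conviction": "drug",
}


@dataclass(frozen=True)
class PolicySpec:
    criterion: str  # one of CRITERIA
    trigger: str = "single_event"  # single_event | two_events_within_5yr
    duration: int = 5  # years, 5 or 10

    def __post_init__(self):
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion '{self.criterion}'")
        if self.trigger not in TRIGGERS:
            raise ValueError(f"unknown trigger '{self.trigger}'")
        if self.duration not in (5, 10):
            raise ValueError("duration must be 5 or 10 years")
        if self.trigger == "two_events_within_5yr" and self.duration != 10:
            raise ValueError("two-event trigger uses a 10-year prohibition")

    @property
    def label(self) -> str:
        return f"{self.criterion}:{self.trigger}:{self.duration}"


def parse_policy_token(token: str) -> PolicySpec:
    """Parse 'criterion:trigger:duration' with short trigger aliases."""
    parts = token.split(":")
    if len(parts) != 3:
        raise ValueError("policy token must be criterion:trigger:duration")
    crit, trig, dur = parts
    trig = {"single": "single_event", "two": "two_events_within_5yr"}.get(trig, trig)
    return PolicySpec(criterion=crit, trigger=trig, duration=int(dur))


def all_policies() -> list[PolicySpec]:
    """The 12 interventions: 4 criteria x {single/5, single/10, two/10}."""
    out = []
    for c in CRITERIA:
        out.append(PolicySpec(c, "single_event", 5))
        out.append(PolicySpec(c, "single_event", 10))
        out.append(PolicySpec(c, "two_events_within_5yr", 10))
    return out


def criterion_events_this_year(world: World, events, criterion: str) -> np.ndarray:
    """Agents with a qualifying event among this year's justice events."""
    hit = np.zeros(world.n, dtype=bool)
    if criterion in _ARREST_CRITERIA:
        atype = _ARREST_CRITERIA[criterion]
        for e in events:
            if e.arrest_type == atype:
                hit[e.agent] = True
    else:
        atype = _CONVICTION_CRITERIA[criterion]
        for e in events:
            if e.arrest_type == atype and e.convicted and e.charge == "misdemeanor":
                hit[e.agent] = True
    return hit


def record_criterion_events(world: World, events) -> dict[str, np.ndarray]:
    """Update per-criterion event recency and ever-qualified bookkeeping.

    Runs every step regardless of the active policy, so subgroup ("ever
    qualified") person-time is available for any criterion in any scenario.
    Returns the per-criterion hit masks for this year.
    """
    gap = world.params.two_event_max_gap
    hits = {}
    for c in CRITERIA:
        hit = criterion_events_this_year(world, events, c)
        hits[c] = hit
        last = world.last_event_year[c]
        prev = world.prev_event_year[c]
        prev[hit] = last[hit]
        last[hit] = world.year
        world.ever_qualified[(c, "single_event")][hit] = True
        two = hit & (world.year - prev <= gap)
        world.ever_qualified[(c, "two_events_within_5yr")][two] = True
    return hits


def qualifying_now(world: World, policy: PolicySpec,
                   hits: dict[str, np.ndarray]) -> np.ndarray:
    """Agents whose event history satisfies the policy trigger this year.

    Assumes :func:`record_criterion_events` already ran for this year.
    """
    hit = hits[policy.criterion]
    if policy.trigger == "single_event":
        return hit
    prev = world.prev_event_year[policy.criterion]
    return hit & (world.year - prev <= world.params.two_event_max_gap)


def check_and_apply(world: World, policy: PolicySpec | None,
                    hits: dict[str, np.ndarray]) -> tuple[int, int]:
    """Start/extend prohibitions for agents qualifying this year.

    Returns (prohibitions started or extended, firearms removed).  The
    prohibition covers years ``t+1 .. t+duration``; the owned firearm is
    removed at qualification time.  Carrying is deliberately untouched.
    """
    if policy is None:
        return 0, 0
    qual = qualifying_now(world, policy, hits) & world.alive
    n_qual = int(qual.sum())
    if n_qual == 0:
        return 0, 0
    until = world.year + policy.duration
    world.prohibited_until[qual] = np.maximum(world.prohibited_until[qual], until)
    removed = int((qual & world.owns).sum())
    world.owns[qual] = False
    return n_qual, removed


def is_prohibited(world: World, year: int | None = None) -> np.ndarray:
    """Vector of active-prohibition flags at ``year`` (default: world clock)."""
    y = world.year if year is None else year
    return world.prohibited_until >= y


def agent_is_prohibited(world: World, agent: int, year: int) -> bool:
    return bool(world.prohibited_until[agent] >= year)
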