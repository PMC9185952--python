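"""Suicide and interpersonal-violence risks, spatial matching, attribution.

Risk-set membership is drawn from the logistic tables; suicide and
homicide-victim probabilities carry the social-network influence as a
multiplicative odds factor.  Potential perpetrators then search, in random
order, a square radius around their cell for a not-yet-victimized potential
victim; victims with a police officer within the protection radius are
protected.  A matched incident becomes a homicide when the victim is in the
potential-homicide-victim set, and a death is firearm-related when either
party owns, carries, or can reach a firearm through a social tie (the
victim-access clause is configurable off).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .network import network_exposures, odds_multiplier
from .params import ParameterSet
from .population import World, compute_features


@dataclass
class IncidentRecord:
    year: int
    perpetrator: int
    victim: int
    ipv: bool
    homicide: bool
    firearm: bool
    firearm_source: str  # ownership | carrying | network | none


@dataclass
class RiskSets:
    potential_perpetrators: np.ndarray  # bool (N,)
    potential_victims: np.ndarray
    potential_ipv_perpetrators: np.ndarray
    potential_ipv_victims: np.ndarray
    homicide_potential: np.ndarray
    p_homicide_potential: np.ndarray  # float, for expected-count statistics
    suicide_deaths: np.ndarray  # bool
    p_suicide: np.ndarray
    exposures: dict[str, np.ndarray]


def compute_risk_sets(world: World, params: ParameterSet,
                      feats: dict | None = None) -> RiskSets:
    """Draw all violence risk-set memberships and suicide deaths."""
    t = params.tables
    rng = world.rng["risk"]
    feats = feats if feats is not None else compute_features(world)
    n = world.n
    expo = network_exposures(world)
    net_factor = 1.0 + params.network_influence_weight * expo["gun_violence"]
    active = world.alive & ~world.incarcerated

    p_perp = t["perpetration"].prob(feats)
    p_vict = t["victimization"].prob(feats)
    partnered = world.marital == 1
    p_ipv_p = t["ipv_perpetration"].prob(feats)
    p_ipv_v = t["ipv_victimization"].prob(feats)
    p_hom = odds_multiplier(t["homicide_victim_potential"].prob(feats), net_factor)
    p_sui = odds_multiplier(t["suicide_death"].prob(feats), net_factor)

    perps = active & (rng.random(n) < p_perp)
    victs = active & (rng.random(n) < p_vict)
    ipv_p = active & partnered & (rng.random(n) < p_ipv_p)
    ipv_v = active & partnered & (rng.random(n) < p_ipv_v)
    hom_pot = rng.random(n) < p_hom
    suicides = world.alive & (rng.random(n) < p_sui)
    # suicide decedents leave the incident pool this step
    perps &= ~suicides
    victs &= ~suicides
    ipv_p &= ~suicides
    ipv_v &= ~suicides
    return RiskSets(
        potential_perpetrators=perps,
        potential_victims=victs,
        potential_ipv_perpetrators=ipv_p,
        potential_ipv_victims=ipv_v,
        homicide_potential=hom_pot,
        p_homicide_potential=p_hom,
        suicide_deaths=suicides,
        p_suicide=p_sui,
        exposures=expo,
    )


def draw_police_positions(world: World, params: ParameterSet) -> np.ndarray:
    """Redraw police positions uniformly within each neighborhood.

    Drawn in "waves" (one officer per neighborhood per wave) so that, for a
    fixed seed, a configuration with more officers per neighborhood places
    a superset of the officers of a configuration with fewer — the basis of
    the protection-monotonicity property.
    """
    rng = world.rng["police"]
    k = params.police_per_neighborhood
    if k == 0:
        world.police_xy = np.empty((0, 2), dtype=np.int32)
        return world.police_xy
    u = rng.random((k, params.n_neighborhoods, 2))
    b = world.nb_bounds  # (n_nb, 4): x0, x1, y0, y1
    xs = (b[:, 0] + u[:, :, 0] * (b[:, 1] - b[:, 0])).astype(np.int32)
    ys = (b[:, 2] + u[:, :, 1] * (b[:, 3] - b[:, 2])).astype(np.int32)
    world.police_xy = np.column_stack([xs.ravel(), ys.ravel()])
    return world.police_xy


def _protected_mask(world: World, params: ParameterSet, idx: np.ndarray) -> np.ndarray:
    """Victims with a police officer within the protection radius."""
    if len(world.police_xy) == 0 or len(idx) == 0:
        return np.zeros(len(idx), dtype=bool)
    p = np.inf if params.distance_metric == "chebyshev" else 2
    tree = cKDTree(world.police_xy)
    pts = np.column_stack([world.x[idx], world.y[idx]])
    d, _ = tree.query(pts, k=1, p=p)
    return d <= params.police_protection_radius


def match_incidents(world: World, params: ParameterSet, risk: RiskSets,
                    perps_mask: np.ndarray | None = None,
                    victims_mask: np.ndarray | None = None,
                    already_victimized: np.ndarray | None = None,
                    ipv: bool = False) -> list[tuple[int, int]]:
    """Match perpetrators to victims within the search radius.

    Perpetrators are iterated in random order; each takes the nearest
    eligible (unprotected, not-yet-victimized) potential victim within the
    radius.  Equidistant candidates are broken uniformly at random via a
    pre-shuffle of the victim array.  Returns (perp, victim) pairs and
    marks ``already_victimized`` in place when provided.
    """
    perps_mask = risk.potential_perpetrators if perps_mask is None else perps_mask
    victims_mask = risk.potential_victims if victims_mask is None else victims_mask
    rng = world.rng["match"]
    perp_idx = np.flatnonzero(perps_mask)
    vict_idx = np.flatnonzero(victims_mask)
    if already_victimized is None:
        already_victimized = np.zeros(world.n, dtype=bool)
    if len(perp_idx) == 0 or len(vict_idx) == 0:
        rng.permutation(len(perp_idx))  # keep stream use stable
        return []
    vict_idx = vict_idx[rng.permutation(len(vict_idx))]  # random tie order
    protected = _protected_mask(world, params, vict_idx)
    eligible = vict_idx[~protected]
    if len(eligible) == 0:
        rng.permutation(len(perp_idx))
        return []
    p = np.inf if params.distance_metric == "chebyshev" else 2
    tree = cKDTree(np.column_stack([world.x[eligible], world.y[eligible]]))
    order = rng.permutation(len(perp_idx))
    perp_order = perp_idx[order]
    k = min(16, len(eligible))
    _, nbrs = tree.query(
        np.column_stack([world.x[perp_order], world.y[perp_order]]),
        k=k, p=p, distance_upper_bound=params.perp_search_radius + 0.5,
    )
    if k == 1:
        nbrs = nbrs.reshape(-1, 1)
    pairs: list[tuple[int, int]] = []
    n_elig = len(eligible)
    elig_list = eligible.tolist()
    taken = already_victimized[eligible].tolist()  # victimized view of eligible
    nbrs_list = nbrs.tolist()
    for row, perp in enumerate(perp_order.tolist()):
        chosen = -1
        saw_sentinel = False
        for cand in nbrs_list[row]:
            if cand >= n_elig:  # sentinel: past the search radius
                saw_sentinel = True
                break
            if taken[cand] or elig_list[cand] == perp:
                continue
            chosen = cand
            break
        if chosen < 0 and not saw_sentinel and k < n_elig:
            # all k nearest were taken: widen the query for this perpetrator
            kk = k
            while chosen < 0:
                kk = min(kk * 4, n_elig)
                _, wide = tree.query(
                    [world.x[perp], world.y[perp]], k=kk, p=p,
                    distance_upper_bound=params.perp_search_radius + 0.5,
                )
                for cand in np.atleast_1d(wide)[k:].tolist():
                    if cand >= n_elig:
                        saw_sentinel = True
                        break
                    if taken[cand] or elig_list[cand] == perp:
                        continue
                    chosen = int(cand)
                    break
                if saw_sentinel or kk >= n_elig:
                    break
        if chosen >= 0:
            v = elig_list[chosen]
            taken[chosen] = True
            already_victimized[v] = True
            pairs.append((perp, v))
    return pairs


def resolve_incident(world: World, params: ParameterSet, risk: RiskSets,
                     perp: int, victim: int, ipv: bool) -> IncidentRecord:
    """Complete an incident: homicide flag and firearm attribution."""
    homicide = bool(risk.homicide_potential[victim])
    firearm, source = attribute_firearm_incident(world, params, risk.exposures, perp, victim)
    return IncidentRecord(
        year=world.year, perpetrator=perp, victim=victim, ipv=ipv,
        homicide=homicide, firearm=firearm, firearm_source=source,
    )


def attribute_firearm_incident(world, params, expo, perp, victim):
    """Firearm source for an incident, precedence ownership > carrying > network,
    checking the perpetrator then the victim at each level."""
    victim_counts = params.victim_access_counts
    if world.owns[perp] or (victim_counts and world.owns[victim]):
        return True, "ownership"
    if world.carries[perp] or (victim_counts and world.carries[victim]):
        return True, "carrying"
    if expo["firearm_access"][perp] or (victim_counts and expo["firearm_access"][victim]):
        return True, "network"
    return False, "none"


def attribute_firearm_suicide(world, expo, agent):
    if world.owns[agent]:
        return True, "ownership"
    if world.carries[agent]:
        return True, "carrying"
    if expo["firearm_access"][agent]:
        return True, "network"
    return False, "none"
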