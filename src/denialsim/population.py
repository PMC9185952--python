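"""Agent population, neighborhoods, spatial grid, and feature extraction.

Agents are stored struct-of-arrays on a :class:`World`: every attribute is a
length-N numpy array, which keeps the per-year update loop vectorized.  The
grid is a single rectangular lattice partitioned into rectangular
neighborhood blocks with areas proportional to configured population shares;
multiple agents may share a cell.  Distances are Chebyshev by default
(square radii), configurable to Euclidean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ParameterSet, sigmoid

NEG_YEAR = -(10**6)  # sentinel for "never happened"

#: Named per-module random streams (common-random-numbers contract: each
#: module draws from its own generator, so extra draws in one module never
#: perturb another's).
STREAM_NAMES = (
    "init",
    "network",
    "mortality",
    "rebirth",
    "characteristics",
    "movement",
    "risk",
    "match",
    "police",
    "justice",
)

MENTAL_DISORDERS = ("asb", "gad", "ied", "mdd", "mania", "ptsd", "psychosis")
CRITERIA = (
    "alcohol_misdemeanor_conviction",
    "alcohol_arrest",
    "drug_misdemeanor_conviction",
    "drug_arrest",
)
TRIGGERS = ("single_event", "two_events_within_5yr")


def make_streams(seed: int) -> dict[str, np.random.Generator]:
    return {
        name: np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), i])))
        for i, name in enumerate(STREAM_NAMES)
    }


@dataclass
class Neighborhood:
    """Rectangular block of the grid with its own police and covariates."""

    id: int
    x0: int
    x1: int  # exclusive
    y0: int
    y1: int  # exclusive
    share: float


def partition_grid(width: int, height: int, n: int, shares=None) -> list[Neighborhood]:
    """Tile the grid into n rectangles with areas ~ population shares.

    Rows of blocks: ~sqrt(n) rows, each row split into columns.  Shares
    default to equal.
    """
    if shares is None:
        shares = np.full(n, 1.0 / n)
    shares = np.asarray(shares, dtype=float)
    shares = shares / shares.sum()
    nrows = max(1, int(round(np.sqrt(n))))
    base = n // nrows
    extra = n % nrows
    counts = [base + (1 if r < extra else 0) for r in range(nrows)]
    blocks: list[Neighborhood] = []
    idx = 0
    y_edges = np.round(np.linspace(0, height, nrows + 1)).astype(int)
    for r, cnt in enumerate(counts):
        row_share = shares[idx : idx + cnt]
        cum = np.concatenate([[0.0], np.cumsum(row_share / row_share.sum())])
        x_edges = np.round(cum * width).astype(int)
        for c in range(cnt):
            blocks.append(
                Neighborhood(
                    id=idx + c,
                    x0=int(x_edges[c]),
                    x1=int(max(x_edges[c + 1], x_edges[c] + 1)),
                    y0=int(y_edges[r]),
                    y1=int(max(y_edges[r + 1], y_edges[r] + 1)),
                    share=float(shares[idx + c]),
                )
            )
        idx += cnt
    return blocks


def _largest_remainder(n_total: int, shares: np.ndarray) -> np.ndarray:
    raw = shares / shares.sum() * n_total
    base = np.floor(raw).astype(int)
    rem = n_total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


class World:
    """Grid + neighborhoods + agent arrays + ties + clock + RNG streams."""

    def __init__(self, params: ParameterSet, seed: int):
        self.params = params
        self.seed = int(seed)
        self.year = 0
        self.n = int(params.population_size)
        self.rng = make_streams(seed)
        self.neighborhoods = partition_grid(
            params.grid_width, params.grid_height, params.n_neighborhoods
        )
        self.nb_bounds = np.array(
            [[b.x0, b.x1, b.y0, b.y1] for b in self.neighborhoods], dtype=np.int32
        )
        self.ties = None  # set by network.build_social_network
        self.police_xy = np.empty((0, 2), dtype=np.int32)
        self.nbhd_violence = np.zeros(params.n_neighborhoods)  # per-1000, last year
        n = self.n
        z = lambda dt: np.zeros(n, dtype=dt)
        self.age = z(np.int32)
        self.sex_male = z(bool)
        self.race = z(np.int8)  # 0 white, 1 black, 2 hispanic, 3 other
        self.income = z(np.int8)  # 0 low, 1 mid, 2 high
        self.education = z(np.int8)
        self.marital = z(np.int8)  # 0 single, 1 partnered, 2 other
        self.neighborhood = z(np.int32)
        self.x = z(np.int32)
        self.y = z(np.int32)
        self.drinking = z(np.int8)  # 0 none, 1 light/moderate, 2 heavy
        self.aud = z(bool)
        self.drug_use = z(bool)
        self.dud = z(bool)
        self.mental = {d: z(bool) for d in MENTAL_DISORDERS}
        self.mh_treatment = z(bool)
        self.mh_hospitalization = z(bool)
        self.ideation_history = z(bool)
        self.attempt_history = z(bool)
        self.owns = z(bool)
        self.carries = z(bool)
        self.ownership_history = z(bool)
        self.carrying_history = z(bool)
        self.victimization_history = z(bool)
        self.perpetration_history = z(bool)
        self.victimized_last_year = z(bool)
        self.victimized_this_year = z(bool)
        self.ipv_victimization_history = z(bool)
        self.ipv_perpetration_history = z(bool)
        self.gun_violence_history = z(bool)
        self.arrest_history = {t: z(bool) for t in ("violent", "alcohol", "drug", "other")}
        self.felony_ever = z(bool)
        self.incarcerated = z(bool)
        self.sentence_left = z(np.int16)
        self.prohibited_until = np.full(n, NEG_YEAR, dtype=np.int64)
        self.residence_duration = z(np.int16)
        self.alive = np.ones(n, dtype=bool)
        # per-criterion event recency (for two-event windows)
        self.last_event_year = {c: np.full(n, NEG_YEAR, dtype=np.int64) for c in CRITERIA}
        self.prev_event_year = {c: np.full(n, NEG_YEAR, dtype=np.int64) for c in CRITERIA}
        # ever-qualified flags for all criterion x trigger combos (subgroups)
        self.ever_qualified = {
            (c, t): z(bool) for c in CRITERIA for t in TRIGGERS
        }

    # -- geometry ----------------------------------------------------------

    def random_cells_in_neighborhood(self, nb_id, count, rng) -> tuple[np.ndarray, np.ndarray]:
        x0, x1, y0, y1 = self.nb_bounds[nb_id]
        pts = rng.integers(0, [x1 - x0, y1 - y0], size=(count, 2))
        return (pts[:, 0] + x0).astype(np.int32), (pts[:, 1] + y0).astype(np.int32)

    # -- demographics ------------------------------------------------------

    def sample_demographics(self, idx: np.ndarray, rng, age18: bool = False) -> None:
        """(Re)draw demographic attributes for agents ``idx`` from marginals."""
        d = self.params.demographics
        k = len(idx)
        if k == 0:
            return
        if age18:
            self.age[idx] = 18
        else:
            ages = np.arange(18, 85)
            w = np.exp(-float(d["age_decay"]) * (ages - 18))
            self.age[idx] = rng.choice(ages, size=k, p=w / w.sum())
        self.sex_male[idx] = rng.random(k) < float(d["sex_male"])
        self.race[idx] = rng.choice(4, size=k, p=np.asarray(d["race"], float))
        self.income[idx] = rng.choice(3, size=k, p=np.asarray(d["income"], float))
        self.education[idx] = rng.choice(3, size=k, p=np.asarray(d["education"], float))
        self.marital[idx] = rng.choice(3, size=k, p=np.asarray(d["marital"], float))

    def clear_state(self, idx: np.ndarray) -> None:
        """Reset all non-demographic state (rebirth agents start clean)."""
        self.drinking[idx] = 0
        self.aud[idx] = False
        self.drug_use[idx] = False
        self.dud[idx] = False
        for d in MENTAL_DISORDERS:
            self.mental[d][idx] = False
        self.mh_treatment[idx] = False
        self.mh_hospitalization[idx] = False
        self.ideation_history[idx] = False
        self.attempt_history[idx] = False
        self.owns[idx] = False
        self.carries[idx] = False
        self.ownership_history[idx] = False
        self.carrying_history[idx] = False
        self.victimization_history[idx] = False
        self.perpetration_history[idx] = False
        self.victimized_last_year[idx] = False
        self.victimized_this_year[idx] = False
        self.ipv_victimization_history[idx] = False
        self.ipv_perpetration_history[idx] = False
        self.gun_violence_history[idx] = False
        for t in self.arrest_history:
            self.arrest_history[t][idx] = False
        self.felony_ever[idx] = False
        self.incarcerated[idx] = False
        self.sentence_left[idx] = 0
        self.prohibited_until[idx] = NEG_YEAR
        self.residence_duration[idx] = 0
        self.alive[idx] = True
        for c in CRITERIA:
            self.last_event_year[c][idx] = NEG_YEAR
            self.prev_event_year[c][idx] = NEG_YEAR
        for key in self.ever_qualified:
            self.ever_qualified[key][idx] = False

    # -- exports -----------------------------------------------------------

    def to_agent_dataframe(self) -> pd.DataFrame:
        cols = {
            "id": np.arange(self.n),
            "age": self.age,
            "sex_male": self.sex_male,
            "race": self.race,
            "income": self.income,
            "education": self.education,
            "marital": self.marital,
            "neighborhood": self.neighborhood,
            "x": self.x,
            "y": self.y,
            "drinking": self.drinking,
            "aud": self.aud,
            "drug_use": self.drug_use,
            "dud": self.dud,
            "mh_treatment": self.mh_treatment,
            "mh_hospitalization": self.mh_hospitalization,
            "ideation_history": self.ideation_history,
            "attempt_history": self.attempt_history,
            "owns_firearm": self.owns,
            "carries_firearm": self.carries,
            "ownership_history": self.ownership_history,
            "carrying_history": self.carrying_history,
            "victimization_history": self.victimization_history,
            "perpetration_history": self.perpetration_history,
            "ipv_victimization_history": self.ipv_victimization_history,
            "ipv_perpetration_history": self.ipv_perpetration_history,
            "felony_ever": self.felony_ever,
            "incarcerated": self.incarcerated,
            "sentence_left": self.sentence_left,
            "prohibited_until": self.prohibited_until,
            "residence_duration": self.residence_duration,
            "alive": self.alive,
        }
        for d in MENTAL_DISORDERS:
            cols[d] = self.mental[d]
        for t, arr in self.arrest_history.items():
            cols[f"arrest_history_{t}"] = arr
        return pd.DataFrame(cols)

    def export_snapshot(self, directory) -> None:
        """Agents CSV + ties CSV + JSON metadata, for debugging/fixtures."""
        import os

        os.makedirs(directory, exist_ok=True)
        self.to_agent_dataframe().to_csv(os.path.join(directory, "agents.csv"), index=False)
        if self.ties is not None:
            pd.DataFrame(self.ties.edges, columns=["agent_a", "agent_b"]).to_csv(
                os.path.join(directory, "ties.csv"), index=False
            )
        meta = {
            "year": int(self.year),
            "n": int(self.n),
            "seed": int(self.seed),
            "config_hash": self.params.config_hash(),
        }
        with open(os.path.join(directory, "meta.json"), "w") as fh:
            json.dump(meta, fh, indent=1)


# --------------------------------------------------------------------------
# Features
# --------------------------------------------------------------------------


_FEATURE_FUNCS = {
    "age_std": lambda w: (w.age - 40.0) / 20.0,
    "young_adult": lambda w: w.age < 30,
    "male": lambda w: w.sex_male,
    "race_black": lambda w: w.race == 1,
    "race_hispanic": lambda w: w.race == 2,
    "race_other": lambda w: w.race == 3,
    "income_low": lambda w: w.income == 0,
    "income_high": lambda w: w.income == 2,
    "educ_low": lambda w: w.education == 0,
    "educ_high": lambda w: w.education == 2,
    "partnered": lambda w: w.marital == 1,
    "drinking_light": lambda w: w.drinking == 1,
    "drinking_heavy": lambda w: w.drinking == 2,
    "aud": lambda w: w.aud,
    "drug_use": lambda w: w.drug_use,
    "dud": lambda w: w.dud,
    "mh_treatment": lambda w: w.mh_treatment,
    "ideation_history": lambda w: w.ideation_history,
    "attempt_history": lambda w: w.attempt_history,
    "owns_firearm": lambda w: w.owns,
    "carries_firearm": lambda w: w.carries,
    "ownership_history": lambda w: w.ownership_history,
    "carrying_history": lambda w: w.carrying_history,
    "victimization_history": lambda w: w.victimization_history,
    "perpetration_history": lambda w: w.perpetration_history,
    "victimized_last_year": lambda w: w.victimized_last_year,
    "ipv_victimization_history": lambda w: w.ipv_victimization_history,
    "ipv_perpetration_history": lambda w: w.ipv_perpetration_history,
    "arrest_history_violent": lambda w: w.arrest_history["violent"],
    "arrest_history_alcohol": lambda w: w.arrest_history["alcohol"],
    "arrest_history_drug": lambda w: w.arrest_history["drug"],
    "arrest_history_other": lambda w: w.arrest_history["other"],
    "any_arrest_history": lambda w: (
        w.arrest_history["violent"] | w.arrest_history["alcohol"]
        | w.arrest_history["drug"] | w.arrest_history["other"]
    ),
    "residence_short": lambda w: w.residence_duration < 2,
    "neighborhood_violence": lambda w: w.nbhd_violence[w.neighborhood],
    "neighborhood_group": lambda w: ((w.neighborhood % 5) - 2.0) / 2.0,
}
for _d in MENTAL_DISORDERS:
    _FEATURE_FUNCS[_d] = (lambda name: (lambda w: w.mental[name]))(_d)


# features whose lambda returns a live world array: copied on access so a
# cached feature is a true snapshot even though the world mutates in place
_PASSTHROUGH = frozenset(
    ["aud", "drug_use", "dud", "mh_treatment", "ideation_history",
     "attempt_history", "owns_firearm", "carries_firearm",
     "ownership_history", "carrying_history", "victimization_history",
     "perpetration_history", "victimized_last_year",
     "ipv_victimization_history", "ipv_perpetration_history",
     "arrest_history_violent", "arrest_history_alcohol",
     "arrest_history_drug", "arrest_history_other"]
    + list(MENTAL_DISORDERS)
)


class FeatureView:
    """Lazy snapshot of agent-level predictors.

    Values are materialized (and cached) on first access, so each pipeline
    stage only pays for the predictors its tables actually reference.
    Stages that mutate state they also read must :meth:`touch` the
    predictors they need *before* mutating, which freezes the snapshot.
    Boolean features stay boolean (numpy promotes them in arithmetic).
    """

    __slots__ = ("_world", "_cache")

    def __init__(self, world: "World"):
        self._world = world
        self._cache: dict[str, np.ndarray] = {}

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self._cache[name]
        except KeyError:
            val = np.asarray(_FEATURE_FUNCS[name](self._world))
            if name in _PASSTHROUGH:
                val = val.copy()
            self._cache[name] = val
            return val

    def touch(self, names) -> None:
        """Materialize ``names`` now (snapshot before in-place mutation)."""
        for n in names:
            self[n]

    def touch_tables(self, tables) -> None:
        for t in tables:
            for name, _ in t.terms:
                if name in _FEATURE_FUNCS:
                    self[name]

    def __contains__(self, name: str) -> bool:
        return name in _FEATURE_FUNCS

    def get(self, name, default=None):
        return self[name] if name in self else default

    def keys(self):
        return _FEATURE_FUNCS.keys()

    def values(self):
        return (self[k] for k in _FEATURE_FUNCS)

    def __len__(self):
        return len(_FEATURE_FUNCS)


def compute_features(world: World) -> FeatureView:
    """Snapshot view of all agent-level predictors (lazily materialized)."""
    return FeatureView(world)


# --------------------------------------------------------------------------
# Initialization
# --------------------------------------------------------------------------


def initialize_population(params: ParameterSet, seed: int) -> World:
    """Create a World with N agents placed and initial behavior states drawn.

    Agents are allocated to neighborhoods by largest-remainder rounding of
    the configured shares (equal by default), placed uniformly within their
    neighborhood's block, and given demographics from the configured
    marginals.  Behavior states are then drawn from the coefficient tables
    applied to demographics (histories start empty and are seeded from the
    first draw); burn-in brings the state distribution to equilibrium.
    """
    world = World(params, seed)
    rng = world.rng["init"]
    n = world.n
    cells_total = params.grid_width * params.grid_height
    if cells_total < params.n_neighborhoods:
        raise ValueError(
            f"grid {params.grid_width}x{params.grid_height} too small for "
            f"{params.n_neighborhoods} neighborhoods"
        )
    shares = np.array([b.share for b in world.neighborhoods])
    counts = _largest_remainder(n, shares)
    nb_ids = np.repeat(np.arange(params.n_neighborhoods), counts)
    world.neighborhood[:] = nb_ids
    for b in world.neighborhoods:
        mask = nb_ids == b.id
        k = int(mask.sum())
        xs, ys = world.random_cells_in_neighborhood(b.id, k, rng)
        world.x[mask] = xs
        world.y[mask] = ys
    world.sample_demographics(np.arange(n), rng)
    world.residence_duration[:] = rng.integers(0, 10, size=n).astype(np.int16)
    _draw_initial_states(world, rng)
    return world


def _draw_initial_states(world: World, rng) -> None:
    """Draw initial behavior states from the coefficient tables.

    Current states come from one pass through the annual equations;
    ever-history flags are seeded from a lifetime-exposure approximation,
    ``P(history) = 1 - (1 - p_annual)^(age - 18)``, so the initial
    population sits near the stationary age profile instead of drifting
    toward it over decades of burn-in.
    """
    t = world.params.tables
    n = world.n
    years = np.maximum(world.age - 18, 1).astype(float)

    def lifetime(p_annual):
        return rng.random(n) < 1.0 - np.power(1.0 - np.minimum(p_annual, 0.999), years)

    feats = compute_features(world)
    p_l = t["drinking_light"].prob(feats)
    p_h = t["drinking_heavy"].prob(feats)
    tot = p_l + p_h
    over = tot > 1.0
    if over.any():
        p_l = np.where(over, p_l / tot, p_l)
        p_h = np.where(over, p_h / tot, p_h)
    u = rng.random(n)
    world.drinking[:] = np.where(u < p_h, 2, np.where(u < p_h + p_l, 1, 0))
    feats = compute_features(world)
    world.aud[:] = (world.drinking > 0) & (rng.random(n) < t["alcohol_use_disorder"].prob(feats))
    world.drug_use[:] = rng.random(n) < t["drug_use"].prob(feats)
    feats = compute_features(world)
    world.dud[:] = world.drug_use & (rng.random(n) < t["drug_use_disorder"].prob(feats))
    feats = compute_features(world)
    for d in MENTAL_DISORDERS:
        world.mental[d][:] = rng.random(n) < t[d].prob(feats)
    feats = compute_features(world)
    world.mh_treatment[:] = rng.random(n) < t["mh_treatment"].prob(feats)
    world.mh_hospitalization[:] = world.mh_treatment & (rng.random(n) < 0.15)

    # event histories at their lifetime-exposure levels
    world.victimization_history[:] = lifetime(t["victimization"].prob(feats))
    world.perpetration_history[:] = lifetime(t["perpetration"].prob(feats))
    feats = compute_features(world)
    partnered = world.marital == 1
    world.ipv_victimization_history[:] = partnered & lifetime(t["ipv_victimization"].prob(feats))
    world.ipv_perpetration_history[:] = partnered & lifetime(t["ipv_perpetration"].prob(feats))
    feats = compute_features(world)
    for atype in ("violent", "alcohol", "drug", "other"):
        world.arrest_history[atype][:] = lifetime(t[f"arrest_{atype}"].prob(feats))
    feats = compute_features(world)
    world.felony_ever[:] = lifetime(_annual_felony_conviction_prob(world, feats))
    world.ideation_history[:] = lifetime(t["suicidal_ideation"].prob(feats))
    feats = compute_features(world)
    world.attempt_history[:] = world.ideation_history & lifetime(
        t["suicide_attempt"].prob(feats)
    )
    # firearm involvement history (network exposure source) at its
    # lifetime level, approximated from incident-involvement probabilities
    world.gun_violence_history[:] = lifetime(
        0.9 * (t["victimization"].prob(feats) + t["perpetration"].prob(feats))
    )
    feats = compute_features(world)
    world.owns[:] = (rng.random(n) < t["ownership"].prob(feats)) & ~world.felony_ever
    world.ownership_history[:] = world.owns | lifetime(t["ownership"].prob(feats))
    feats = compute_features(world)
    world.carries[:] = rng.random(n) < t["carrying"].prob(feats)
    world.carrying_history[:] = world.carries | lifetime(t["carrying"].prob(feats))


def _annual_felony_conviction_prob(world: World, feats) -> np.ndarray:
    """Per-agent annual probability of any felony conviction (all types)."""
    t = world.params.tables
    offsets = world.params.conviction_type_offsets

    def lp_split(table):
        agent = np.zeros(world.n)
        ev = {}
        for name, coef in table.terms:
            if name in feats:
                agent = agent + coef * feats[name]
            else:
                ev[name] = coef
        return agent + table.intercept, ev

    mis_lp, mis_ev = lp_split(t["misdemeanor_split"])
    conv_lp, conv_ev = lp_split(t["conviction"])
    p_no_felony = np.ones(world.n)
    for atype in ("violent", "alcohol", "drug", "other"):
        p_arr = t[f"arrest_{atype}"].prob(feats)
        p_mis = sigmoid(mis_lp + mis_ev.get(f"arrest_type_{atype}", 0.0))
        p_conv = sigmoid(conv_lp + conv_ev.get(f"arrest_type_{atype}", 0.0)
                         + conv_ev.get("charge_felony", 0.0)
                         + offsets.get(atype, 0.0))
        p_no_felony = p_no_felony * (1.0 - p_arr * (1.0 - p_mis) * p_conv)
    return 1.0 - p_no_felony


def check_agent_invariants(world: World) -> list[str]:
    """Exhaustive post-hoc scan of the Agent invariants; returns violations."""
    problems = []
    if (world.aud & (world.drinking == 0)).any():
        problems.append("aud without drinking")
    if (world.dud & ~world.drug_use).any():
        problems.append("dud without drug use")
    if (world.felony_ever & world.owns).any():
        problems.append("felon owns firearm")
    if (world.owns & (world.prohibited_until >= world.year)).any():
        problems.append("prohibited agent owns firearm")
    if (world.age < 18).any():
        problems.append("agent under 18")
    counts = np.bincount(world.neighborhood, minlength=world.params.n_neighborhoods)
    if counts.sum() != world.n:
        problems.append("agents not partitioned into neighborhoods")
    return problems
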