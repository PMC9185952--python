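"""Baseline social network: homophilous tie formation and risk exposures.

Each agent draws a target degree from U{degree_min..degree_max} (default
1-9, mean 5).  Ties are formed by stochastic candidate sampling: a large
pool of candidate pairs is proposed (part spatially local, part global),
every pair is scored by weighted attribute similarity plus spatial
proximity, and pairs are accepted greedily in score order while both
endpoints have spare capacity.  A cleanup pass pairs leftover stubs
regardless of score so the realized mean degree stays at the target mean.
The network is fixed for the whole run; when an agent dies, the rebirth
agent inherits the tie slots, keeping the degree distribution stationary.

Exposure features: whether any tie owns a firearm, carries one, or has a
history of involvement in gun violence.  The last enters homicide/suicide
probabilities and sentence length through a multiplicative odds factor
``1 + w * exposure`` with ``w = network_influence_weight``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet
from .population import World


@dataclass
class TieStore:
    """Undirected ties as an edge array plus a CSR adjacency view."""

    edges: np.ndarray  # (E, 2) int32, a < b
    target_degree: np.ndarray  # (N,) int
    indptr: np.ndarray  # (N+1,)
    neighbors: np.ndarray  # (2E,)

    @classmethod
    def from_edges(cls, edges: np.ndarray, target_degree: np.ndarray, n: int) -> "TieStore":
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if len(edges):
            edges = np.sort(edges, axis=1)
            edges = np.unique(edges, axis=0)
        ends = np.concatenate([edges[:, 0], edges[:, 1]])
        nbrs = np.concatenate([edges[:, 1], edges[:, 0]])
        order = np.argsort(ends, kind="stable")
        sorted_ends = ends[order]
        neighbors = nbrs[order]
        indptr = np.searchsorted(sorted_ends, np.arange(n + 1))
        return cls(edges=edges, target_degree=np.asarray(target_degree),
                   indptr=indptr, neighbors=neighbors)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    def neighbor_any(self, flag: np.ndarray) -> np.ndarray:
        """For each agent, whether any neighbor has ``flag`` set."""
        vals = flag[self.neighbors].astype(np.int64)
        if len(vals) == 0:
            return np.zeros(len(self.indptr) - 1, dtype=bool)
        csum = np.concatenate([[0], np.cumsum(vals)])
        return (csum[self.indptr[1:]] - csum[self.indptr[:-1]]) > 0

    def neighbors_of(self, i: int) -> np.ndarray:
        return self.neighbors[self.indptr[i] : self.indptr[i + 1]]

    def to_edge_csv(self) -> str:
        lines = ["agent_a,agent_b"]
        lines += [f"{a},{b}" for a, b in self.edges]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_edge_csv(cls, text: str, n: int) -> "TieStore":
        rows = [ln for ln in text.strip().splitlines() if ln and not ln.startswith("agent_a")]
        edges = np.array([[int(v) for v in ln.split(",")] for ln in rows], dtype=np.int64)
        deg = np.zeros(n, dtype=np.int64)
        return cls.from_edges(edges if len(rows) else np.empty((0, 2)), deg, n)


def _similarity_scores(world: World, a: np.ndarray, b: np.ndarray, w: dict) -> np.ndarray:
    """Weighted similarity for candidate pairs (a[k], b[k])."""
    max_dim = max(world.params.grid_width, world.params.grid_height)
    s = np.zeros(len(a))
    if w.get("age", 0):
        s += w["age"] * (1.0 - np.minimum(np.abs(world.age[a] - world.age[b]), 20) / 20.0)
    if w.get("sex", 0):
        s += w["sex"] * (world.sex_male[a] == world.sex_male[b])
    if w.get("race", 0):
        s += w["race"] * (world.race[a] == world.race[b])
    if w.get("education", 0):
        s += w["education"] * (world.education[a] == world.education[b])
    if w.get("ownership", 0):
        s += w["ownership"] * (world.owns[a] == world.owns[b])
    if w.get("drinking", 0):
        s += w["drinking"] * (world.drinking[a] == world.drinking[b])
    if w.get("drug_use", 0):
        s += w["drug_use"] * (world.drug_use[a] == world.drug_use[b])
    if w.get("proximity", 0):
        if world.params.distance_metric == "euclidean":
            d = np.hypot(world.x[a] - world.x[b], world.y[a] - world.y[b])
        else:
            d = np.maximum(np.abs(world.x[a] - world.x[b]), np.abs(world.y[a] - world.y[b]))
        s += w["proximity"] * (1.0 - d / max_dim)
    return s


def _greedy_accept(a, b, capacity):
    """Accept distinct pairs in order while both endpoints have capacity.

    ``a``/``b`` must already be deduplicated; ``capacity`` is mutated.
    """
    out = []
    cap = capacity.tolist()  # plain-int ops in the hot loop
    for ia, ib in zip(a.tolist(), b.tolist()):
        if cap[ia] <= 0 or cap[ib] <= 0:
            continue
        cap[ia] -= 1
        cap[ib] -= 1
        out.append((ia, ib))
    capacity[:] = cap
    return out


def build_social_network(world: World, params: ParameterSet, seed=None) -> TieStore:
    """Build the fixed baseline network and attach it to the world.

    Construction is best effort: realized degree can fall short of target
    when capacity runs out, but the cleanup pass keeps the shortfall to the
    odd-stub level, so the realized mean degree tracks the target mean.
    """
    rng = world.rng["network"] if seed is None else np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([int(seed), 1]))
    )
    n = world.n
    targets = rng.integers(params.degree_min, params.degree_max + 1, size=n)
    w = params.homophily_weights
    n_stubs = int(targets.sum())
    # Candidate pool: ~2 proposals per stub local (same neighborhood) and
    # ~2 global, scored and accepted greedily from the best score down.
    m = max(2 * n, int(1.3 * n_stubs))
    a_glob = rng.integers(0, n, size=m)
    b_glob = rng.integers(0, n, size=m)
    # local proposals: permute agents within each neighborhood
    order_nb = np.argsort(world.neighborhood, kind="stable")
    a_loc = np.concatenate([order_nb, order_nb])
    b_loc = np.empty_like(a_loc)
    # pair each agent with a random same-neighborhood partner
    counts = np.bincount(world.neighborhood, minlength=params.n_neighborhoods)
    offs = np.concatenate([[0], np.cumsum(counts)])
    for rep in range(2):
        seg = np.empty(n, dtype=np.int64)
        for j in range(params.n_neighborhoods):
            lo, hi = offs[j], offs[j + 1]
            if hi > lo:
                seg[lo:hi] = order_nb[lo + rng.permutation(hi - lo)]
        b_loc[rep * n : (rep + 1) * n] = seg
    a_all = np.concatenate([a_glob, a_loc])
    b_all = np.concatenate([b_glob, b_loc])
    keep = a_all != b_all
    a_all, b_all = a_all[keep], b_all[keep]
    lo = np.minimum(a_all, b_all)
    hi = np.maximum(a_all, b_all)
    keys = lo * n + hi
    _, uniq_idx = np.unique(keys, return_index=True)
    a_all, b_all = lo[uniq_idx], hi[uniq_idx]
    scores = _similarity_scores(world, a_all, b_all, w)
    scores = scores + 1e-6 * rng.random(len(scores))  # random tie-break
    order = np.argsort(-scores, kind="stable")
    capacity = targets.astype(np.int64).copy()
    accepted = _greedy_accept(a_all[order], b_all[order], capacity)
    taken = {ia * n + ib for ia, ib in accepted}
    # Cleanup: pair leftover stubs randomly so mean degree hits the target.
    for _ in range(3):
        left = np.flatnonzero(capacity > 0)
        if len(left) < 2:
            break
        stubs = np.repeat(left, capacity[left])
        stubs = stubs[rng.permutation(len(stubs))]
        if len(stubs) % 2:
            stubs = stubs[:-1]
        pa, pb = stubs[0::2], stubs[1::2]
        keep = pa != pb
        pa, pb = pa[keep], pb[keep]
        progress = False
        for ia, ib in zip(pa.tolist(), pb.tolist()):
            if capacity[ia] <= 0 or capacity[ib] <= 0:
                continue
            key = (ia * n + ib) if ia < ib else (ib * n + ia)
            if key in taken:
                continue
            taken.add(key)
            capacity[ia] -= 1
            capacity[ib] -= 1
            accepted.append((ia, ib) if ia < ib else (ib, ia))
            progress = True
        if not progress:
            break
    edges = np.array(accepted, dtype=np.int64) if accepted else np.empty((0, 2), dtype=np.int64)
    ties = TieStore.from_edges(edges, targets, n)
    world.ties = ties
    return ties


def network_exposures(world: World, ties: TieStore | None = None) -> dict[str, np.ndarray]:
    """Boolean exposure arrays for every agent (vectorized).

    ``firearm_access``: a tie owns or carries (usable for an incident);
    ``gun_violence``: a tie was ever involved in firearm violence.
    """
    ties = ties if ties is not None else world.ties
    friend_owns = ties.neighbor_any(world.owns & world.alive)
    friend_carries = ties.neighbor_any(world.carries & world.alive)
    friend_gun_violence = ties.neighbor_any(world.gun_violence_history & world.alive)
    return {
        "friend_owns": friend_owns,
        "friend_carries": friend_carries,
        "firearm_access": friend_owns | friend_carries,
        "gun_violence": friend_gun_violence,
    }


def agent_exposures(world: World, agent: int, ties: TieStore | None = None) -> dict[str, bool]:
    """Per-agent exposure record (same flags as :func:`network_exposures`)."""
    ties = ties if ties is not None else world.ties
    nbrs = ties.neighbors_of(agent)
    nbrs = nbrs[world.alive[nbrs]] if len(nbrs) else nbrs
    fo = bool(world.owns[nbrs].any()) if len(nbrs) else False
    fc = bool(world.carries[nbrs].any()) if len(nbrs) else False
    gv = bool(world.gun_violence_history[nbrs].any()) if len(nbrs) else False
    return {
        "friend_owns": fo,
        "friend_carries": fc,
        "firearm_access": fo or fc,
        "gun_violence": gv,
    }


def odds_multiplier(p: np.ndarray, factor: np.ndarray) -> np.ndarray:
    """Scale probabilities on the odds scale: odds' = odds * factor."""
    odds = p / (1.0 - p) * factor
    return odds / (1.0 + odds)
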