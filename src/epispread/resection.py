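"""Virtual-resection search: effective-distance surrogate + simulated annealing.

A virtual resection zeroes all links of the chosen nodes (network size fixed).
Exhaustive search over node subsets is infeasible, so optimal resections of a
given size S are found in four steps:

1. restrict candidates to the seed and its first and second neighbours
   (unweighted hops);
2. simulated annealing over size-S subsets maximizing a fast structural
   surrogate — the mean *effective distance* from the seed, with per-link
   length ``d_ij = 1 - ln(w_ij / sum_k w_ik)`` and multi-source shortest
   paths (the standard effective-distance construction; the per-node
   averaging convention is this package's reconstruction);
3. SI evaluation (propagation extent at t0) of the top-k surrogate sets;
4. selection of the extent-minimal set.

Summaries per patient: R90 (smallest resection with >= 90% reduction in
propagation, i_R <= 0.1), R100 (zero non-seed infections in every run), R1
(best single-node resection), the relative sizes s90/s100, and the seed's
link budget E_RA = S_RA * kappa_RA.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .network import BrainNetwork, khop_neighborhood
from .si_dynamics import SIConfig, propagation_extent

__all__ = [
    "EffectiveDistanceMap",
    "SAConfig",
    "ResectionOutcome",
    "ResectionCurve",
    "SeedStats",
    "effective_distance",
    "unreachable_cap",
    "surrogate_objective",
    "optimize_resection",
    "evaluate_and_select",
    "resection_curve",
    "seed_stats",
]


@dataclass(frozen=True)
class EffectiveDistanceMap:
    """Per-ROI effective distance to the seed (0 on the seed, inf unreachable)."""

    roi_ids: np.ndarray
    distances: np.ndarray
    seed_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if (d[np.isfinite(d)] < 0).any():
            raise ValueError("effective distances must be nonnegative")
        object.__setattr__(self, "distances", d)


def _distance_graph(net: BrainNetwork) -> np.ndarray:
    """Directed per-link effective lengths d_ij = 1 - ln(w_ij / s_i).

    Rows with zero strength (isolated nodes) have no outgoing edges.  All
    finite lengths are >= 1, so 0 unambiguously encodes 'no edge' for the
    dense shortest-path routines.
    """
    w = net.weights
    s = w.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(s > 0, w / s, 0.0)
        d = np.where(p > 0, 1.0 - np.log(p), 0.0)
    return d


def effective_distance(net: BrainNetwork, seed) -> EffectiveDistanceMap:
    """Multi-source shortest-path effective distance from the seed to every ROI."""
    seed = sorted(int(s) for s in seed)
    if not seed:
        raise ValueError("seed must be nonempty")
    d = _distance_graph(net)
    seed_pos = net.rois.positions(seed)
    dist = dijkstra(d, directed=True, indices=seed_pos, min_only=True)
    dist[seed_pos] = 0.0
    return EffectiveDistanceMap(
        roi_ids=net.rois.roi_ids.copy(), distances=dist, seed_ids=tuple(seed)
    )


def unreachable_cap(net: BrainNetwork, d_graph: np.ndarray | None = None) -> float:
    """Finite stand-in distance for unreachable nodes: d-graph diameter + 1."""
    d = _distance_graph(net) if d_graph is None else d_graph
    full = dijkstra(d, directed=True)
    finite = full[np.isfinite(full)]
    return float(finite.max()) + 1.0 if finite.size else 1.0


def surrogate_objective(
    net: BrainNetwork,
    seed,
    resected,
    cap: float | None = None,
    d_graph: np.ndarray | None = None,
) -> float:
    """Mean effective distance from the seed after a virtual resection.

    Per-link lengths are frozen on the *intact* network (resection deletes
    routes; it does not re-normalize the surviving transition probabilities
    — re-normalizing would let a resection shorten distances elsewhere).
    Averaged over all non-seed nodes; resected and disconnected nodes
    contribute the finite cap (diameter of the intact d-graph + 1).  Larger
    values mean better containment, and adding a node to the resection can
    never decrease the objective.

    ``d_graph`` may carry the precomputed intact effective-length matrix to
    amortize repeated calls during optimization.
    """
    seed = sorted(int(s) for s in seed)
    resected = set(int(r) for r in resected)
    if d_graph is None:
        d_graph = _distance_graph(net)
    if cap is None:
        cap = unreachable_cap(net, d_graph)
    n = net.n
    seed_pos = net.rois.positions(seed)
    res_pos = net.rois.positions(sorted(resected)) if resected else np.array([], int)
    live_sources = np.setdiff1d(seed_pos, res_pos)
    if live_sources.size:
        d = d_graph
        if res_pos.size:
            d = d_graph.copy()
            d[res_pos, :] = 0.0
            d[:, res_pos] = 0.0
        dist = dijkstra(d, directed=True, indices=live_sources, min_only=True)
    else:
        dist = np.full(n, np.inf)
    dist = np.where(np.isfinite(dist), np.minimum(dist, cap), cap)
    if res_pos.size:
        dist[res_pos] = cap
    mask = np.ones(n, dtype=bool)
    mask[seed_pos] = False
    return float(dist[mask].mean())


@dataclass(frozen=True)
class SAConfig:
    """Simulated-annealing schedule for the surrogate search.

    Moves swap one resected node with one candidate outside the set.  The
    initial temperature is calibrated on a short random walk so ~80% of
    downhill moves are accepted; geometric cooling by ``cooling`` every
    |pool| proposals; ``proposals_per_node * |pool|`` proposals per restart.
    """

    proposals_per_node: int = 200
    cooling: float = 0.95
    restarts: int = 3
    top_k: int = 10
    accept_frac: float = 0.8
    calibration_moves: int = 50


def optimize_resection(
    net: BrainNetwork,
    seed,
    S: int,
    sa_cfg: SAConfig = SAConfig(),
    rng_seed: int = 0,
    pool=None,
    cap: float | None = None,
    d_graph: np.ndarray | None = None,
    exclude=(),
) -> list[tuple[tuple[int, ...], float]]:
    """Best size-S resections by surrogate value, via simulated annealing.

    The candidate pool defaults to the seed plus its first and second
    neighbours; ``exclude`` removes forbidden ROIs (e.g. eloquent cortex)
    from the pool — no further clinical logic is applied.  Returns up to
    ``top_k`` distinct sets as (sorted ROI ids, surrogate value), best first.
    """
    seed = sorted(int(s) for s in seed)
    if pool is None:
        pool = sorted(khop_neighborhood(net, seed, 2))
    else:
        pool = sorted(int(p) for p in pool)
    pool = [p for p in pool if p not in set(int(e) for e in exclude)]
    if S > len(pool):
        raise ValueError(f"resection size {S} exceeds candidate pool {len(pool)}")
    if d_graph is None:
        d_graph = _distance_graph(net)
    if cap is None:
        cap = unreachable_cap(net, d_graph)
    if S == len(pool):
        return [(tuple(pool), surrogate_objective(net, seed, pool, cap, d_graph))]

    rng = np.random.default_rng(rng_seed)
    pool_arr = np.asarray(pool, dtype=int)
    best: dict[tuple[int, ...], float] = {}

    def obj(subset) -> float:
        key = tuple(sorted(int(x) for x in subset))
        if key not in best:
            best[key] = surrogate_objective(net, seed, key, cap, d_graph)
        return best[key]

    n_pool = len(pool)
    n_props = sa_cfg.proposals_per_node * n_pool
    for _ in range(sa_cfg.restarts):
        current = rng.choice(pool_arr, size=S, replace=False)
        cur_val = obj(current)
        # temperature calibration on a random walk
        deltas = []
        walk = current.copy()
        walk_val = cur_val
        for _ in range(sa_cfg.calibration_moves):
            cand = _swap_move(walk, pool_arr, rng)
            v = obj(cand)
            if v < walk_val:
                deltas.append(walk_val - v)
            walk, walk_val = cand, v
        t0 = (np.median(deltas) / -np.log(sa_cfg.accept_frac)) if deltas else 1.0
        temp = max(t0, 1e-12)
        for it in range(n_props):
            cand = _swap_move(current, pool_arr, rng)
            v = obj(cand)
            dv = v - cur_val
            if dv >= 0 or rng.random() < np.exp(dv / temp):
                current, cur_val = cand, v
            if (it + 1) % n_pool == 0:
                temp *= sa_cfg.cooling

    ranked = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(k, v) for k, v in ranked[: sa_cfg.top_k]]


def _swap_move(current: np.ndarray, pool: np.ndarray, rng) -> np.ndarray:
    out = np.setdiff1d(pool, current, assume_unique=False)
    new = current.copy()
    new[rng.integers(current.size)] = out[rng.integers(out.size)]
    return new


@dataclass(frozen=True)
class ResectionOutcome:
    """One evaluated resection: set, extent at t0, normalized i_R, surrogate."""

    resected: tuple[int, ...]
    size: int
    extent: float
    i_r: float
    surrogate: float
    zero_spread: bool

    def __post_init__(self) -> None:
        if self.size != len(self.resected):
            raise ValueError("size does not match resected set")


def evaluate_and_select(
    net: BrainNetwork,
    seed,
    candidates,
    cfg: SIConfig,
    baseline_extent: float | None = None,
    cap: float | None = None,
) -> tuple[ResectionOutcome, list[ResectionOutcome]]:
    """SI fine-tuning: simulate each candidate set, return the extent-minimal one.

    ``candidates`` is a list of (roi-id tuple, surrogate value) or plain
    tuples.  Ties in extent are broken by surrogate rank (candidate order),
    then lexicographic ROI order.
    """
    cand = [(tuple(sorted(c[0] if isinstance(c, tuple) and len(c) == 2
                          and not isinstance(c[0], (int, np.integer)) else c)),
             (c[1] if isinstance(c, tuple) and len(c) == 2
              and not isinstance(c[0], (int, np.integer)) else np.nan))
            for c in candidates]
    if not cand:
        raise ValueError("no candidate resections")
    if baseline_extent is None:
        baseline_extent = propagation_extent(net, seed, (), cfg)["extent"]
    outcomes = []
    for subset, sur in cand:
        r = propagation_extent(net, seed, subset, cfg, baseline_extent=baseline_extent)
        if np.isnan(sur):
            sur = surrogate_objective(net, seed, subset, cap)
        outcomes.append(
            ResectionOutcome(
                resected=subset,
                size=len(subset),
                extent=r["extent"],
                i_r=r["i_r"],
                surrogate=float(sur),
                zero_spread=r["zero_spread"],
            )
        )
    best_idx = min(
        range(len(outcomes)),
        key=lambda i: (outcomes[i].extent, i, outcomes[i].resected),
    )
    return outcomes[best_idx], outcomes


@dataclass(frozen=True)
class SeedStats:
    """Seed size, mean degree of the seed nodes and link budget E_RA."""

    s_ra: int
    kappa_ra: float
    e_ra: float


def seed_stats(net: BrainNetwork, seed) -> SeedStats:
    """Mean number of links of the seed nodes and E_RA = S_RA * kappa_RA."""
    seed = sorted(int(s) for s in seed)
    if not seed:
        raise ValueError("seed must be nonempty")
    deg = net.degrees()[net.rois.positions(seed)]
    kappa_ra = float(deg.mean())
    return SeedStats(s_ra=len(seed), kappa_ra=kappa_ra, e_ra=len(seed) * kappa_ra)


@dataclass
class ResectionCurve:
    """Optimal resections per size with R90/R100/R1 summaries."""

    outcomes: list[ResectionOutcome]
    baseline_extent: float
    r90: ResectionOutcome | None
    r100: ResectionOutcome | None
    r1: ResectionOutcome
    stats: SeedStats

    @property
    def s90(self) -> float | None:
        return self.r90.size / self.stats.s_ra if self.r90 else None

    @property
    def s100(self) -> float | None:
        return self.r100.size / self.stats.s_ra if self.r100 else None

    @property
    def i_r1(self) -> float:
        return self.r1.i_r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "S": [o.size for o in self.outcomes],
                "resected": [",".join(map(str, o.resected)) for o in self.outcomes],
                "I_R": [o.extent for o in self.outcomes],
                "i_R": [o.i_r for o in self.outcomes],
                "zero_spread": [o.zero_spread for o in self.outcomes],
            }
        )

    def summary(self) -> dict:
        return {
            "S_RA": self.stats.s_ra,
            "kappa_RA": self.stats.kappa_ra,
            "E_RA": self.stats.e_ra,
            "baseline_extent": self.baseline_extent,
            "R90_size": self.r90.size if self.r90 else None,
            "R90_set": list(self.r90.resected) if self.r90 else None,
            "R100_size": self.r100.size if self.r100 else None,
            "R100_set": list(self.r100.resected) if self.r100 else None,
            "s90": self.s90,
            "s100": self.s100,
            "i_R1": self.i_r1,
            "R1_node": self.r1.resected[0],
        }


def resection_curve(
    net: BrainNetwork,
    seed,
    si_cfg: SIConfig,
    sa_cfg: SAConfig = SAConfig(),
    rng_seed: int = 0,
    s_max: int | None = None,
    exclude=(),
) -> ResectionCurve:
    """Optimal virtual resections of increasing size S.

    For each S, candidates are the top-k surrogate sets from simulated
    annealing, a monotone-hull candidate (best size-(S-1) set plus the best
    single surrogate addition), and — at S = S_RA — the trivial full-seed
    resection.  The scan stops at the first size achieving 100% reduction
    (zero non-seed infections in all runs), at the latest at S_RA, where the
    full-seed resection guarantees it.  Extents are non-increasing in S by
    the monotone hull.
    """
    seed = sorted(int(s) for s in seed)
    stats = seed_stats(net, seed)
    d_graph = _distance_graph(net)
    cap = unreachable_cap(net, d_graph)
    baseline = propagation_extent(net, seed, (), si_cfg)["extent"]
    excluded = set(int(e) for e in exclude)
    pool = [p for p in sorted(khop_neighborhood(net, seed, 2))
            if p not in excluded]
    s_stop = min(s_max or stats.s_ra, len(pool))
    ss = np.random.SeedSequence(rng_seed)
    outcomes: list[ResectionOutcome] = []
    prev_best: ResectionOutcome | None = None
    r90 = r100 = None
    for S in range(1, s_stop + 1):
        sa_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
        cands = optimize_resection(net, seed, S, sa_cfg, rng_seed=sa_seed,
                                   pool=pool, cap=cap, d_graph=d_graph)
        cand_sets = list(cands)
        if prev_best is not None:
            rest = [p for p in pool if p not in prev_best.resected]
            if rest:
                add = max(
                    rest,
                    key=lambda x: surrogate_objective(
                        net, seed, prev_best.resected + (x,), cap, d_graph),
                )
                cand_sets.append((tuple(sorted(prev_best.resected + (add,))), np.nan))
        if S == stats.s_ra and not (excluded & set(seed)):
            cand_sets.append((tuple(seed), np.nan))
        best, _ = evaluate_and_select(net, seed, cand_sets, si_cfg,
                                      baseline_extent=baseline, cap=cap)
        if prev_best is not None and prev_best.extent < best.extent:
            # monotone hull: a larger resection never spreads more
            best = ResectionOutcome(
                resected=best.resected, size=S, extent=prev_best.extent,
                i_r=prev_best.i_r, surrogate=best.surrogate,
                zero_spread=prev_best.zero_spread,
            )
        outcomes.append(best)
        prev_best = best
        if r90 is None and best.i_r <= 0.1:
            r90 = best
        if r100 is None and best.zero_spread:
            r100 = best
        if r100 is not None:
            break
    return ResectionCurve(
        outcomes=outcomes,
        baseline_extent=baseline,
        r90=r90,
        r100=r100,
        r1=outcomes[0],
        stats=stats,
    )
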