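"""Susceptible-Infected (SI) epidemic dynamics on weighted brain networks.

Seizure propagation is abstracted as an SI process: nodes are susceptible or
infected, infected nodes stay infected, and at each synchronous step an
infected node i transmits to a susceptible neighbour j with probability
``beta * w_ij``.  The module provides

* a vectorized Monte-Carlo simulator (probability maps ``p_i(t)``, infection
  curves ``I(t)``, mean infection times ``t_i``),
* the slow-propagation (beta -> 0) limit, where exactly one node is infected
  per step with probability proportional to its total weight to the infected
  set — the first-passage activation ordering used for pattern fitting, and
* post-resection propagation extents ``I_R(t0)`` and the normalized ``i_R``.

To compare networks of different density the transmission rate is tied to the
density via ``beta * theta = const`` (default 4e-4), i.e. beta = 0.01 at 4%
density.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numba
import numpy as np
import pandas as pd

from .network import BrainNetwork, apply_resection

__all__ = [
    "SIConfig",
    "PropagationResult",
    "simulate_si",
    "mean_infection_times",
    "slow_propagation_pattern",
    "propagation_extent",
]

BETA_THETA_DEFAULT = 4e-4


@dataclass(frozen=True)
class SIConfig:
    """Simulation settings.

    ``beta`` may be None, in which case it is derived from the density
    control ``beta = beta_theta_product / theta`` of the network at hand.
    ``t0`` is the fixed evaluation horizon for propagation extents; ``T``
    the maximum integration horizon for probability maps (default 10*N,
    chosen so censoring is negligible on connected networks).
    """

    beta: float | None = None
    t0: int = 50
    T: int | None = None
    n_runs: int = 10_000
    rng_seed: int = 0
    beta_theta_product: float = BETA_THETA_DEFAULT

    def __post_init__(self) -> None:
        if self.beta is not None and not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must be in [0, 1]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.T is not None and self.t0 > self.T:
            raise ValueError("t0 must not exceed T")

    def resolve_beta(self, theta: float) -> float:
        if self.beta is not None:
            return self.beta
        return self.beta_theta_product / theta

    def resolve_T(self, n: int) -> int:
        return self.T if self.T is not None else 10 * n


@dataclass
class PropagationResult:
    """Aggregated Monte-Carlo output of an SI simulation.

    ``p[i, t]`` is the probability that ROI i first becomes infected at step
    t (seed nodes have p[:, 0] = 1).  ``infected_curve[t]`` is the mean
    fraction of infected nodes by step t, seed included.  ``mean_times`` are
    expected first-infection steps with censoring at the horizon T
    (``censored_frac`` reports the per-ROI fraction of censored runs).
    ``printed_time_sum`` is the literal sum over t of p_i(t), kept for audit:
    it is a total infection probability (<= 1), not a time.
    """

    p: np.ndarray
    infected_curve: np.ndarray
    mean_times: np.ndarray
    censored_frac: np.ndarray
    seed_ids: tuple[int, ...]
    n_runs: int
    T: int
    beta: float
    watch_hit_fraction: float | None = None

    @property
    def printed_time_sum(self) -> np.ndarray:
        return self.p.sum(axis=1)

    def total_infection_prob(self) -> np.ndarray:
        return self.p.sum(axis=1)

    def to_frames(self, rois) -> tuple[pd.DataFrame, pd.DataFrame]:
        per_roi = pd.DataFrame(
            {
                "roi_id": rois.roi_ids,
                "mean_time": self.mean_times,
                "total_infection_prob": self.total_infection_prob(),
                "censored_frac": self.censored_frac,
            }
        )
        curve = pd.DataFrame(
            {"t": np.arange(self.infected_curve.size), "I": self.infected_curve}
        )
        return per_roi, curve


def simulate_si(
    net: BrainNetwork,
    seed,
    cfg: SIConfig,
    watch_ids=None,
    chunk_size: int = 2000,
) -> PropagationResult:
    """Monte-Carlo synchronous SI simulation.

    Per run, a susceptible node j becomes infected at step t+1 with
    probability ``1 - prod_{i infected at t} (1 - beta * w_ij)``, evaluated
    from the state at step t.  Runs are vectorized in chunks; a single
    master seed drives deterministic per-chunk streams.

    ``watch_ids``: optional ROI ids; the result then reports the fraction of
    runs in which any watched node was infected by ``t0`` (used for the
    zero-spread criterion of resections).
    """
    seed = sorted(int(s) for s in seed)
    if not seed:
        raise ValueError("seed must be nonempty")
    n = net.n
    beta = cfg.resolve_beta(net.theta)
    if not (0.0 <= beta <= 1.0):
        raise ValueError(f"derived beta {beta} outside [0, 1]")
    T = cfg.resolve_T(n)
    seed_pos = net.rois.positions(seed)
    watch_pos = net.rois.positions(list(watch_ids)) if watch_ids is not None else None

    # log survival per potential transmission; float32 keeps the per-step
    # BLAS update cheap at N_R = 1e4
    L = np.log1p(-np.clip(beta * net.weights, 0.0, 1.0 - 1e-15)).astype(np.float32)
    np.fill_diagonal(L, 0.0)

    p_counts = np.zeros((n, T + 1), dtype=np.int64)
    inf_by_t = np.zeros(T + 1, dtype=np.float64)
    time_sum = np.zeros(n, dtype=np.float64)
    censored = np.zeros(n, dtype=np.int64)
    watch_hits = 0

    ss = np.random.SeedSequence(cfg.rng_seed)
    n_chunks = int(np.ceil(cfg.n_runs / chunk_size))
    child_seeds = ss.spawn(n_chunks)
    runs_left = cfg.n_runs
    for ci in range(n_chunks):
        r = min(chunk_size, runs_left)
        runs_left -= r
        rng = np.random.default_rng(child_seeds[ci])
        infected = np.zeros((r, n), dtype=bool)
        infected[:, seed_pos] = True
        first_time = np.full((r, n), -1, dtype=np.int32)
        first_time[:, seed_pos] = 0
        # cumulative log survival from all infected nodes so far
        logsurv = infected.astype(np.float32) @ L
        count_inf = np.full(r, len(seed_pos), dtype=np.int64)
        inf_counts_t = np.zeros(T + 1, dtype=np.float64)
        inf_counts_t[0] = count_inf.sum()
        t_stop = T
        for t in range(1, T + 1):
            probs = -np.expm1(logsurv)
            probs[infected] = 0.0
            if probs.max() <= 0.0:
                t_stop = t - 1
                break
            new = rng.random((r, n)) < probs
            new &= ~infected
            if new.any():
                first_time[new] = t
                infected |= new
                logsurv += new.astype(np.float32) @ L
                count_inf = infected.sum(axis=1)
            inf_counts_t[t] = count_inf.sum()
            if count_inf.min() == n:
                t_stop = t
                break
        if t_stop < T:
            inf_counts_t[t_stop + 1 :] = inf_counts_t[t_stop]
        # aggregate chunk
        tt = first_time.ravel()
        ii = np.tile(np.arange(n), r)
        ok = tt >= 0
        np.add.at(p_counts, (ii[ok], tt[ok]), 1)
        censored += (first_time < 0).sum(axis=0)
        time_sum += np.where(first_time >= 0, first_time, T).sum(axis=0)
        inf_by_t += inf_counts_t
        if watch_pos is not None:
            ft_w = first_time[:, watch_pos]
            watch_hits += int(
                (((ft_w >= 0) & (ft_w <= cfg.t0)).any(axis=1)).sum()
            )

    p = p_counts.astype(float) / cfg.n_runs
    curve = inf_by_t / (cfg.n_runs * n)
    mean_times = time_sum / cfg.n_runs
    return PropagationResult(
        p=p,
        infected_curve=curve,
        mean_times=mean_times,
        censored_frac=censored / cfg.n_runs,
        seed_ids=tuple(seed),
        n_runs=cfg.n_runs,
        T=T,
        beta=beta,
        watch_hit_fraction=(watch_hits / cfg.n_runs) if watch_pos is not None else None,
    )


def mean_infection_times(res: PropagationResult) -> np.ndarray:
    """Expected first-infection step per ROI from the probability map.

    Equals ``sum_t t * p_i(t) + T * (1 - sum_t p_i(t))``, i.e. the mean with
    never-infected runs censored at the horizon T; identically the sum over
    t < T of the survival probability P(i not yet infected by t).  Seed nodes
    get 0.  (The naive sum of p_i(t) alone is a probability, not a time; it
    is available as ``res.printed_time_sum``.)
    """
    t = np.arange(res.p.shape[1])
    tot = res.p.sum(axis=1)
    return res.p @ t + res.T * (1.0 - tot)


@numba.njit(cache=False)
def _slow_kernel(indptr, indices, weights, seed_pos, reachable, n, n_runs, seed_int):  # pragma: no cover - numba
    np.random.seed(seed_int)
    order_sum = np.zeros(n, dtype=np.float64)
    n_seed = seed_pos.size
    n_target = 0
    for i in range(n):
        if reachable[i]:
            n_target += 1
    n_target -= n_seed
    for _ in range(n_runs):
        infected = np.zeros(n, dtype=np.bool_)
        pressure = np.zeros(n, dtype=np.float64)
        for s in seed_pos:
            infected[s] = True
        for s in seed_pos:
            for k in range(indptr[s], indptr[s + 1]):
                j = indices[k]
                if not infected[j]:
                    pressure[j] += weights[k]
        for step in range(1, n_target + 1):
            total = 0.0
            for j in range(n):
                if not infected[j]:
                    total += pressure[j]
            r = np.random.random() * total
            acc = 0.0
            pick = -1
            for j in range(n):
                if not infected[j] and pressure[j] > 0.0:
                    acc += pressure[j]
                    if acc >= r:
                        pick = j
                        break
            if pick < 0:  # numerical guard: take last positive-pressure node
                for j in range(n - 1, -1, -1):
                    if not infected[j] and pressure[j] > 0.0:
                        pick = j
                        break
            infected[pick] = True
            pressure[pick] = 0.0
            order_sum[pick] += step
            for k in range(indptr[pick], indptr[pick + 1]):
                j = indices[k]
                if not infected[j]:
                    pressure[j] += weights[k]
    return order_sum


def slow_propagation_pattern(
    net: BrainNetwork, seed, n_runs: int = 10_000, rng_seed: int = 0
) -> np.ndarray:
    """Mean activation step per ROI in the beta -> 0 limit.

    Per run exactly one susceptible node is infected per step, chosen with
    probability proportional to its total link weight to the infected set.
    Returns the mean activation step (0 for seed nodes, ``inf`` for nodes
    unreachable from the seed on the nonzero-weight graph).
    """
    seed = sorted(int(s) for s in seed)
    if not seed:
        raise ValueError("seed must be nonempty")
    n = net.n
    seed_pos = net.rois.positions(seed)
    # reachability is deterministic on the thresholded graph
    adj = net.weights > 0
    reach = np.zeros(n, dtype=bool)
    reach[seed_pos] = True
    frontier = reach.copy()
    while True:
        frontier = adj[frontier].any(axis=0) & ~reach
        if not frontier.any():
            break
        reach |= frontier

    from scipy.sparse import csr_matrix

    w = csr_matrix(net.weights)
    kernel_seed = int(np.random.default_rng(rng_seed).integers(2**31 - 1))
    order_sum = _slow_kernel(
        w.indptr,
        w.indices,
        w.data.astype(np.float64),
        seed_pos.astype(np.int64),
        reach,
        n,
        int(n_runs),
        kernel_seed,
    )
    mean_order = order_sum / n_runs
    mean_order[~reach] = np.inf
    mean_order[seed_pos] = 0.0
    return mean_order


def propagation_extent(
    net: BrainNetwork,
    seed,
    resected,
    cfg: SIConfig,
    baseline_extent: float | None = None,
) -> dict:
    """Post-resection propagation extent at t0 and its normalized value.

    Runs the SI dynamics on the virtually resected network from the
    surviving seed nodes, with beta tied to the network density
    (``beta = beta_theta_product / theta`` unless cfg.beta is set).  The
    extent counts infected nodes *outside the original seed* divided by
    (N - |seed|), so complete disconnection of the seed yields exactly 0.
    ``i_R`` normalizes by the pre-resection extent on the intact network
    (computed here unless ``baseline_extent`` is supplied).

    Returns a dict with extent, i_r, baseline_extent, zero_spread (True when
    no run infected any non-seed node by t0) and the resolved beta.
    """
    seed = sorted(int(s) for s in seed)
    resected = set(int(r) for r in resected)
    if not seed:
        raise ValueError("seed must be nonempty")
    n = net.n
    non_seed_ids = [int(r) for r in net.rois.roi_ids if int(r) not in set(seed)]
    cfg_eval = replace(cfg, T=cfg.t0)

    if baseline_extent is None:
        base = simulate_si(net, seed, cfg_eval)
        baseline_extent = _extent_at_t0(base, net, seed, cfg.t0)

    effective_seed = [s for s in seed if s not in resected]
    if not effective_seed:
        return {
            "extent": 0.0,
            "i_r": 0.0,
            "baseline_extent": baseline_extent,
            "zero_spread": True,
            "beta": cfg.resolve_beta(net.theta),
        }
    rnet = apply_resection(net, resected)
    res = simulate_si(rnet, effective_seed, cfg_eval, watch_ids=non_seed_ids)
    extent = _extent_at_t0(res, net, seed, cfg.t0)
    i_r = extent / baseline_extent if baseline_extent > 0 else 0.0
    return {
        "extent": extent,
        "i_r": i_r,
        "baseline_extent": baseline_extent,
        "zero_spread": res.watch_hit_fraction == 0.0,
        "beta": res.beta,
    }


def _extent_at_t0(res: PropagationResult, net: BrainNetwork, seed, t0: int) -> float:
    """Expected fraction of non-seed nodes infected by t0."""
    pos = net.rois.positions(seed)
    mask = np.ones(net.n, dtype=bool)
    mask[pos] = False
    t_hi = min(t0, res.p.shape[1] - 1)
    prob_by_t0 = res.p[:, : t_hi + 1].sum(axis=1)
    return float(prob_by_t0[mask].sum() / mask.sum())
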