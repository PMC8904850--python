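"""Seizure propagation patterns and density fitting.

The clinical pattern comes from SEEG: electrode contact points (CPs) are
assigned to the nearest atlas ROI centroid, grouped into activation steps
(step 1 = seizure onset zone), and turned into midpoint-tie activation ranks
over the sampled ROI set.  The model pattern ranks the same ROIs by their
mean SI activation time.  The two rankings are compared with the rank
correlation

    C = cov(RANK_seeg, RANK_si) / (sigma(RANK_seeg) * sigma(RANK_si)),

i.e. Pearson on midpoint-tie ranks (tie-corrected Spearman); significance is
assessed with a two-sided permutation test.  The network density theta is
fitted per patient by scanning a grid, simulating the slow-propagation
ordering at each density, and selecting the lowest-density local maximum of
C(theta) that is significant (the correlation curve is typically bimodal and
only the low-density maximum isolates the fundamental pathways).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .network import BrainNetwork, RoiTable, DEFAULT_THETA_GRID, threshold_network
from .si_dynamics import slow_propagation_pattern

__all__ = [
    "ClinicalPattern",
    "ModelPattern",
    "FitResult",
    "FitConfig",
    "load_clinical_pattern",
    "nearest_roi_assignment",
    "midpoint_ranks",
    "model_pattern",
    "pattern_correlation",
    "fit_threshold",
    "median_correlation_curve",
    "fully_connected_baseline",
]


def midpoint_ranks(values) -> np.ndarray:
    """Midpoint-tie ranking: tied groups get the midpoint of unadjusted ranks."""
    return rankdata(np.asarray(values, dtype=float), method="average")


@dataclass(frozen=True)
class ClinicalPattern:
    """SEEG activation pattern over the sampled ROI subset.

    ``roi_ids`` are the sampled ROIs that took part in the propagation
    pattern (CPs that never activated are simply absent), ``steps`` their
    positive activation steps (1 = SOZ), ``ranks`` the midpoint-tie ranks.
    """

    roi_ids: np.ndarray
    steps: np.ndarray
    ranks: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.roi_ids, dtype=int)
        steps = np.asarray(self.steps, dtype=int)
        if ids.size != steps.size or ids.size != len(self.ranks):
            raise ValueError("roi_ids/steps/ranks length mismatch")
        if len(set(ids.tolist())) != ids.size:
            raise ValueError("duplicate ROI in pattern")
        if (steps <= 0).any():
            raise ValueError("activation steps must be positive")
        object.__setattr__(self, "roi_ids", ids)
        object.__setattr__(self, "steps", steps)
        object.__setattr__(self, "ranks", np.asarray(self.ranks, dtype=float))

    @classmethod
    def from_steps(cls, roi_ids, steps) -> "ClinicalPattern":
        return cls(roi_ids=np.asarray(roi_ids, dtype=int),
                   steps=np.asarray(steps, dtype=int),
                   ranks=midpoint_ranks(steps))

    @property
    def n_sampled(self) -> int:
        return int(self.roi_ids.size)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "cp_id": np.arange(1, self.n_sampled + 1),
                "electrode_id": ["E1"] * self.n_sampled,
                "roi_id": self.roi_ids,
                "activation_step": self.steps,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ModelPattern:
    """Midpoint-tie ranking of mean SI activation times over the sampled ROIs."""

    roi_ids: np.ndarray
    ranks: np.ndarray
    degenerate: bool = False  # all times tied: correlation undefined


def nearest_roi_assignment(cp_coords, rois: RoiTable) -> np.ndarray:
    """Assign each contact point to the ROI with the nearest centroid.

    Ties are broken by the smaller roi_id.  Returns ROI ids per CP.
    """
    if len(rois) == 0:
        raise ValueError("empty ROI table")
    coords = np.atleast_2d(np.asarray(cp_coords, dtype=float))
    if not np.all(np.isfinite(coords)):
        raise ValueError("contact-point coordinates must be finite")
    # sort ROIs by id so argmin's first-hit tie-break is the smaller id
    order = np.argsort(rois.roi_ids, kind="stable")
    cents = rois.centroids[order]
    d2 = ((coords[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    return rois.roi_ids[order][np.argmin(d2, axis=1)]


def load_clinical_pattern(path, rois: RoiTable) -> ClinicalPattern:
    """Read a CP-level pattern TSV and build the ROI-level clinical pattern.

    Expected columns: cp_id, electrode_id, activation_step, and either
    roi_id or x_mm/y_mm/z_mm (then CPs are assigned to the nearest centroid).
    CPs mapping to the same ROI are merged; the merged ROI activates at the
    earliest step among its CPs (seizure-onset semantics).
    """
    df = pd.read_csv(path, sep="\t")
    if "activation_step" not in df.columns:
        raise ValueError("pattern file missing activation_step column")
    if df["activation_step"].isna().any() or (df["activation_step"] <= 0).any():
        raise ValueError("activation steps must be positive")
    if "roi_id" in df.columns:
        if df["roi_id"].isna().any():
            raise ValueError("contact point with no ROI assignment")
        roi_ids = df["roi_id"].to_numpy(dtype=int)
    elif {"x_mm", "y_mm", "z_mm"} <= set(df.columns):
        roi_ids = nearest_roi_assignment(
            df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float), rois
        )
    else:
        raise ValueError("pattern file needs roi_id or x_mm/y_mm/z_mm columns")
    rois.positions(roi_ids)  # validates ids
    merged = (
        pd.DataFrame({"roi_id": roi_ids, "step": df["activation_step"].to_numpy(int)})
        .groupby("roi_id", as_index=False)["step"]
        .min()
        .sort_values("roi_id")
    )
    return ClinicalPattern.from_steps(merged["roi_id"].to_numpy(),
                                      merged["step"].to_numpy())


def model_pattern(times, sampled_ids, rois: RoiTable) -> ModelPattern:
    """Rank per-ROI mean activation times over the sampled ROI subset.

    ``times`` is the full per-ROI array (position-indexed); ``sampled_ids``
    the sampled subset.  Unreachable ROIs (time inf) rank last, tied.
    """
    ids = np.asarray(sampled_ids, dtype=int)
    t = np.asarray(times, dtype=float)[rois.positions(ids)]
    if np.isnan(t).any():
        raise ValueError("missing mean time for a sampled ROI")
    ranks = midpoint_ranks(t)
    return ModelPattern(roi_ids=ids, ranks=ranks,
                        degenerate=bool(np.ptp(ranks) == 0))


def pattern_correlation(
    a_ranks,
    b_ranks,
    n_perm: int = 10_000,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """Rank correlation C between two rankings and its permutation p-value.

    C is the Pearson correlation of the two midpoint-tie rank vectors
    (population and sample moments give the same ratio).  The p-value is a
    two-sided permutation test: one rank vector is permuted ``n_perm`` times
    and the fraction of |C_perm| >= |C_obs| reported (add-one corrected).
    """
    a = np.asarray(a_ranks, dtype=float)
    b = np.asarray(b_ranks, dtype=float)
    if a.size != b.size:
        raise ValueError("rankings differ in length")
    if a.size < 3:
        raise ValueError("need at least 3 entries")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant ranking: correlation undefined")
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac**2).sum() * (bc**2).sum())
    c = float((ac * bc).sum() / denom)
    rng = np.random.default_rng(rng_seed)
    perms = rng.permuted(np.tile(bc, (n_perm, 1)), axis=1)
    c_perm = perms @ ac / denom
    p = (1 + int((np.abs(c_perm) >= abs(c) - 1e-12).sum())) / (n_perm + 1)
    return c, float(p)


@dataclass(frozen=True)
class FitConfig:
    """Settings for the density fit: slow-propagation runs per density,
    permutations for the p-value, master RNG seed, significance level."""

    n_runs: int = 10_000
    n_perm: int = 10_000
    rng_seed: int = 0
    alpha: float = 0.05
    #: a local maximum only qualifies as "the first maximum" if it comes
    #: within this relative margin of the global maximum — Monte-Carlo
    #: wiggles on the rising shoulder of C(theta) are not maxima.
    prominence: float = 0.05


@dataclass
class FitResult:
    """C(theta) curve with significance and the selected first maximum."""

    thetas: np.ndarray
    correlations: np.ndarray
    pvalues: np.ndarray
    theta_max: float
    kappa_max: float
    c_max: float
    p_max: float
    significant: bool
    seed_kind: str = "RA"

    def to_frame(self) -> pd.DataFrame:
        n = self.kappa_max / self.theta_max
        return pd.DataFrame(
            {
                "theta": self.thetas,
                "kappa": self.thetas * n,
                "C": self.correlations,
                "p": self.pvalues,
            }
        )

    def summary(self) -> dict:
        return {
            "theta_max": float(self.theta_max),
            "kappa_max": float(self.kappa_max),
            "C_max": float(self.c_max),
            "p_max": float(self.p_max),
            "significant": bool(self.significant),
            "seed_kind": self.seed_kind,
        }


def _select_first_maximum(thetas, cs, ps, alpha, prominence):
    """Lowest-theta local maximum of C that is significant and within the
    prominence margin of the global maximum; fall back to the global maximum
    (flagged non-significant) when no local maximum qualifies."""
    n = len(thetas)
    c_max = cs.max()
    c_thr = c_max - prominence * abs(c_max)
    for i in range(n):
        left_ok = i == 0 or cs[i] >= cs[i - 1]
        right_ok = i == n - 1 or cs[i] >= cs[i + 1]
        if left_ok and right_ok and ps[i] < alpha and cs[i] >= c_thr:
            return i, True
    return int(np.argmax(cs)), False


def fit_threshold(
    net_unthresholded: BrainNetwork,
    clinical: ClinicalPattern,
    seed,
    grid=DEFAULT_THETA_GRID,
    cfg: FitConfig = FitConfig(),
    seed_kind: str = "RA",
) -> FitResult:
    """Fit the network density to the clinical propagation pattern.

    For each density in the grid: threshold the network, simulate the
    slow-propagation (beta -> 0) activation ordering from the seed, rank the
    sampled ROIs by mean activation step, and correlate with the clinical
    ranks.  Deterministic given cfg.rng_seed.
    """
    thetas = np.asarray(sorted(grid), dtype=float)
    if (np.diff(thetas) <= 0).any() or thetas[0] <= 0 or thetas[-1] > 1:
        raise ValueError("grid must be strictly increasing in (0, 1]")
    net_unthresholded.rois.positions(list(seed))  # validates seed ids
    master = np.random.SeedSequence(cfg.rng_seed)
    children = master.spawn(2 * thetas.size)
    cs, ps = [], []
    for i, theta in enumerate(thetas):
        tnet = threshold_network(net_unthresholded, float(theta))
        times = slow_propagation_pattern(
            tnet, seed, n_runs=cfg.n_runs,
            rng_seed=int(children[2 * i].generate_state(1)[0] % (2**31 - 1)),
        )
        mp = model_pattern(times, clinical.roi_ids, net_unthresholded.rois)
        try:
            c, p = pattern_correlation(
                clinical.ranks, mp.ranks, n_perm=cfg.n_perm,
                rng_seed=int(children[2 * i + 1].generate_state(1)[0] % (2**31 - 1)),
            )
        except ValueError:  # fully tied model ranking
            c, p = 0.0, 1.0
        cs.append(c)
        ps.append(p)
    cs, ps = np.asarray(cs), np.asarray(ps)
    idx, sig = _select_first_maximum(thetas, cs, ps, cfg.alpha, cfg.prominence)
    return FitResult(
        thetas=thetas,
        correlations=cs,
        pvalues=ps,
        theta_max=float(thetas[idx]),
        kappa_max=float(thetas[idx] * net_unthresholded.n),
        c_max=float(cs[idx]),
        p_max=float(ps[idx]),
        significant=sig,
        seed_kind=seed_kind,
    )


def median_correlation_curve(fits: list[FitResult]) -> pd.DataFrame:
    """Pointwise median of C(theta) across patients, with its argmax flagged.

    All fits must share the same density grid.  A single-patient list
    returns that patient's own curve.
    """
    if not fits:
        raise ValueError("empty fit list")
    grid = fits[0].thetas
    for f in fits[1:]:
        if not np.array_equal(f.thetas, grid):
            raise ValueError("fits do not share the density grid")
    med = np.median(np.vstack([f.correlations for f in fits]), axis=0)
    df = pd.DataFrame({"theta": grid, "median_C": med})
    df["best"] = df["median_C"] == df["median_C"].max()
    return df


def fully_connected_baseline(
    clinical: ClinicalPattern,
    seed,
    rois: RoiTable,
    cfg: FitConfig = FitConfig(),
) -> dict:
    """Correlation of the clinical pattern with a trivial fully connected net.

    On a uniform complete graph all non-seed nodes are exchangeable, so the
    expected activation times are exactly: 0 on the seed, one common value
    elsewhere.  The model ranking is computed analytically from that symmetry.
    If it is constant over the sampled set (no seed ROI sampled) the
    correlation is undefined and reported as 0 with ``degenerate=True``.
    """
    seed_set = set(int(s) for s in seed)
    times = np.array([0.0 if int(r) in seed_set else 1.0 for r in clinical.roi_ids])
    ranks = midpoint_ranks(times)
    if np.ptp(ranks) == 0:
        return {"C": 0.0, "p": 1.0, "degenerate": True}
    c, p = pattern_correlation(clinical.ranks, ranks, n_perm=cfg.n_perm,
                               rng_seed=cfg.rng_seed)
    return {"C": c, "p": p, "degenerate": False}
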