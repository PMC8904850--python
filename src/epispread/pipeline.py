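"""Cohort orchestration: patient records, fit/resection runs, group statistics.

Also carries the published cohort's implantation summary (electrode and
contact-point counts, seed and sampling sizes, surgical outcome) used to
parameterize realistic synthetic cohorts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .network import BrainNetwork, RoiTable, DEFAULT_THETA_GRID, load_network
from .patterns import (ClinicalPattern, FitConfig, FitResult, fit_threshold,
                       fully_connected_baseline, load_clinical_pattern,
                       median_correlation_curve)
from .resection import ResectionCurve, SAConfig, resection_curve
from .si_dynamics import SIConfig

log = logging.getLogger("epispread")

__all__ = [
    "COHORT_TABLE",
    "PatientRecord",
    "RunConfig",
    "run_fit",
    "run_resect",
    "paired_t",
    "unpaired_t",
    "pearson_fit",
]

#: Published per-patient implantation summary: number of resected ROIs
#: (S_RA), Engel-based outcome (SF = seizure-free), number of intracranial
#: electrodes (#E), total electrode contact points (#ECP), and number of
#: atlas ROIs sampled by the electrodes (N_SR).
COHORT_TABLE = pd.DataFrame(
    {
        "patient": [f"P{i}" for i in range(1, 11)],
        "s_ra": [5, 5, 4, 5, 6, 4, 3, 6, 12, 6],
        "outcome": ["NSF", "SF", "NSF", "SF", "SF", "SF", "SF", "NSF", "SF", "SF"],
        "n_electrodes": [9, 12, 13, 11, 12, 10, 12, 15, 10, 14],
        "n_contact_points": [99, 106, 117, 110, 124, 104, 102, 194, 107, 193],
        "n_sampled_rois": [40, 30, 47, 44, 40, 37, 38, 60, 32, 49],
    }
)


@dataclass
class PatientRecord:
    """File-backed patient: network matrix, ROI table, pattern, seed lists."""

    id: str
    network_path: str
    roi_path: str
    pattern_path: str
    ra_seed_path: str
    soz_seed_path: str | None = None
    outcome: str | None = None   # SF / NSF, metadata only
    engel: str | None = None     # metadata only

    def load(self) -> tuple[BrainNetwork, ClinicalPattern, list[int], list[int] | None]:
        rois = RoiTable.from_tsv(self.roi_path)
        net = load_network(self.network_path, rois)
        pattern = load_clinical_pattern(self.pattern_path, rois)
        ra = _read_seed(self.ra_seed_path)
        soz = _read_seed(self.soz_seed_path) if self.soz_seed_path else None
        return net, pattern, ra, soz


def _read_seed(path) -> list[int]:
    text = Path(path).read_text()
    sep = "," if "," in text else None
    return [int(tok) for tok in text.replace(",", "\n").split() if tok.strip()]


@dataclass
class RunConfig:
    """Full run settings; hashed into every output for provenance."""

    grid: tuple[float, ...] = DEFAULT_THETA_GRID
    fit: FitConfig = field(default_factory=FitConfig)
    si: SIConfig = field(default_factory=SIConfig)
    sa: SAConfig = field(default_factory=SAConfig)
    seed_kind: str = "RA"
    rng_seed: int = 0

    def digest(self) -> str:
        blob = json.dumps(
            {
                "grid": list(self.grid),
                "fit": asdict(self.fit),
                "si": asdict(self.si),
                "sa": asdict(self.sa),
                "seed_kind": self.seed_kind,
                "rng_seed": self.rng_seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_fit(
    patients: list[PatientRecord],
    config: RunConfig,
    average_network: bool = False,
    baseline: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, FitResult]]:
    """Per-patient density fits plus the cohort median correlation curve.

    ``average_network=True`` replaces every patient's matrix by the cohort
    mean matrix (common substrate, individual seeds and patterns);
    ``baseline=True`` adds the fully-connected-network correlation.
    Per-patient failures are isolated and logged; the run continues.
    """
    loaded = []
    for rec in patients:
        try:
            loaded.append((rec, *rec.load()))
        except Exception as exc:  # noqa: BLE001 - isolate per-patient failures
            log.error("patient %s: load failed: %s", rec.id, exc)
    if average_network and loaded:
        mean_w = np.mean([net.weights for _, net, _, _, _ in loaded], axis=0)
    rows, fits = [], {}
    for rec, net, pattern, ra, soz in loaded:
        seed = soz if (config.seed_kind == "SOZ" and soz) else ra
        if average_network:
            net = BrainNetwork(weights=mean_w, rois=net.rois, theta=1.0)
        try:
            fr = fit_threshold(net, pattern, seed, grid=config.grid,
                               cfg=config.fit, seed_kind=config.seed_kind)
        except Exception as exc:  # noqa: BLE001
            log.error("patient %s: fit failed: %s", rec.id, exc)
            continue
        fits[rec.id] = fr
        row = {"patient": rec.id, "outcome": rec.outcome, **fr.summary()}
        if baseline:
            fcn = fully_connected_baseline(pattern, seed, net.rois, cfg=config.fit)
            row.update({"C_fcn": fcn["C"], "p_fcn": fcn["p"],
                        "fcn_degenerate": fcn["degenerate"]})
        if not fr.significant:
            log.warning("patient %s: no significant density (global max reported)",
                        rec.id)
        rows.append(row)
        log.info("patient %s: theta_max=%.3g C_max=%.3f", rec.id,
                 fr.theta_max, fr.c_max)
    table = pd.DataFrame(rows)
    median = median_correlation_curve(list(fits.values())) if fits else pd.DataFrame()
    for df in (table, median):
        if not df.empty:
            df.attrs["config_digest"] = config.digest()
            df.attrs["rng_seed"] = config.rng_seed
    return table, median, fits


def run_resect(
    patients: list[PatientRecord],
    config: RunConfig,
    thetas: dict[str, float],
) -> dict[str, ResectionCurve]:
    """Resection curves per patient at the fitted densities ``thetas``."""
    from .network import threshold_network

    curves = {}
    for rec in patients:
        try:
            net, _, ra, soz = rec.load()
            seed = soz if (config.seed_kind == "SOZ" and soz) else ra
            tnet = threshold_network(net, thetas[rec.id])
            curve = resection_curve(tnet, seed, config.si, config.sa,
                                    rng_seed=config.rng_seed)
        except Exception as exc:  # noqa: BLE001
            log.error("patient %s: resection failed: %s", rec.id, exc)
            continue
        curves[rec.id] = curve
        outside = [o for o in curve.outcomes
                   if set(o.resected) - set(seed)]
        if outside:
            log.warning("patient %s: %d optimal resections include ROIs outside "
                        "the seed", rec.id, len(outside))
    return curves


# -- thin statistics helpers (two-sided, alpha = 0.05 convention) -----------

def paired_t(x, y) -> dict:
    """Paired Student's t-test; identical vectors give t=0, p=1."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two paired vectors of length >= 2")
    d = x - y
    if np.allclose(d, d[0]) and np.allclose(d[0], 0.0):
        return {"t": 0.0, "p": 1.0, "df": x.size - 1}
    t, p = sstats.ttest_rel(x, y)
    return {"t": float(t), "p": float(p), "df": x.size - 1}


def unpaired_t(x, y) -> dict:
    """Unpaired Student's t-test (equal-variance, as in classic group tests)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per group")
    t, p = sstats.ttest_ind(x, y)
    return {"t": float(t), "p": float(p), "df": x.size + y.size - 2}


def pearson_fit(x, y) -> dict:
    """Pearson r with the least-squares line (slope, intercept)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance")
    res = sstats.linregress(x, y)
    return {
        "r": float(res.rvalue),
        "p": float(res.pvalue),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
    }
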