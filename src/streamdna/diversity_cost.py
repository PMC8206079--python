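"""Diversity summaries, bootstrap accumulation curves, cost-efficiency.

Total richness gamma is the number of taxa detected at least once; mean
per-unit richness alpha-bar is the average column sum of the detection
matrix; between-unit turnover is the additive beta-diversity fraction

    turnover = (gamma - alpha_bar) / gamma,

the share of landscape-level richness not captured by an average single
sampling unit. Accumulation curves resample sampling units with replacement
(a true bootstrap, 1000 iterations by default) across the full effort
gradient 1..M and report percentile 95% intervals; cost curves re-index the
same means by cumulative survey dollars (units x per-unit cost).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from streamdna.io_schemas import CostModel, DetectionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiversitySummary:
    gamma: int
    alpha_bar: float
    turnover: float


@dataclass(frozen=True)
class AccumulationCurve:
    """Bootstrap mean richness and percentile CI per effort level m=1..M."""

    m: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_iter: int
    seed: int

    def to_frame(self, method: str = "", year: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"m": self.m, "mean": self.mean,
                           "lo": self.lo, "hi": self.hi})
        if method:
            df.insert(0, "method", method)
        if year is not None:
            df.insert(1, "year", year)
        return df


@dataclass(frozen=True)
class CostCurve:
    """Cumulative cost (USD) against bootstrap mean richness."""

    cost: np.ndarray
    mean_richness: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cost_usd": self.cost,
                             "mean_richness": self.mean_richness})


def site_richness(m: DetectionMatrix) -> tuple[np.ndarray, float]:
    """Per-unit richness (taxa detected per sampling unit) and its mean."""
    if m.n_taxa == 0 or m.n_units == 0:
        raise ValueError("detection matrix must be non-empty")
    per_unit = m.y.sum(axis=0).astype(float)
    return per_unit, float(per_unit.mean())


def turnover_from_summary(gamma: float, alpha_bar: float, ndigits: int = 2) -> float:
    """Turnover (gamma - alpha_bar) / gamma from printed summary values."""
    if gamma <= 0:
        raise ValueError("turnover undefined for gamma <= 0")
    if alpha_bar > gamma:
        raise ValueError("alpha_bar cannot exceed gamma")
    return round((gamma - alpha_bar) / gamma, ndigits)


def turnover(m: DetectionMatrix) -> DiversitySummary:
    """Between-unit diversity turnover of a detection matrix.

    Reported to 2 decimals, matching field convention; gamma counts taxa
    detected in at least one unit.
    """
    gamma = int((m.y.sum(axis=1) > 0).sum())
    if gamma == 0:
        raise ValueError("turnover undefined: no taxon detected")
    _, alpha_bar = site_richness(m)
    return DiversitySummary(
        gamma=gamma,
        alpha_bar=round(alpha_bar, 1),
        turnover=turnover_from_summary(gamma, alpha_bar),
    )


def bootstrap_accumulation(
    m: DetectionMatrix,
    n_iter: int = 1000,
    seed: int = 0,
) -> AccumulationCurve:
    """Bootstrap species-accumulation curve over the effort gradient 1..M.

    Each iteration draws one length-M sequence of units uniformly with
    replacement and accumulates the union richness over its prefixes, so the
    first m draws are m uniform with-replacement draws and the curve is
    non-decreasing within every iteration (hence in the mean).
    Deterministic given seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    M = m.n_units
    y = m.y.astype(bool)
    idx = rng.integers(0, M, size=(n_iter, M))
    rich = np.empty((n_iter, M), dtype=np.int64)
    seen = np.zeros((m.n_taxa, n_iter), dtype=bool)
    for mm in range(M):
        seen |= y[:, idx[:, mm]]
        rich[:, mm] = seen.sum(axis=0)
    means = rich.mean(axis=0)
    lo, hi = np.percentile(rich, [2.5, 97.5], axis=0)
    return AccumulationCurve(m=np.arange(1, M + 1), mean=means, lo=lo, hi=hi,
                             n_iter=n_iter, seed=seed)


def cost_curve(ac: AccumulationCurve, cost: CostModel) -> CostCurve:
    """Re-index an accumulation curve by cumulative survey cost.

    A (0, 0) origin is prepended so curves start at zero dollars.
    """
    if cost.per_unit <= 0:
        raise ValueError("per-unit cost must be > 0")
    dollars = np.concatenate([[0.0], ac.m * float(cost.per_unit)])
    richness = np.concatenate([[0.0], ac.mean])
    return CostCurve(cost=dollars, mean_richness=richness)


def cost_to_reach(ac: AccumulationCurve, cost: CostModel, target: float) -> int:
    """Dollars needed for the mean accumulation curve to reach ``target`` taxa.

    Uses the smallest effort m whose bootstrap mean richness is >= target.
    """
    reached = np.flatnonzero(ac.mean >= target)
    if reached.size == 0:
        raise ValueError(f"curve never reaches {target} taxa")
    m_needed = int(ac.m[reached[0]])
    return m_needed * cost.per_unit


def restrict_to_camera_detectable(m: DetectionMatrix) -> DetectionMatrix:
    """Drop taxa a camera grid cannot detect/identify (bats, most small
    rodents, semi-aquatic species); sampling units are unchanged."""
    keep = [t.name for t in m.taxa if t.camera_detectable]
    if not keep:
        logger.warning("no camera-detectable taxa remain")
    dropped = m.n_taxa - len(keep)
    if dropped:
        logger.info("restricted matrix: dropped %d non-camera taxa", dropped)
    return m.subset_taxa(keep)
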