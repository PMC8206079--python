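"""Between-year and between-method agreement of detection probabilities.

Pairs per-taxon standardized detection estimates from two surveys (inner
join on taxon name, optionally restricted to camera-detectable taxa) and
summarizes their ordinary-least-squares relationship on the probability
scale: slope, intercept, and the coefficient of determination R^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from streamdna.detection_model import DetectionEstimate


@dataclass(frozen=True)
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"R^2 out of range: {self.r_squared}")


def paired_estimates(
    a: Sequence[DetectionEstimate],
    b: Sequence[DetectionEstimate],
    camera_detectable_only: bool = False,
) -> pd.DataFrame:
    """Inner-join two estimate lists on taxon name.

    Returns columns (taxon, x, y) with x from ``a`` and y from ``b``.
    """
    if not a or not b:
        raise ValueError("both estimate lists must be non-empty")

    def _frame(ests: Sequence[DetectionEstimate]) -> pd.DataFrame:
        rows = [
            {"taxon": e.taxon.name, "p": e.p60_mean,
             "camera_detectable": e.taxon.camera_detectable}
            for e in ests
        ]
        return pd.DataFrame(rows)

    fa, fb = _frame(a), _frame(b)
    merged = fa.merge(fb, on="taxon", suffixes=("_x", "_y"))
    if camera_detectable_only:
        merged = merged[merged["camera_detectable_x"]
                        & merged["camera_detectable_y"]]
    if merged.empty:
        raise ValueError("no taxa shared between the two estimate lists")
    return pd.DataFrame(
        {"taxon": merged["taxon"], "x": merged["p_x"], "y": merged["p_y"]}
    )


def linear_fit(x, y) -> RegressionSummary:
    """Ordinary least squares of y on x with R^2 = 1 - SS_res / SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return RegressionSummary(slope=float(slope), intercept=float(intercept),
                             r_squared=min(max(r2, 0.0), 1.0), n=n)


def compare_surveys(
    pairs: dict[str, tuple[Sequence[DetectionEstimate],
                           Sequence[DetectionEstimate], bool]],
) -> pd.DataFrame:
    """Run all named pairwise regressions; rows (pair, n, slope, intercept,
    r_squared). The boolean selects camera-detectable taxa only."""
    rows = []
    for name, (a, b, cam_only) in pairs.items():
        tab = paired_estimates(a, b, camera_detectable_only=cam_only)
        fit = linear_fit(tab["x"], tab["y"])
        rows.append({"pair": name, "n": fit.n, "slope": fit.slope,
                     "intercept": fit.intercept, "r_squared": fit.r_squared})
    return pd.DataFrame(rows)
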