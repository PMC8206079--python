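"""From-scratch GLM machinery with AICc all-subsets model selection.

Two response families are supported, matching the two analyses they power:

- Poisson with log link — number of taxa detected per water sample
  (site richness) against sampling covariates,
- Bernoulli/binomial with logit link — per (taxon x sample) detection
  (1/0) against local camera detection rate, sampling covariates, and
  taxonomic group or diet/body-mass effects.

Fitting is iteratively reweighted least squares (IRLS) run to
``max |dbeta| < 1e-8`` (100 iterations cap), with the coefficient
covariance taken as the inverse Fisher information at convergence and
exact log-likelihoods (the Poisson includes the ``-log y!`` term).
Model selection uses AICc,

    AICc = -2 logL + 2k + 2k(k + 1) / (n - k - 1),

over every additive subset of the candidate covariates (factors enter and
leave as blocks); subsets within 2 AICc of the best are treated as
statistically equivalent.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr as _qr
from scipy.special import expit, gammaln

from streamdna.io_schemas import CameraDeployment

logger = logging.getLogger(__name__)

MAX_CANDIDATES = 12  # all-subsets cap: 2^12 fits


class RankDeficientError(ValueError):
    """Design matrix has linearly dependent columns."""


@dataclass(frozen=True)
class Covariate:
    """One candidate covariate of a design.

    Numeric covariates may be log-transformed (body mass spans voles to
    moose); factors use treatment coding against ``reference`` (first level
    in sorted order when unspecified).
    """

    name: str
    kind: str = "numeric"  # 'numeric' or 'factor'
    transform: str = "identity"  # 'identity' or 'log'
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "factor"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.transform not in ("identity", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")

    @property
    def label(self) -> str:
        return f"log({self.name})" if self.transform == "log" else self.name


@dataclass(frozen=True)
class DesignSpec:
    """Response family plus the candidate covariate set."""

    response: str  # 'site_richness' (Poisson) or 'detection' (binomial)
    covariates: tuple[Covariate, ...] = ()

    def __post_init__(self) -> None:
        if self.response not in ("site_richness", "detection"):
            raise ValueError(f"unknown response {self.response!r}")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("duplicate candidate covariates")

    @property
    def family(self) -> str:
        return "poisson" if self.response == "site_richness" else "binomial"


def build_design(
    data: pd.DataFrame,
    covariates: Sequence[Covariate],
    factor_levels: dict[str, tuple] | None = None,
) -> tuple[np.ndarray, list[str], dict[str, tuple]]:
    """Expand covariates into a design matrix with intercept.

    Returns ``(X, column_names, factor_levels)``. When ``factor_levels`` is
    given (prediction on new data), levels are taken from it and unseen
    levels raise; otherwise levels are the sorted observed values with the
    covariate's reference first.
    """
    cols: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = ["Intercept"]
    levels_out: dict[str, tuple] = {}
    for cov in covariates:
        if cov.name not in data.columns:
            raise KeyError(f"covariate {cov.name!r} missing from data")
        if cov.kind == "numeric":
            x = data[cov.name].to_numpy(dtype=float)
            if cov.transform == "log":
                if np.any(x <= 0):
                    raise ValueError(f"log transform of non-positive {cov.name!r}")
                x = np.log(x)
            cols.append(x)
            names.append(cov.label)
        else:
            vals = data[cov.name].astype(str)
            if factor_levels and cov.name in factor_levels:
                levels = factor_levels[cov.name]
                unseen = set(vals) - set(levels)
                if unseen:
                    raise ValueError(
                        f"factor {cov.name!r}: unseen levels {sorted(unseen)}"
                    )
            else:
                observed = sorted(vals.unique())
                ref = cov.reference if cov.reference is not None else observed[0]
                if ref not in observed:
                    raise ValueError(
                        f"factor {cov.name!r}: reference level {ref!r} not observed"
                    )
                levels = tuple([ref] + [v for v in observed if v != ref])
            levels_out[cov.name] = tuple(levels)
            for lev in levels[1:]:
                cols.append((vals == lev).to_numpy(dtype=float))
                names.append(f"{cov.name}[{lev}]")
    return np.column_stack(cols), names, levels_out


@dataclass
class GlmFit:
    """A fitted GLM: coefficients, covariance, exact log-likelihood."""

    beta: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    k: int
    n: int
    converged: bool
    family: str
    column_names: list[str]
    covariates: tuple[Covariate, ...] = ()
    factor_levels: dict[str, tuple] = field(default_factory=dict)
    n_iter: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def wald_ci(self, z: float = 1.96) -> np.ndarray:
        """95% Wald intervals, rows (low, high) per coefficient."""
        se = self.se
        return np.column_stack([self.beta - z * se, self.beta + z * se])

    def coefficients_frame(self) -> pd.DataFrame:
        ci = self.wald_ci()
        return pd.DataFrame(
            {"term": self.column_names, "beta": self.beta, "se": self.se,
             "ci_low": ci[:, 0], "ci_high": ci[:, 1]}
        )


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r, piv = _qr(X, mode="economic", pivoting=True)
        bad = [names[piv[i]] for i in range(rank, X.shape[1])]
        raise RankDeficientError(f"collinear design columns: {bad}")


def fit_glm_matrix(
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    column_names: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlmFit:
    """IRLS fit on an explicit design matrix (intercept column included)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    names = list(column_names) if column_names is not None else [
        f"x{i}" for i in range(k)
    ]
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (got n={n}, k={k})")
    if family not in ("poisson", "binomial"):
        raise ValueError(f"unknown family {family!r}")
    if family == "poisson" and np.any(y < 0):
        raise ValueError("Poisson response must be non-negative")
    if family == "binomial" and not np.isin(y, (0, 1)).all():
        raise ValueError("binomial response must be 0/1")
    _check_rank(X, names)

    beta = np.zeros(k)
    if family == "poisson":
        # start at log of mean for the intercept (guards exp overflow)
        beta[0] = np.log(max(y.mean(), 1e-8))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        if family == "poisson":
            mu = np.exp(np.clip(eta, -30, 30))
            w = mu
            z = eta + (y - mu) / mu
        else:
            mu = expit(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            z = eta + (y - mu) / w
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 30 and family == "binomial":
        converged = False  # quasi-separation: estimates diverging
        logger.warning("binomial fit shows separation (|beta| > 30)")

    eta = X @ beta
    if family == "poisson":
        mu = np.exp(np.clip(eta, -30, 30))
        loglik = float(np.sum(y * eta - mu - gammaln(y + 1)))
        w = mu
    else:
        mu = expit(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll_terms = np.where(y == 1, np.log(mu), np.log1p(-mu))
        loglik = float(np.sum(ll_terms))
        w = np.clip(mu * (1 - mu), 1e-10, None)
    fisher = (X * w[:, None]).T @ X
    covariance = np.linalg.pinv(fisher)
    covariance = (covariance + covariance.T) / 2.0

    return GlmFit(
        beta=beta, covariance=covariance, log_likelihood=loglik, k=k, n=n,
        converged=converged, family=family, column_names=names, n_iter=it,
    )


def fit_glm(
    spec: DesignSpec,
    data: pd.DataFrame,
    y: np.ndarray,
    covariates: Sequence[Covariate] | None = None,
) -> GlmFit:
    """Build the design from raw covariate columns and fit by IRLS.

    ``covariates`` defaults to the spec's full candidate set; pass a subset
    during model selection.
    """
    covs = tuple(covariates if covariates is not None else spec.covariates)
    X, names, levels = build_design(data, covs)
    fit = fit_glm_matrix(X, np.asarray(y, dtype=float), spec.family, names)
    fit.covariates = covs
    fit.factor_levels = levels
    return fit


def aicc(fit: GlmFit) -> float:
    """Small-sample corrected Akaike information criterion."""
    n, k = fit.n, fit.k
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * fit.log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelSelectionTable:
    """Ranked all-subsets results. ``table`` is sorted ascending by AICc."""

    table: pd.DataFrame  # columns: subset, k, log_lik, aicc, daicc, converged
    fits: dict[tuple[str, ...], GlmFit]
    best_subset: tuple[str, ...]

    @property
    def best_fit(self) -> GlmFit:
        return self.fits[self.best_subset]

    @property
    def equivalence_set(self) -> list[tuple[str, ...]]:
        """Subsets within 2 AICc of the best (statistically equivalent)."""
        ok = self.table["daicc"] < 2.0
        return [tuple(s.split("+")) if s else () for s in self.table.loc[ok, "subset"]]


def all_subsets(
    spec: DesignSpec,
    data: pd.DataFrame,
    y: np.ndarray,
) -> ModelSelectionTable:
    """Fit every additive subset of the candidate covariates (plus the null).

    Factors enter/leave as blocks. Subsets whose fit does not converge, or
    for which AICc is undefined, are kept in the table with ``NaN`` AICc.
    """
    cands = spec.covariates
    if len(cands) > MAX_CANDIDATES:
        raise ValueError(f"more than {MAX_CANDIDATES} candidate covariates")
    rows = []
    fits: dict[tuple[str, ...], GlmFit] = {}
    for r in range(len(cands) + 1):
        for combo in itertools.combinations(cands, r):
            key = tuple(c.name for c in combo)
            label = "+".join(key)
            try:
                fit = fit_glm(spec, data, y, covariates=combo)
            except (RankDeficientError, ValueError) as exc:
                logger.warning("subset %s dropped: %s", label or "<null>", exc)
                rows.append({"subset": label, "k": np.nan, "log_lik": np.nan,
                             "aicc": np.nan, "converged": False})
                continue
            fits[key] = fit
            try:
                crit = aicc(fit) if fit.converged else np.nan
            except ValueError:
                crit = np.nan
            rows.append({"subset": label, "k": fit.k,
                         "log_lik": fit.log_likelihood, "aicc": crit,
                         "converged": fit.converged})
    table = pd.DataFrame(rows).sort_values(
        "aicc", na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    best_aicc = table["aicc"].min()
    table["daicc"] = table["aicc"] - best_aicc
    best_label = table.loc[table["aicc"].idxmin(), "subset"]
    best_subset = tuple(best_label.split("+")) if best_label else ()
    return ModelSelectionTable(table=table, fits=fits, best_subset=best_subset)


def predict_with_se(
    fit: GlmFit,
    newdata: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted mean and delta-method SE on the response scale.

    ``eta = X beta``, ``SE_eta = sqrt(x' Sigma x)``; response mean is the
    inverse link of eta and its SE is ``|dmu/deta| * SE_eta``. Prediction
    beyond the observed covariate range is allowed (logged at debug level).
    """
    X, names, _ = build_design(newdata, fit.covariates,
                               factor_levels=fit.factor_levels)
    if names != fit.column_names:
        raise ValueError(
            f"newdata columns {names} do not match design {fit.column_names}"
        )
    eta = X @ fit.beta
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.covariance, X))
    if fit.family == "poisson":
        mu = np.exp(eta)
        dmu = mu
    else:
        mu = expit(eta)
        dmu = mu * (1 - mu)
    return mu, np.abs(dmu) * se_eta


def detection_curves(
    fit: GlmFit,
    levels: Sequence[str],
    level_covariate: str,
    camera_rate_grid: Sequence[float],
    volume: float = 60.0,
    catchment_area: float = 500.0,
    rain_values: Sequence[float] = (0.0, 30.0),
    extra: dict | None = None,
) -> pd.DataFrame:
    """Predicted eDNA site-detection probability curves per group and rain.

    For each level of the taxonomic/diet factor and each rain value, the
    fitted binomial model is evaluated over a grid of catchment-average
    camera detection rates at fixed volume (60 L) and catchment area
    (500 km2). Returns long-format (level, rain, camera_rate, mean, se).
    """
    if fit.family != "binomial":
        raise ValueError("detection curves require a binomial fit")
    cov_names = {c.name for c in fit.covariates}
    if "camera_rate" not in cov_names:
        raise ValueError("fitted model must include camera_rate")
    if level_covariate in fit.factor_levels:
        known = set(fit.factor_levels[level_covariate])
        missing = set(levels) - known
        if missing:
            raise ValueError(f"levels absent from fit: {sorted(missing)}")
    frames = []
    for lev in levels:
        for rain in rain_values:
            nd = pd.DataFrame({"camera_rate": list(camera_rate_grid)})
            nd[level_covariate] = lev
            if "volume" in cov_names:
                nd["volume"] = volume
            if "catchment_area" in cov_names:
                nd["catchment_area"] = catchment_area
            if "rain_prev_day" in cov_names:
                nd["rain_prev_day"] = rain
            for name, value in (extra or {}).items():
                nd[name] = value
            mean, se = predict_with_se(fit, nd)
            frames.append(pd.DataFrame(
                {"level": lev, "rain": rain,
                 "camera_rate": nd["camera_rate"], "mean": mean, "se": se}
            ))
    return pd.concat(frames, ignore_index=True)


def camera_rates(
    deployments: Sequence[CameraDeployment],
    membership: dict[str, set[str]],
) -> pd.DataFrame:
    """Catchment-average camera detection rates per taxon and eDNA site.

    ``rate(taxon, site)`` is the mean over the site's upstream cameras of
    (independent pictures / trap-days). A taxon never photographed gets 0.
    Returns a taxon x eDNA-site DataFrame.
    """
    by_site = {d.site_id: d for d in deployments}
    taxa = sorted({t for d in deployments for t in d.detections})
    cols = {}
    for edna_site, cameras in membership.items():
        if not cameras:
            raise ValueError(f"eDNA site {edna_site!r} has empty camera membership")
        unknown = set(cameras) - set(by_site)
        if unknown:
            raise ValueError(
                f"eDNA site {edna_site!r}: unknown cameras {sorted(unknown)}"
            )
        rates = []
        for taxon in taxa:
            per_cam = [
                by_site[c].detections.get(taxon, 0) / by_site[c].trap_days
                for c in sorted(cameras)
            ]
            rates.append(float(np.mean(per_cam)))
        cols[edna_site] = rates
    return pd.DataFrame(cols, index=taxa)
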