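"""Bayesian binomial-logit geostatistical model with a Matérn Gaussian field.

The model: conditional on the true prevalence P(x_i) at cluster location x_i,
the count of modern-contraception users Y_i out of n_i women in need is
Binomial(n_i, P(x_i)) with

    logit P(x_i) = beta0 + D_i beta + S(x_i),

where D is a dummy-coded design matrix of individual covariates and S(.) is a
zero-mean Gaussian process with variance sigma^2 and Matérn correlation
rho(u; phi, kappa).  Priors are Gaussian on the regression coefficients and on
the log hyperparameters theta1 = log sigma^2, theta2 = log phi.

Inference is a dense-covariance Laplace approximation: for each node of a
(theta1, theta2) grid the joint mode of (beta, S) is found by Newton's method
(the binomial-logit log-likelihood plus Gaussian priors is strictly concave),
a Gaussian approximation is formed at the mode, and nodes are weighted by the
Laplace-approximate marginal likelihood times the hyperprior.  Posteriors are
grid mixtures of conditional Gaussians.  A random-walk/elliptical-slice MCMC
sampler provides an independent cross-check of the same posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import brentq
from scipy.stats import norm

from .geodata import (
    CATEGORY_LEVELS,
    GeoPoint,
    WomanRecord,
    categorize_distance,
    pairwise_haversine_km,
    cross_haversine_km,
)

__all__ = [
    "MaternParams",
    "ModelSpec",
    "ClusterSummary",
    "BinomialDesign",
    "PosteriorFit",
    "PredictionSurface",
    "matern_correlation",
    "build_covariance",
    "cluster_summaries",
    "build_design",
    "log_joint",
    "fit_laplace",
    "fit_laplace_design",
    "fit_mcmc",
    "predict_surface",
    "posterior_odds_ratios",
]


@dataclass(frozen=True)
class MaternParams:
    """Matérn field hyperparameters: variance sigma2, scale phi (km), shape kappa."""

    sigma2: float
    phi: float
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sigma2 > 0 and self.phi > 0 and self.kappa > 0):
            raise ValueError(f"Matérn parameters must be positive: {self}")


def matern_correlation(u, phi: float, kappa: float):
    """Matérn correlation rho(u; phi, kappa) at distance(s) u >= 0 km.

    rho(u) = 2^(1-kappa)/Gamma(kappa) * (u/phi)^kappa * K_kappa(u/phi), with
    rho(0) = 1 by continuity.  kappa = 0.5 reduces to exp(-u/phi) and
    kappa = 1.5 to (1 + u/phi) exp(-u/phi).
    """
    if phi <= 0 or kappa <= 0:
        raise ValueError(f"phi and kappa must be positive (phi={phi}, kappa={kappa})")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("distances must be nonnegative")
    t = u / phi
    with np.errstate(invalid="ignore", over="ignore", under="ignore"):
        val = (
            (2.0 ** (1.0 - kappa) / special.gamma(kappa))
            * np.power(t, kappa)
            * special.kv(kappa, t)
        )
    out = np.where(t == 0.0, 1.0, val)
    # K_kappa underflows for large arguments; correlation there is 0
    out = np.nan_to_num(out, nan=0.0, posinf=1.0, neginf=0.0)
    return out if out.ndim else float(out)


def _chol_with_jitter(mat: np.ndarray, base_jitter: float, max_jitter: float):
    """Cholesky factor of mat + jitter*I, escalating jitter tenfold as needed."""
    jitter = base_jitter
    while jitter <= max_jitter:
        try:
            c = cho_factor(mat + jitter * np.eye(mat.shape[0]), lower=True)
            return c, jitter
        except np.linalg.LinAlgError:
            jitter *= 10.0
    eigmin = float(np.linalg.eigvalsh(mat).min())
    raise np.linalg.LinAlgError(
        f"covariance not positive definite after jitter {max_jitter:g} "
        f"(smallest eigenvalue {eigmin:.3e})"
    )


def build_covariance(
    points: Sequence[GeoPoint] | np.ndarray, params: MaternParams
) -> np.ndarray:
    """Dense Matérn covariance sigma2 * rho(u_ij) over great-circle distances.

    ``points`` may also be a precomputed distance matrix in km.  A diagonal
    jitter of 1e-8 * sigma2 is added for numerical positive definiteness.
    """
    if isinstance(points, np.ndarray) and points.ndim == 2 and points.shape[0] == points.shape[1]:
        dists = points
    else:
        dists = pairwise_haversine_km(points)
    cov = params.sigma2 * matern_correlation(dists, params.phi, params.kappa)
    cov[np.diag_indices_from(cov)] += 1e-8 * params.sigma2
    return cov


# ---------------------------------------------------------------------------
# Design construction


#: Reference level of each factor (dropped by dummy coding).
DEFAULT_REFERENCES: dict[str, str] = {
    "age_group": "15-19",
    "education": "never",
    "marital": "not_married",
    "religion": "christian",
    "wealth": "low",
    "residence": "urban",
    "parity": "0-1",
    "media": "no",
    "ever_pregnant": "no",
    "partner_discussion": "no",
    "partner_feeling": "disapprove",
    "fertility_intention": "have_another",
    "sdp_distance": "le2km",
    "region": "Addis Ababa",
}

#: Full factor list in reporting order.
DEFAULT_FACTORS: tuple[str, ...] = (
    "age_group",
    "education",
    "marital",
    "religion",
    "wealth",
    "residence",
    "parity",
    "media",
    "ever_pregnant",
    "partner_discussion",
    "partner_feeling",
    "fertility_intention",
    "sdp_distance",
    "region",
)


@dataclass
class ModelSpec:
    """Model structure and priors.

    ``factors`` lists the categorical covariates entering the linear predictor
    (dummy coded against ``references``).  ``prior_sd_beta`` is the sd of the
    independent zero-mean Gaussian priors on the intercept and coefficients;
    ``hyper_mean``/``hyper_sd`` give the independent Gaussian hyperpriors on
    theta1 = log sigma^2 and theta2 = log phi.  The hyperparameter grid has
    ``grid_res`` points per axis spanning ``grid_halfwidth`` prior sds around
    the hyperprior mean, pruned to nodes within ``prune_logml`` log-units of
    the best marginal likelihood.
    """

    factors: tuple[str, ...] = DEFAULT_FACTORS
    references: dict[str, str] = dc_field(default_factory=lambda: dict(DEFAULT_REFERENCES))
    prior_sd_beta: float = 10.0
    hyper_mean: tuple[float, float] = (0.0, 0.0)
    hyper_sd: tuple[float, float] = (2.0, 2.0)
    grid_res: int = 15
    grid_halfwidth: float = 3.0
    prune_logml: float = 10.0
    kappa: float = 1.0
    newton_tol: float = 1e-6
    newton_maxit: int = 100
    #: importance-sampling draws per retained node used to correct the
    #: Gaussian-at-mode approximation (the joint mode underestimates strongly
    #: skewed coefficient means); 0 disables the correction.
    is_draws: int = 2000


@dataclass
class ClusterSummary:
    """Per-enumeration-area binomial summary: y_i users of n_i women in need."""

    ea_id: str
    location: GeoPoint
    n_i: int
    y_i: int

    def __post_init__(self) -> None:
        if not (self.n_i >= 1 and 0 <= self.y_i <= self.n_i):
            raise ValueError(f"invalid cluster counts y={self.y_i}, n={self.n_i}")


def cluster_summaries(
    records: Sequence[WomanRecord],
    ea_locations: dict[str, GeoPoint] | None = None,
) -> list[ClusterSummary]:
    """Aggregate records into per-EA (location, n_i, y_i) summaries.

    When no centroid map is given the EA location is the mean household
    position.  EAs are ordered by id for determinism.
    """
    by_ea: dict[str, list[WomanRecord]] = {}
    for w in records:
        by_ea.setdefault(w.ea_id, []).append(w)
    out = []
    for ea_id in sorted(by_ea):
        group = by_ea[ea_id]
        if ea_locations is not None:
            loc = ea_locations[ea_id]
        else:
            loc = GeoPoint(
                float(np.mean([w.household_location.lon for w in group])),
                float(np.mean([w.household_location.lat for w in group])),
            )
        out.append(
            ClusterSummary(
                ea_id=ea_id,
                location=loc,
                n_i=len(group),
                y_i=sum(w.uses_modern for w in group),
            )
        )
    return out


def _factor_value(w: WomanRecord, factor: str) -> str:
    if factor == "sdp_distance":
        if w.sdp_distance_km is None:
            raise ValueError(f"record {w.woman_id}: sdp_distance_km unset")
        return categorize_distance(w.sdp_distance_km)
    return getattr(w, factor)


def _factor_levels(factor: str, records: Sequence[WomanRecord]) -> list[str]:
    if factor in CATEGORY_LEVELS:
        return list(CATEGORY_LEVELS[factor])
    if factor == "sdp_distance":
        return ["le2km", "2to6km", "gt6km"]
    # free-label factors (region, zone): levels discovered from data
    return sorted({getattr(w, factor) for w in records})


@dataclass
class BinomialDesign:
    """Binomial likelihood rows: covariate-pattern cells within clusters.

    Women sharing an EA and a covariate pattern are collapsed into one
    binomial row, so individual covariates are preserved exactly while the
    spatial effect stays cluster-level.
    """

    X: np.ndarray          # (J, p) design incl. intercept column
    y: np.ndarray          # (J,) users
    n: np.ndarray          # (J,) women
    ea_index: np.ndarray   # (J,) index into ea_ids
    ea_ids: list[str]
    ea_locations: list[GeoPoint]
    colnames: list[str]
    row_weights: np.ndarray | None = None  # mean sampling weight per row

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    @property
    def n_clusters(self) -> int:
        return len(self.ea_ids)

    def weighted_mean_row(self) -> np.ndarray:
        """Design row of the weighted-average covariate profile."""
        if self.row_weights is not None:
            w_eff = self.row_weights * self.n  # total sampling weight per cell
        else:
            w_eff = self.n.astype(float)
        return (self.X * w_eff[:, None]).sum(axis=0) / w_eff.sum()


def build_design(
    records: Sequence[WomanRecord],
    spec: ModelSpec,
    ea_locations: dict[str, GeoPoint] | None = None,
) -> BinomialDesign:
    """Dummy-coded design over covariate-pattern cells within EAs.

    Raises on a rank-deficient design (e.g. a factor level perfectly aliased
    with another).
    """
    level_map = {f: _factor_levels(f, records) for f in spec.factors}
    colnames = ["intercept"]
    for f in spec.factors:
        ref = spec.references.get(f)
        levels = level_map[f]
        if ref not in levels:
            ref = levels[0]
        for lev in levels:
            if lev != ref:
                colnames.append(f"{f}:{lev}")
    col_index = {c: i for i, c in enumerate(colnames)}

    ea_ids = sorted({w.ea_id for w in records})
    ea_pos = {e: i for i, e in enumerate(ea_ids)}
    cells: dict[tuple, list[int, int, float, int]] = {}
    for w in records:
        pattern = tuple(_factor_value(w, f) for f in spec.factors)
        key = (w.ea_id, pattern)
        cell = cells.setdefault(key, [0, 0, 0.0, ea_pos[w.ea_id]])
        cell[0] += 1
        cell[1] += int(w.uses_modern)
        cell[2] += w.weight

    J, p = len(cells), len(colnames)
    X = np.zeros((J, p))
    y = np.zeros(J)
    n = np.zeros(J)
    ea_index = np.zeros(J, dtype=int)
    row_weights = np.zeros(J)
    for j, ((ea_id, pattern), (nn, yy, ww, ei)) in enumerate(sorted(cells.items())):
        X[j, 0] = 1.0
        for f, lev in zip(spec.factors, pattern):
            c = col_index.get(f"{f}:{lev}")
            if c is not None:
                X[j, c] = 1.0
        y[j], n[j], ea_index[j], row_weights[j] = yy, nn, ei, ww / nn

    if ea_locations is None:
        locs = {c.ea_id: c.location for c in cluster_summaries(records)}
    else:
        locs = ea_locations
    rank = np.linalg.matrix_rank(X.T @ X)
    if rank < p:
        raise ValueError(f"design matrix rank {rank} < {p}: aliased factor levels")
    return BinomialDesign(
        X=X, y=y, n=n, ea_index=ea_index, ea_ids=ea_ids,
        ea_locations=[locs[e] for e in ea_ids], colnames=colnames,
        row_weights=row_weights,
    )


# ---------------------------------------------------------------------------
# Log joint and Laplace machinery


def binomial_loglik(y: np.ndarray, n: np.ndarray, eta: np.ndarray) -> float:
    """Sum_j [ y_j eta_j - n_j log(1 + e^eta_j) ] (binomial kernel, no binom coef)."""
    return float(np.sum(y * eta - n * np.logaddexp(0.0, eta)))


def log_joint(
    design: BinomialDesign,
    gamma: np.ndarray,
    field_values: np.ndarray,
    theta: tuple[float, float],
    spec: ModelSpec,
    dists: np.ndarray | None = None,
) -> float:
    """Unnormalised log posterior of (coefficients, field, theta).

    Likelihood kernel + Gaussian prior on the coefficients + the Gaussian
    process prior on the field given theta + hyperpriors on theta.
    """
    gamma = np.asarray(gamma, dtype=float)
    field_values = np.asarray(field_values, dtype=float)
    if gamma.shape[0] != design.n_coef or field_values.shape[0] != design.n_clusters:
        raise ValueError(
            f"dimension mismatch: gamma {gamma.shape} vs p={design.n_coef}, "
            f"field {field_values.shape} vs m={design.n_clusters}"
        )
    eta = design.X @ gamma + field_values[design.ea_index]
    ll = binomial_loglik(design.y, design.n, eta)
    tau2 = spec.prior_sd_beta**2
    lp_gamma = -0.5 * float(gamma @ gamma) / tau2 - 0.5 * len(gamma) * math.log(
        2 * math.pi * tau2
    )
    sigma2, phi = math.exp(theta[0]), math.exp(theta[1])
    if dists is None:
        dists = pairwise_haversine_km(design.ea_locations)
    cov = build_covariance(dists, MaternParams(sigma2, phi, spec.kappa))
    c, _ = _chol_with_jitter(cov, 0.0, 1e-4 * sigma2)
    alpha = cho_solve(c, field_values)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    m = design.n_clusters
    lp_field = -0.5 * float(field_values @ alpha) - 0.5 * logdet - 0.5 * m * math.log(2 * math.pi)
    lp_hyper = sum(
        norm.logpdf(theta[i], spec.hyper_mean[i], spec.hyper_sd[i]) for i in (0, 1)
    )
    return ll + lp_gamma + lp_field + lp_hyper


def _newton_mode(design, Rinv_over_s2, logdet_sigma, tau2, spec, z0=None):
    """Newton ascent to the joint mode of (gamma, S) at fixed hyperparameters.

    Returns (z_mode, chol_H, log_target_at_mode) where H is the negative
    Hessian at the mode and log_target = loglik + log p(z | theta).
    """
    X, y, n, ei = design.X, design.y, design.n, design.ea_index
    p, m = design.n_coef, design.n_clusters
    z = np.zeros(p + m) if z0 is None else z0.copy()

    def log_target(z):
        eta = X @ z[:p] + z[p:][ei]
        ll = binomial_loglik(y, n, eta)
        lp = (
            -0.5 * float(z[:p] @ z[:p]) / tau2
            - 0.5 * p * math.log(2 * math.pi * tau2)
            - 0.5 * float(z[p:] @ (Rinv_over_s2 @ z[p:]))
            - 0.5 * logdet_sigma
            - 0.5 * m * math.log(2 * math.pi)
        )
        return ll + lp

    f = log_target(z)
    cH = None
    for _ in range(spec.newton_maxit):
        eta = X @ z[:p] + z[p:][ei]
        mu = special.expit(eta)
        g_eta = y - n * mu
        W = n * mu * (1.0 - mu)
        grad = np.empty(p + m)
        grad[:p] = X.T @ g_eta - z[:p] / tau2
        grad[p:] = np.bincount(ei, weights=g_eta, minlength=m) - Rinv_over_s2 @ z[p:]
        if float(np.max(np.abs(grad))) < spec.newton_tol:
            break
        XtW = X.T * W
        H = np.empty((p + m, p + m))
        H[:p, :p] = XtW @ X + np.eye(p) / tau2
        B = np.zeros((p, m))
        for k in range(p):
            B[k] = np.bincount(ei, weights=XtW[k], minlength=m)
        H[:p, p:] = B
        H[p:, :p] = B.T
        H[p:, p:] = Rinv_over_s2 + np.diag(np.bincount(ei, weights=W, minlength=m))
        cH = cho_factor(H, lower=True)
        step = cho_solve(cH, grad)
        # affine-invariant stop: half the squared Newton decrement
        if 0.5 * float(grad @ step) < 1e-9:
            break
        # backtracking: the target is concave so full steps almost always hold
        t = 1.0
        for _bt in range(40):
            z_new = z + t * step
            f_new = log_target(z_new)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        else:
            raise RuntimeError("Newton line search failed to improve the target")
        z, f = z_new, f_new
    else:
        raise RuntimeError(
            f"Newton did not converge in {spec.newton_maxit} iterations "
            f"(|grad|_inf = {float(np.max(np.abs(grad))):.2e})"
        )
    if cH is None:  # converged at start; still need H for the Laplace step
        eta = X @ z[:p] + z[p:][ei]
        mu = special.expit(eta)
        W = n * mu * (1.0 - mu)
        XtW = X.T * W
        H = np.empty((p + m, p + m))
        H[:p, :p] = XtW @ X + np.eye(p) / tau2
        B = np.zeros((p, m))
        for k in range(p):
            B[k] = np.bincount(ei, weights=XtW[k], minlength=m)
        H[:p, p:] = B
        H[p:, :p] = B.T
        H[p:, p:] = Rinv_over_s2 + np.diag(np.bincount(ei, weights=W, minlength=m))
        cH = cho_factor(H, lower=True)
    else:
        # refresh the factor at the final iterate
        eta = X @ z[:p] + z[p:][ei]
        mu = special.expit(eta)
        W = n * mu * (1.0 - mu)
        XtW = X.T * W
        H = np.empty((p + m, p + m))
        H[:p, :p] = XtW @ X + np.eye(p) / tau2
        B = np.zeros((p, m))
        for k in range(p):
            B[k] = np.bincount(ei, weights=XtW[k], minlength=m)
        H[:p, p:] = B
        H[p:, :p] = B.T
        H[p:, p:] = Rinv_over_s2 + np.diag(np.bincount(ei, weights=W, minlength=m))
        cH = cho_factor(H, lower=True)
    return z, cH, f


@dataclass
class PosteriorFit:
    """Grid-mixture Laplace posterior.

    ``nodes`` holds, per retained hyperparameter node: theta values, the
    normalised posterior weight, the joint mode of (coefficients, field), the
    Cholesky factor of the negative Hessian, and the log marginal likelihood.
    """

    coef_names: list[str]
    coef_table: pd.DataFrame       # mean, sd, q2.5, q97.5 per coefficient
    theta_table: pd.DataFrame      # posterior summaries of theta1, theta2
    nodes: list[dict]
    design: BinomialDesign
    spec: ModelSpec
    field_mean: np.ndarray         # per-cluster posterior mean of S
    field_sd: np.ndarray
    dists: np.ndarray              # cluster distance matrix (km)

    @property
    def n_coef(self) -> int:
        return len(self.coef_names)


def _mixture_summary(weights, means, sds, qs=(0.025, 0.975)):
    """Mean, sd and quantiles of a weighted mixture of normals."""
    weights = np.asarray(weights)
    means = np.asarray(means)
    sds = np.asarray(sds)
    mean = float(weights @ means)
    var = float(weights @ (sds**2 + means**2) - mean**2)
    sd = math.sqrt(max(var, 0.0))
    lo = float(np.min(means - 8 * sds))
    hi = float(np.max(means + 8 * sds))
    out = [mean, sd]
    for q in qs:
        if hi - lo < 1e-14:
            out.append(mean)
            continue
        f = lambda x: float(weights @ norm.cdf((x - means) / sds)) - q
        out.append(brentq(f, lo, hi, xtol=1e-10))
    return out


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    cw = np.cumsum(weights[order])
    cw /= cw[-1]
    return float(np.interp(q, cw, values[order]))


def _importance_correct(design, nodes, spec, dists, seed):
    """Self-normalised importance sampling at each significant grid node.

    The Gaussian at the joint mode is the proposal and the exact log joint the
    target, so the pooled weighted draws correct the mode-vs-mean discrepancy
    of skewed coefficient marginals.  Nodes whose effective sample size
    collapses keep their Gaussian summaries (weight left untouched).
    """
    rng = np.random.default_rng(seed)
    X, y, n, ei = design.X, design.y, design.n, design.ea_index
    p, m = design.n_coef, design.n_clusters
    tau2 = spec.prior_sd_beta**2
    K = spec.is_draws
    for node in nodes:
        if node["weight"] < 0.02:
            continue
        sigma2 = math.exp(node["theta1"])
        phi = math.exp(node["theta2"])
        R = matern_correlation(dists, phi, spec.kappa)
        cR, _ = _chol_with_jitter(R, 1e-8, 1e-4)
        Rinv_s2 = cho_solve(cR, np.eye(m)) / sigma2
        eps = rng.standard_normal((K, p + m))
        Z = node["mode"] + solve_triangular(
            node["chol_H"][0], eps.T, lower=True, trans="T"
        ).T
        eta = Z[:, :p] @ X.T + Z[:, p:][:, ei]
        ll = (y * eta - n * np.logaddexp(0.0, eta)).sum(axis=1)
        lp = (
            -0.5 * (Z[:, :p] ** 2).sum(axis=1) / tau2
            - 0.5 * np.einsum("ki,ij,kj->k", Z[:, p:], Rinv_s2, Z[:, p:])
        )
        lw = ll + lp + 0.5 * (eps**2).sum(axis=1)
        lw -= lw.max()
        w = np.exp(lw)
        w /= w.sum()
        if 1.0 / float(np.sum(w**2)) < 50.0:
            continue
        node["is_samples"] = Z
        node["is_weights"] = w


def fit_laplace_design(
    design: BinomialDesign, spec: ModelSpec | None = None, seed: int = 0
) -> PosteriorFit:
    """Laplace-approximate posterior over a (theta1, theta2) grid.

    An importance-sampling correction (``spec.is_draws`` draws per retained
    node, seeded) refines the Gaussian-at-mode coefficient summaries.
    """
    spec = spec or ModelSpec()
    p, m = design.n_coef, design.n_clusters
    if m < 2:
        raise ValueError("need at least 2 clusters")
    tau2 = spec.prior_sd_beta**2
    dists = pairwise_haversine_km(design.ea_locations)

    t1_grid = np.linspace(
        spec.hyper_mean[0] - spec.grid_halfwidth * spec.hyper_sd[0],
        spec.hyper_mean[0] + spec.grid_halfwidth * spec.hyper_sd[0],
        spec.grid_res,
    )
    t2_grid = np.linspace(
        spec.hyper_mean[1] - spec.grid_halfwidth * spec.hyper_sd[1],
        spec.hyper_mean[1] + spec.grid_halfwidth * spec.hyper_sd[1],
        spec.grid_res,
    )

    nodes = []
    z_warm = None
    for t2 in t2_grid:
        phi = math.exp(t2)
        R = matern_correlation(dists, phi, spec.kappa)
        cR, _ = _chol_with_jitter(R, 1e-8, 1e-4)
        logdet_R = 2.0 * float(np.sum(np.log(np.diag(cR[0]))))
        Rinv = cho_solve(cR, np.eye(m))
        for t1 in t1_grid:
            sigma2 = math.exp(t1)
            Rinv_over_s2 = Rinv / sigma2
            logdet_sigma = logdet_R + m * math.log(sigma2)
            z, cH, log_target = _newton_mode(
                design, Rinv_over_s2, logdet_sigma, tau2, spec, z0=z_warm
            )
            z_warm = z
            logdet_H = 2.0 * float(np.sum(np.log(np.diag(cH[0]))))
            log_ml = log_target + 0.5 * (p + m) * math.log(2 * math.pi) - 0.5 * logdet_H
            log_post = log_ml + sum(
                norm.logpdf((t1, t2)[i], spec.hyper_mean[i], spec.hyper_sd[i])
                for i in (0, 1)
            )
            nodes.append(
                {"theta1": float(t1), "theta2": float(t2), "log_ml": log_ml,
                 "log_post": log_post, "mode": z, "chol_H": cH}
            )

    best = max(n["log_post"] for n in nodes)
    nodes = [n for n in nodes if n["log_post"] >= best - spec.prune_logml]
    lw = np.array([n["log_post"] for n in nodes])
    w = np.exp(lw - lw.max())
    w /= w.sum()
    for n, wi in zip(nodes, w):
        n["weight"] = float(wi)
        Hinv_diag = np.sum(cho_solve(n["chol_H"], np.eye(p + m)) * np.eye(p + m), axis=1)
        # cho_solve on identity gives the full inverse; keep only its diagonal
        n["marg_var"] = np.maximum(Hinv_diag, 1e-300)

    if spec.is_draws > 0:
        _importance_correct(design, nodes, spec, dists, seed)

    def component_summary(k: int):
        """Mean/sd/quantiles of latent component k across the node mixture,
        using IS draws where available and the node Gaussian otherwise."""
        vals, vw = [], []       # pooled importance draws
        g_w, g_mu, g_sd = [], [], []  # Gaussian components
        for n_, wi in zip(nodes, w):
            if "is_samples" in n_:
                vals.append(n_["is_samples"][:, k])
                vw.append(wi * n_["is_weights"])
            else:
                g_w.append(wi)
                g_mu.append(n_["mode"][k])
                g_sd.append(math.sqrt(n_["marg_var"][k]))
        vals = np.concatenate(vals) if vals else np.empty(0)
        vw = np.concatenate(vw) if vw else np.empty(0)
        g_w = np.asarray(g_w)
        g_mu = np.asarray(g_mu)
        g_sd = np.asarray(g_sd)
        mean = float(vw @ vals) + float(g_w @ g_mu) if len(g_w) else float(vw @ vals)
        second = float(vw @ vals**2)
        if len(g_w):
            second += float(g_w @ (g_sd**2 + g_mu**2))
        sd = math.sqrt(max(second - mean**2, 0.0))

        def cdf(x):
            c = float(np.sum(vw[vals <= x]))
            if len(g_w):
                c += float(g_w @ norm.cdf((x - g_mu) / g_sd))
            return c

        lo_candidates = [vals.min()] if len(vals) else []
        hi_candidates = [vals.max()] if len(vals) else []
        if len(g_w):
            lo_candidates.append(float(np.min(g_mu - 8 * g_sd)))
            hi_candidates.append(float(np.max(g_mu + 8 * g_sd)))
        lo, hi = min(lo_candidates), max(hi_candidates)
        out = [mean, sd]
        for q in (0.025, 0.975):
            if hi - lo < 1e-14:
                out.append(mean)
            else:
                out.append(brentq(lambda x: cdf(x) - q, lo - 1e-9, hi + 1e-9,
                                  xtol=1e-10))
        return out

    rows = []
    for k, name in enumerate(design.colnames):
        mean, sd, q025, q975 = component_summary(k)
        rows.append({"coefficient": name, "mean": mean, "sd": sd,
                     "q2.5": q025, "q97.5": q975})
    coef_table = pd.DataFrame(rows)

    field_mean = np.zeros(m)
    field_var = np.zeros(m)
    for n_, wi in zip(nodes, w):
        if "is_samples" in n_:
            mu = n_["is_weights"] @ n_["is_samples"][:, p:]
            second = n_["is_weights"] @ n_["is_samples"][:, p:] ** 2
            field_mean += wi * mu
            field_var += wi * second
        else:
            mu = n_["mode"][p:]
            field_mean += wi * mu
            field_var += wi * (n_["marg_var"][p:] + mu**2)
    field_var -= field_mean**2
    field_sd = np.sqrt(np.maximum(field_var, 0.0))

    theta_rows = []
    for i, name in enumerate(["theta1", "theta2"]):
        vals = np.array([n_[f"theta{i+1}"] for n_ in nodes])
        mean = float(w @ vals)
        sd = math.sqrt(max(float(w @ vals**2) - mean**2, 0.0))
        order = np.argsort(vals)
        cdf = np.cumsum(w[order])
        q025 = float(vals[order][np.searchsorted(cdf, 0.025)])
        q975 = float(vals[order][min(np.searchsorted(cdf, 0.975), len(vals) - 1)])
        theta_rows.append({"parameter": name, "mean": mean, "sd": sd,
                           "q2.5": q025, "q97.5": q975})
    theta_table = pd.DataFrame(theta_rows)

    return PosteriorFit(
        coef_names=list(design.colnames),
        coef_table=coef_table,
        theta_table=theta_table,
        nodes=nodes,
        design=design,
        spec=spec,
        field_mean=field_mean,
        field_sd=field_sd,
        dists=dists,
    )


def fit_laplace(
    records: Sequence[WomanRecord],
    spec: ModelSpec | None = None,
    ea_locations: dict[str, GeoPoint] | None = None,
    seed: int = 0,
) -> PosteriorFit:
    """Fit the geostatistical model to woman records (>= 10 clusters)."""
    spec = spec or ModelSpec()
    design = build_design(records, spec, ea_locations=ea_locations)
    if design.n_clusters < 10:
        raise ValueError(f"need >= 10 clusters, got {design.n_clusters}")
    return fit_laplace_design(design, spec, seed=seed)


# ---------------------------------------------------------------------------
# Prediction


@dataclass
class PredictionSurface:
    """Posterior prevalence surface on a lattice, with credible bands."""

    points: list[GeoPoint]
    mean: np.ndarray
    q025: np.ndarray
    q975: np.ndarray
    field_mean: np.ndarray
    field_sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lon": [pt.lon for pt in self.points],
                "lat": [pt.lat for pt in self.points],
                "prev_mean": self.mean,
                "prev_q2.5": self.q025,
                "prev_q97.5": self.q975,
                "field_mean": self.field_mean,
                "field_sd": self.field_sd,
            }
        )


def predict_surface(
    fit: PosteriorFit,
    lattice: Sequence[GeoPoint],
    covariate_profile: np.ndarray | None = None,
    n_draws: int = 2000,
    seed: int = 0,
) -> PredictionSurface:
    """Posterior prevalence at new locations for a fixed covariate profile.

    For each posterior draw the hyperparameter node is sampled by weight,
    (coefficients, field) are drawn from that node's Gaussian, the field is
    kriged to the lattice by exact GP conditioning (pointwise), and prevalence
    is the inverse logit of profile + kriged field.  The default profile is
    the weighted mean design row (a population-average covariate setting).
    """
    rng = np.random.default_rng(seed)
    design = fit.design
    p, m = design.n_coef, design.n_clusters
    if covariate_profile is None:
        covariate_profile = design.weighted_mean_row()
    covariate_profile = np.asarray(covariate_profile, dtype=float)
    L = len(lattice)
    d_cross = cross_haversine_km(lattice, design.ea_locations)  # (L, m)

    # per-node conditioning cache, keyed by theta2 (phi) for R and by node for scale
    cache_phi: dict[float, tuple] = {}
    node_w = np.array([n["weight"] for n in fit.nodes])
    node_choice = rng.choice(len(fit.nodes), size=n_draws, p=node_w)
    draws = np.empty((n_draws, L))
    field_draws = np.empty((n_draws, L))
    eps_z = rng.standard_normal((n_draws, p + m))
    eps_s = rng.standard_normal((n_draws, L))

    for idx in range(n_draws):
        node = fit.nodes[node_choice[idx]]
        t1, t2 = node["theta1"], node["theta2"]
        sigma2, phi = math.exp(t1), math.exp(t2)
        if t2 not in cache_phi:
            R = matern_correlation(fit.dists, phi, fit.spec.kappa)
            cR, _ = _chol_with_jitter(R, 1e-8, 1e-4)
            r_cross = matern_correlation(d_cross, phi, fit.spec.kappa)  # (L, m)
            A = cho_solve(cR, r_cross.T)  # (m, L): R^-1 r
            base_var = 1.0 - np.sum(r_cross.T * A, axis=0)  # (L,)
            cache_phi[t2] = (A, np.maximum(base_var, 1e-10))
        A, base_var = cache_phi[t2]
        if "is_samples" in node:
            # resample from the node's importance-corrected posterior
            j = rng.choice(len(node["is_weights"]), p=node["is_weights"])
            z = node["is_samples"][j]
        else:
            # draw (gamma, S) ~ N(mode, H^-1): z = mode + L^-T eps
            cH = node["chol_H"]
            z = node["mode"] + solve_triangular(cH[0], eps_z[idx], lower=True,
                                                trans="T")
        S = z[p:]
        s_mean = S @ A  # (L,)
        s_var = sigma2 * base_var
        S_star = s_mean + np.sqrt(s_var) * eps_s[idx]
        field_draws[idx] = S_star
        draws[idx] = special.expit(covariate_profile @ z[:p] + S_star)

    mean = draws.mean(axis=0)
    q025 = np.quantile(draws, 0.025, axis=0)
    q975 = np.quantile(draws, 0.975, axis=0)
    return PredictionSurface(
        points=list(lattice),
        mean=mean,
        q025=np.minimum(q025, mean),
        q975=np.maximum(q975, mean),
        field_mean=field_draws.mean(axis=0),
        field_sd=field_draws.std(axis=0),
    )


# ---------------------------------------------------------------------------
# Reporting


def posterior_odds_ratios(fit: PosteriorFit) -> pd.DataFrame:
    """Coefficient table with posterior odds ratios (exp of log-odds summaries)."""
    tab = fit.coef_table.copy()
    tab["por_mean"] = np.exp(tab["mean"])
    tab["por_q2.5"] = np.exp(tab["q2.5"])
    tab["por_q97.5"] = np.exp(tab["q97.5"])
    return tab


# ---------------------------------------------------------------------------
# MCMC cross-check


@dataclass
class McmcFit:
    """Posterior samples from the slice-within-Metropolis sampler."""

    coef_names: list[str]
    gamma_samples: np.ndarray   # (n_kept, p)
    field_samples: np.ndarray   # (n_kept, m)
    theta_samples: np.ndarray   # (n_kept, 2)
    coef_table: pd.DataFrame
    accept_gamma: float
    accept_theta: float
    rhat: np.ndarray


def _split_rhat(chain: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor, per column."""
    nkeep = (chain.shape[0] // 2) * 2
    halves = chain[:nkeep].reshape(2, nkeep // 2, -1)
    means = halves.mean(axis=1)
    vars_ = halves.var(axis=1, ddof=1)
    W = vars_.mean(axis=0)
    B = (nkeep // 2) * means.var(axis=0, ddof=1)
    var_hat = (nkeep // 2 - 1) / (nkeep // 2) * W + B / (nkeep // 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sqrt(var_hat / W)


def fit_mcmc(
    design: BinomialDesign,
    spec: ModelSpec | None = None,
    n_iter: int = 4000,
    burn: int | None = None,
    seed: int = 0,
) -> McmcFit:
    """MCMC over the same posterior as :func:`fit_laplace_design`.

    Elliptical slice sampling for the latent field, componentwise random-walk
    Metropolis (with burn-in scale adaptation) for the coefficients, and a
    joint random-walk for (theta1, theta2).  Serves as an independent check of
    the Laplace route; reproducible by seed.
    """
    if n_iter < 2000:
        raise ValueError("n_iter must be >= 2000")
    spec = spec or ModelSpec()
    rng = np.random.default_rng(seed)
    burn = n_iter // 2 if burn is None else burn
    X, y, n, ei = design.X, design.y, design.n, design.ea_index
    p, m = design.n_coef, design.n_clusters
    tau2 = spec.prior_sd_beta**2
    has_data = len(y) > 0

    dists = pairwise_haversine_km(design.ea_locations) if m else np.zeros((0, 0))

    def chol_R(phi):
        R = matern_correlation(dists, phi, spec.kappa)
        cR, _ = _chol_with_jitter(R, 1e-8, 1e-4)
        return cR

    gamma = np.zeros(p)
    S = np.zeros(m)
    theta = np.array(spec.hyper_mean, dtype=float)
    cR = chol_R(math.exp(theta[1])) if m else None
    logdet_R = 2.0 * float(np.sum(np.log(np.diag(cR[0])))) if m else 0.0

    def loglik(gamma, S):
        if not has_data:
            return 0.0
        eta = X @ gamma + (S[ei] if m else 0.0)
        return binomial_loglik(y, n, eta)

    def field_logprior(S, theta, cR, logdet_R):
        if m == 0:
            return 0.0
        sigma2 = math.exp(theta[0])
        alpha = cho_solve(cR, S)
        return (
            -0.5 * float(S @ alpha) / sigma2
            - 0.5 * (logdet_R + m * math.log(sigma2))
            - 0.5 * m * math.log(2 * math.pi)
        )

    ll = loglik(gamma, S)
    step_gamma = np.full(p, 0.2)
    step_theta = 0.3
    acc_g = np.zeros(p)
    try_g = np.zeros(p)
    acc_t = 0
    kept_g, kept_S, kept_t = [], [], []

    for it in range(n_iter):
        # --- elliptical slice update for S (prior N(0, sigma2 R))
        if m:
            sig = math.exp(0.5 * theta[0])
            nu = sig * (cR[0] @ rng.standard_normal(m))
            log_u = ll + math.log(rng.random())
            angle = rng.random() * 2 * math.pi
            lo, hi = angle - 2 * math.pi, angle
            while True:
                S_prop = S * math.cos(angle) + nu * math.sin(angle)
                ll_prop = loglik(gamma, S_prop)
                if ll_prop > log_u or hi - lo < 1e-12:
                    S, ll = S_prop, ll_prop
                    break
                if angle < 0:
                    lo = angle
                else:
                    hi = angle
                angle = lo + rng.random() * (hi - lo)
        # --- componentwise RW Metropolis for gamma
        for k in range(p):
            prop = gamma.copy()
            prop[k] += step_gamma[k] * rng.standard_normal()
            ll_prop = loglik(prop, S)
            log_r = (ll_prop - ll) + (gamma[k] ** 2 - prop[k] ** 2) / (2 * tau2)
            try_g[k] += 1
            if math.log(rng.random()) < log_r:
                gamma, ll = prop, ll_prop
                acc_g[k] += 1
        # --- joint RW for theta
        if m:
            t_prop = theta + step_theta * rng.standard_normal(2)
            cR_prop = chol_R(math.exp(t_prop[1]))
            logdet_prop = 2.0 * float(np.sum(np.log(np.diag(cR_prop[0]))))
            lp_cur = field_logprior(S, theta, cR, logdet_R) + sum(
                norm.logpdf(theta[i], spec.hyper_mean[i], spec.hyper_sd[i]) for i in (0, 1)
            )
            lp_prop = field_logprior(S, t_prop, cR_prop, logdet_prop) + sum(
                norm.logpdf(t_prop[i], spec.hyper_mean[i], spec.hyper_sd[i]) for i in (0, 1)
            )
            if math.log(rng.random()) < lp_prop - lp_cur:
                theta, cR, logdet_R = t_prop, cR_prop, logdet_prop
                acc_t += 1
        # --- burn-in adaptation toward ~40% componentwise acceptance
        if it < burn and (it + 1) % 100 == 0:
            rates = np.where(try_g > 0, acc_g / np.maximum(try_g, 1), 0.4)
            step_gamma *= np.exp(np.clip(rates - 0.4, -0.5, 0.5))
            acc_g[:] = 0
            try_g[:] = 0
        if it >= burn:
            kept_g.append(gamma.copy())
            kept_S.append(S.copy())
            kept_t.append(theta.copy())

    gam = np.array(kept_g)
    fld = np.array(kept_S) if m else np.zeros((len(kept_g), 0))
    tht = np.array(kept_t) if kept_t else np.zeros((len(kept_g), 2))
    if not math.isfinite(ll):
        raise RuntimeError("MCMC diverged: non-finite log joint")
    rows = []
    for k, name in enumerate(design.colnames):
        s = gam[:, k]
        rows.append(
            {"coefficient": name, "mean": float(s.mean()), "sd": float(s.std(ddof=1)),
             "q2.5": float(np.quantile(s, 0.025)), "q97.5": float(np.quantile(s, 0.975))}
        )
    return McmcFit(
        coef_names=list(design.colnames),
        gamma_samples=gam,
        field_samples=fld,
        theta_samples=tht,
        coef_table=pd.DataFrame(rows),
        accept_gamma=float((gam[1:] != gam[:-1]).any(axis=1).mean()) if len(gam) > 1 else 0.0,
        accept_theta=acc_t / max(n_iter, 1),
        rhat=_split_rhat(gam),
    )
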