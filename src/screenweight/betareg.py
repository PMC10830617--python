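"""Hierarchical random-intercept Beta regression of C/IER proportions.

The group-by-scale C/IER proportion pi_sg is modelled as

    pi_sg ~ Beta(mu_sg * phi, (1 - mu_sg) * phi),
    mu_sg = inv_logit(beta_0g + sum_p beta_p x_ps),

with group intercepts beta_0g ~ N(mu_beta0, sigma_beta0^2), scale covariates
x_ps (screen position, number of items, number of response options, average
text length in words per item) and precision phi.

Two estimation modes:

* ``"bayes"`` -- adaptive random-walk Metropolis within Gibbs blocks
  (fixed effects jointly, group intercepts elementwise, log sigma_beta0,
  log phi), N(0, 10) priors on the fixed effects, half-Cauchy(0, 5) on
  sigma_beta0 and phi, 2 chains x 3000 iterations with the first half as
  warm-up, posterior-mean (EAP) point estimates, split-Rhat (PSRF) per
  parameter with < 1.05 taken as satisfactory.
* ``"ml"`` -- maximum likelihood with the random intercept integrated out by
  adaptive Gauss-Hermite quadrature (21 nodes) and direct optimisation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import betaln, expit, logsumexp

from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

COVARIATE_NAMES = ("screen_position", "n_items", "n_options", "avg_length")

PSRF_THRESHOLD = 1.05


@dataclasses.dataclass
class ScaleCovariates:
    """Characteristics of one questionnaire scale/screen."""

    screen_position: int
    n_items: float
    n_options: float
    avg_length: float

    def __post_init__(self):
        vals = dataclasses.astuple(self)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidInputError("covariates must be finite")
        if self.screen_position < 1:
            raise InvalidInputError("screen_position must be >= 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.screen_position, self.n_items,
                         self.n_options, self.avg_length], dtype=float)


@dataclasses.dataclass
class BetaRegressionData:
    """Proportions with group structure and scale covariates."""

    proportions: np.ndarray    # (n,) in (0,1) after boundary adjustment
    group: np.ndarray          # (n,) 0-based group index
    covariates: np.ndarray     # (n, P)
    covariate_names: tuple = COVARIATE_NAMES

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.group = np.asarray(self.group, dtype=int)
        self.covariates = np.asarray(self.covariates, dtype=float)
        n = self.proportions.size
        if self.group.shape != (n,) or self.covariates.shape[0] != n:
            raise InvalidInputError("misaligned proportions/group/covariates")
        y = self.proportions
        if np.any(y <= 0) or np.any(y >= 1):
            # standard boundary adjustment (y*(n-1) + 0.5)/n
            logger.info("boundary proportions present; applying "
                        "(y*(n-1)+0.5)/n adjustment")
            self.proportions = (y * (n - 1) + 0.5) / n

    @property
    def n_groups(self) -> int:
        return int(self.group.max()) + 1

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       proportion_column="cier_proportion",
                       covariate_columns=COVARIATE_NAMES):
        labels = np.sort(df["group_id"].unique())
        gmap = {lab: i for i, lab in enumerate(labels)}
        return cls(df[proportion_column].to_numpy(float),
                   df["group_id"].map(gmap).to_numpy(int),
                   df[list(covariate_columns)].to_numpy(float),
                   tuple(covariate_columns))


@dataclasses.dataclass
class BetaRegressionFit:
    method: str
    fixed: dict                    # intercept mean + slope point estimates
    random_intercept_sd: float
    precision: float
    group_intercepts: np.ndarray
    psrf: dict | None = None
    draws: dict | None = None      # pooled post-warm-up draws (bayes mode)
    posterior_sd: dict | None = None
    loglik: float | None = None    # marginal loglik (ml mode)
    converged: bool = True
    convergence_warning: bool = False

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "fixed": {k: float(v) for k, v in self.fixed.items()},
            "random_intercept_sd": float(self.random_intercept_sd),
            "precision": float(self.precision),
            "group_intercepts": np.asarray(self.group_intercepts).tolist(),
            "converged": bool(self.converged),
            "convergence_warning": bool(self.convergence_warning),
        }
        if self.psrf is not None:
            out["psrf"] = {k: float(v) for k, v in self.psrf.items()}
        if self.posterior_sd is not None:
            out["posterior_sd"] = {k: float(v)
                                   for k, v in self.posterior_sd.items()}
        if self.loglik is not None:
            out["loglik"] = float(self.loglik)
        return out


def predict_mean(intercept, slopes, covariates):
    """Expected proportion inv_logit(intercept + slopes . x)."""
    if isinstance(covariates, ScaleCovariates):
        x = covariates.as_array()
    else:
        x = np.asarray(covariates, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    if slopes.shape != x.shape:
        raise InvalidInputError("slopes and covariates must align")
    return float(expit(intercept + float(np.dot(slopes, x))))


def beta_loglik(mu, phi, y):
    """Log density of Beta(mu*phi, (1-mu)*phi) at y (all interior)."""
    mu = np.asarray(mu, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise InvalidInputError("y must lie strictly inside (0, 1)")
    if np.any(mu <= 0) or np.any(mu >= 1) or phi <= 0:
        raise InvalidInputError("require 0 < mu < 1 and phi > 0")
    a = mu * phi
    b = (1.0 - mu) * phi
    out = (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y) - betaln(a, b)
    return float(out) if out.ndim == 0 else out


def psrf(chains) -> float:
    """Split-Rhat (potential scale reduction factor) for one parameter.

    ``chains`` is an (n_chains, n_draws) array; each chain is split in half
    before the between/within variance ratio is formed.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 10:
        raise InvalidInputError("need >= 2 chains with >= 10 draws each")
    half = c.shape[1] // 2
    split = np.concatenate([c[:, :half], c[:, half:2 * half]], axis=0)
    m, n = split.shape
    means = split.mean(axis=1)
    W = split.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 1e-300:
        logger.warning("degenerate zero-variance chains in PSRF")
        return float("inf") if B > 0 else 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


@dataclasses.dataclass
class BetaRegConfig:
    method: str = "bayes"        # "bayes" or "ml"
    n_chains: int = 2
    n_iter: int = 3000           # per chain; first half is warm-up
    seed: int = 0
    n_quadrature: int = 21       # adaptive Gauss-Hermite nodes (ml mode)
    keep_draws: bool = True


# ---------------------------------------------------------------------------
# log posterior pieces (bayes mode)

_PRIOR_SD_FIXED = 10.0
_HC_SCALE = 5.0


def _log_half_cauchy(x, scale):
    # density 2/(pi*scale*(1+(x/scale)^2)) on x > 0
    return np.log(2.0 / (np.pi * scale)) - np.log1p((x / scale) ** 2)


def _clipped_mu(eta):
    return np.clip(expit(eta), 1e-12, 1.0 - 1e-12)


def _data_loglik_by_group(y, group, n_groups, eta, phi):
    ll = beta_loglik(_clipped_mu(eta), phi, y)
    return np.bincount(group, weights=ll, minlength=n_groups)


def fit_hierarchical_beta(data: BetaRegressionData,
                          config: BetaRegConfig | None = None
                          ) -> BetaRegressionFit:
    """Fit the hierarchical Beta regression in the configured mode."""
    config = config or BetaRegConfig()
    if data.n_groups < 2 or len(np.unique(
            data.covariates @ np.arange(1, data.n_covariates + 1))) < 2:
        raise InvalidInputError("need >= 2 groups and >= 2 distinct scales")
    if config.method == "bayes":
        return _fit_bayes(data, config)
    if config.method == "ml":
        return _fit_ml(data, config)
    raise InvalidInputError("method must be 'bayes' or 'ml'")


def _fit_bayes(data: BetaRegressionData, config: BetaRegConfig):
    y = data.proportions
    X = data.covariates
    g = data.group
    G = data.n_groups
    P = data.n_covariates
    names = (["intercept"] + list(data.covariate_names)
             + ["sigma_intercept", "phi"])

    warmup = config.n_iter // 2
    kept = config.n_iter - warmup
    all_draws = {nm: np.empty((config.n_chains, kept)) for nm in names}
    b_draws = np.empty((config.n_chains, kept, G))

    for chain in range(config.n_chains):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed & 0x7FFFFFFF, chain]))
        # state: mu0, beta (P,), b (G,) group intercepts, lsig, lphi
        mu0 = 0.0
        beta = np.zeros(P)
        b = np.zeros(G)
        lsig = np.log(0.5)
        lphi = np.log(10.0)
        s_beta = np.full(P, 0.02)
        s_shift = np.full(P, 0.05)
        s_b, s_lsig, s_lphi = 0.1, 0.2, 0.2
        xbar = X.mean(axis=0)
        acc = {"beta": np.zeros(P), "shift": np.zeros(P), "b": 0.0,
               "lsig": 0, "lphi": 0}
        tries = {"beta": 0, "b": 0, "lsig": 0, "lphi": 0}

        def group_ll(b_vec, beta_vec, phi):
            eta = b_vec[g] + X @ beta_vec
            return _data_loglik_by_group(y, g, G, eta, phi)

        gll = group_ll(b, beta, np.exp(lphi))

        for it in range(config.n_iter):
            phi = np.exp(lphi)
            sig = np.exp(lsig)

            # --- mu0: exact conjugate-normal conditional given b, sigma
            # (a random walk cannot traverse the mu0 <-> intercepts
            # translation direction at a useful rate)
            prec = G / sig ** 2 + 1.0 / _PRIOR_SD_FIXED ** 2
            mu0 = (b.sum() / sig ** 2) / prec + rng.normal(0, 1 / np.sqrt(prec))

            # --- slope block: componentwise adaptive RW (posterior scales
            # differ by orders of magnitude across covariates)
            tries["beta"] += 1
            for p in range(P):
                prop = beta.copy()
                prop[p] = beta[p] + rng.normal(0, s_beta[p])
                gll_new = group_ll(b, prop, phi)
                dlp = (gll_new.sum() - gll.sum()
                       - 0.5 * (prop[p] ** 2 - beta[p] ** 2)
                       / _PRIOR_SD_FIXED ** 2)
                if np.log(rng.uniform()) < dlp:
                    beta, gll = prop, gll_new
                    acc["beta"][p] += 1

            # --- recentring shear: slope p and all group intercepts move
            # together along their near-degenerate direction
            # (beta_p + delta, b - delta * xbar_p); Jacobian 1
            for p in range(P):
                delta = rng.normal(0, s_shift[p])
                prop_beta = beta.copy()
                prop_beta[p] = beta[p] + delta
                prop_b = b - delta * xbar[p]
                gll_new = group_ll(prop_b, prop_beta, phi)
                dlp = (gll_new.sum() - gll.sum()
                       - 0.5 * (prop_beta[p] ** 2 - beta[p] ** 2)
                       / _PRIOR_SD_FIXED ** 2
                       - 0.5 * np.sum((prop_b - mu0) ** 2
                                      - (b - mu0) ** 2) / sig ** 2)
                if np.log(rng.uniform()) < dlp:
                    beta, b, gll = prop_beta, prop_b, gll_new
                    acc["shift"][p] += 1

            # --- group intercepts, elementwise (vectorised accept/reject)
            b_prop = b + rng.normal(0, s_b, G)
            gll_prop = group_ll(b_prop, beta, phi)
            dlp = (gll_prop - gll
                   - 0.5 * ((b_prop - mu0) ** 2 - (b - mu0) ** 2) / sig ** 2)
            accept = np.log(rng.uniform(size=G)) < dlp
            b = np.where(accept, b_prop, b)
            gll = np.where(accept, gll_prop, gll)
            tries["b"] += 1
            acc["b"] += accept.mean()

            # --- log sigma (prior-only likelihood for b)
            lsig_prop = lsig + rng.normal(0, s_lsig)
            def b_prior(ls):
                s = np.exp(ls)
                return (np.sum(-0.5 * (b - mu0) ** 2 / s ** 2 - ls)
                        + _log_half_cauchy(s, _HC_SCALE) + ls)  # + Jacobian
            tries["lsig"] += 1
            if np.log(rng.uniform()) < b_prior(lsig_prop) - b_prior(lsig):
                lsig = lsig_prop
                acc["lsig"] += 1

            # --- log phi
            lphi_prop = lphi + rng.normal(0, s_lphi)
            gll_prop = group_ll(b, beta, np.exp(lphi_prop))
            lp_old = (gll.sum() + _log_half_cauchy(np.exp(lphi), _HC_SCALE)
                      + lphi)
            lp_new = (gll_prop.sum()
                      + _log_half_cauchy(np.exp(lphi_prop), _HC_SCALE)
                      + lphi_prop)
            tries["lphi"] += 1
            if np.log(rng.uniform()) < lp_new - lp_old:
                lphi, gll = lphi_prop, gll_prop
                acc["lphi"] += 1

            # --- adapt proposal scales during warm-up (target 0.3-0.45)
            if it < warmup and (it + 1) % 50 == 0:
                def tune(scale, rate):
                    if rate < 0.30:
                        return scale * 0.8
                    if rate > 0.45:
                        return scale * 1.25
                    return scale
                for p in range(P):
                    s_beta[p] = tune(s_beta[p], acc["beta"][p] / tries["beta"])
                    s_shift[p] = tune(s_shift[p],
                                      acc["shift"][p] / tries["beta"])
                s_b = tune(s_b, acc["b"] / tries["b"])
                s_lsig = tune(s_lsig, acc["lsig"] / tries["lsig"])
                s_lphi = tune(s_lphi, acc["lphi"] / tries["lphi"])
                acc = {"beta": np.zeros(P), "shift": np.zeros(P), "b": 0.0,
                       "lsig": 0, "lphi": 0}
                tries = {"beta": 0, "b": 0, "lsig": 0, "lphi": 0}

            if it >= warmup:
                idx = it - warmup
                all_draws["intercept"][chain, idx] = mu0
                for p, nm in enumerate(data.covariate_names):
                    all_draws[nm][chain, idx] = beta[p]
                all_draws["sigma_intercept"][chain, idx] = np.exp(lsig)
                all_draws["phi"][chain, idx] = np.exp(lphi)
                b_draws[chain, idx] = b

    psrf_vals = {nm: psrf(all_draws[nm]) for nm in names}
    for gi in range(G):
        psrf_vals[f"b[{gi}]"] = psrf(b_draws[:, :, gi])
    warn = any(v > PSRF_THRESHOLD for v in psrf_vals.values())
    if warn:
        bad = {k: v for k, v in psrf_vals.items() if v > PSRF_THRESHOLD}
        logger.warning("PSRF above %.2f for: %s", PSRF_THRESHOLD, bad)

    pooled = {nm: all_draws[nm].reshape(-1) for nm in names}
    fixed = {"intercept": float(pooled["intercept"].mean())}
    for nm in data.covariate_names:
        fixed[nm] = float(pooled[nm].mean())
    post_sd = {nm: float(pooled[nm].std(ddof=1)) for nm in names}
    draws = None
    if config.keep_draws:
        draws = dict(pooled)
        draws["group_intercepts"] = b_draws.reshape(-1, G)
    return BetaRegressionFit(
        method="bayes", fixed=fixed,
        random_intercept_sd=float(pooled["sigma_intercept"].mean()),
        precision=float(pooled["phi"].mean()),
        group_intercepts=b_draws.reshape(-1, G).mean(axis=0),
        psrf=psrf_vals, draws=draws, posterior_sd=post_sd,
        convergence_warning=warn)


# ---------------------------------------------------------------------------
# maximum likelihood with adaptive Gauss-Hermite integration

def _group_marginal_loglik(yg, Xg, beta, mu0, sig, phi, gh_x, gh_w):
    """log integral over b of prod_s Beta(y; expit(b + x beta), phi) N(b)."""
    def f(bv):
        eta = bv + Xg @ beta
        return (np.sum(beta_loglik(_clipped_mu(eta), phi, yg))
                - 0.5 * ((bv - mu0) / sig) ** 2 - np.log(sig))

    if sig < 1e-6:  # degenerate hierarchy: point mass at mu0
        eta = mu0 + Xg @ beta
        return float(np.sum(beta_loglik(_clipped_mu(eta), phi, yg)))

    res = minimize_scalar(lambda bv: -f(bv),
                          bounds=(mu0 - 8 * sig - 2, mu0 + 8 * sig + 2),
                          method="bounded", options={"xatol": 1e-8})
    bhat = res.x
    h = 1e-4 * max(sig, 1e-2)
    f2 = (f(bhat + h) - 2 * f(bhat) + f(bhat - h)) / h ** 2
    shat = 1.0 / np.sqrt(max(-f2, 1.0 / (25 * sig ** 2)))
    nodes = bhat + np.sqrt(2.0) * shat * gh_x
    fv = np.array([f(b) for b in nodes])
    return float(logsumexp(fv + gh_x ** 2 + np.log(gh_w))
                 + 0.5 * np.log(2.0) + np.log(shat))


def _fit_ml(data: BetaRegressionData, config: BetaRegConfig):
    y = data.proportions
    X = data.covariates
    g = data.group
    G = data.n_groups
    P = data.n_covariates
    gh_x, gh_w = np.polynomial.hermite.hermgauss(config.n_quadrature)
    ygs = [y[g == k] for k in range(G)]
    Xgs = [X[g == k] for k in range(G)]

    def negloglik(p):
        mu0 = p[0]
        beta = p[1:1 + P]
        sig = np.exp(p[1 + P])
        phi = np.exp(p[2 + P])
        try:
            ll = sum(_group_marginal_loglik(ygs[k], Xgs[k], beta, mu0, sig,
                                            phi, gh_x, gh_w)
                     for k in range(G))
        except (FloatingPointError, InvalidInputError):
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    # moment-style start: logit of mean proportion
    ybar = float(np.mean(np.log(y / (1 - y))))
    p0 = np.concatenate([[ybar], np.zeros(P), [np.log(0.3)], [np.log(10.0)]])
    res = minimize(negloglik, p0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 8000,
                            "maxfev": 12000, "adaptive": True})
    p = res.x
    mu0, beta = p[0], p[1:1 + P]
    sig, phi = float(np.exp(p[1 + P])), float(np.exp(p[2 + P]))
    # empirical-Bayes group intercepts at the ML solution
    b_hat = np.empty(G)
    for k in range(G):
        def negpost(bv, k=k):
            eta = bv + Xgs[k] @ beta
            return -(np.sum(beta_loglik(_clipped_mu(eta), phi, ygs[k]))
                     - 0.5 * ((bv - mu0) / max(sig, 1e-6)) ** 2)
        b_hat[k] = minimize_scalar(negpost,
                                   bounds=(mu0 - 10, mu0 + 10),
                                   method="bounded").x
    fixed = {"intercept": float(mu0)}
    for i, nm in enumerate(data.covariate_names):
        fixed[nm] = float(beta[i])
    return BetaRegressionFit(method="ml", fixed=fixed,
                             random_intercept_sd=sig, precision=phi,
                             group_intercepts=b_hat, loglik=float(-res.fun),
                             converged=bool(res.success))
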