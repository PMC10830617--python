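"""Step 1 of the weighting procedure: screen-time mixture decomposition.

Log per-item screen times within one group-by-scale cell are modelled as a
C-component Gaussian mixture.  The number of components is chosen by BIC over
C = 1..max_components.  If the selected solution has at least two components,
the component with the lowest mean is labelled the careless/insufficient-effort
(C/IER) component; each respondent's posterior probability of belonging to it
yields an attentiveness weight w = 1 - posterior that later multiplies the
respondent's (pseudo-)likelihood contribution.

The EM implementation maximises the weight-multiplied log-likelihood
``sum_i w_i log f(x_i)`` with per-observation survey weights, which
``sklearn.mixture`` does not support; everything here is plain numpy/scipy.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exceptions import InsufficientDataError, InvalidInputError

logger = logging.getLogger(__name__)

#: minimum observations per mixture component before a fit is attempted
MIN_PER_COMPONENT = 10
#: minimum observations per group-by-scale cell for decomposition with C >= 2
MIN_CELL_SIZE = 50
#: lower bound on component variances (guards against degenerate spikes)
VAR_FLOOR = 1e-4

_LOG_2PI = np.log(2.0 * np.pi)


def log_geometric_time(time_seconds, n_items):
    """Natural log of the per-item geometric mean screen time, ln(t) / J.

    ``t^(1/J)`` is the geometric mean time per item for a screen showing
    J items for ``t`` seconds; its log is ``ln(t)/J``.

    Parameters
    ----------
    time_seconds : float or array-like
        Total time spent on the screen, in seconds.  Must be positive.
    n_items : int or array-like
        Number of items presented on the screen.  Must be >= 1.
    """
    t = np.asarray(time_seconds, dtype=float)
    j = np.asarray(n_items, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise InvalidInputError("time_seconds must be positive and finite")
    if np.any(~np.isfinite(j)) or np.any(j < 1):
        raise InvalidInputError("n_items must be >= 1")
    out = np.log(t) / j
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass
class MixtureFit:
    """A fitted C-component Gaussian mixture on log times."""

    n_components: int
    means: np.ndarray
    sds: np.ndarray
    proportions: np.ndarray
    loglik: float
    bic: float
    converged: bool
    n_obs: int
    seed: int
    loglik_path: np.ndarray = dataclasses.field(default=None, repr=False)

    def __post_init__(self):
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        self.sds = np.atleast_1d(np.asarray(self.sds, dtype=float))
        self.proportions = np.atleast_1d(np.asarray(self.proportions, dtype=float))
        if not (len(self.means) == len(self.sds) == len(self.proportions)
                == self.n_components):
            raise InvalidInputError("parameter vectors must have length C")
        if abs(self.proportions.sum() - 1.0) > 1e-8:
            raise InvalidInputError("mixture proportions must sum to 1")

    def to_dict(self) -> dict:
        return {
            "n_components": int(self.n_components),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "proportions": self.proportions.tolist(),
            "loglik": float(self.loglik),
            "bic": float(self.bic),
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "seed": int(self.seed),
        }


@dataclasses.dataclass
class CierDecomposition:
    """C/IER labelling of a mixture fit plus per-respondent weights."""

    fit: MixtureFit
    cier_component: int | None
    cier_proportion: float
    posteriors: np.ndarray
    attentiveness_weights: np.ndarray
    mean_cier_time_per_item: float
    #: weighted mean posterior, the empirical-share alternative to the
    #: mixture proportion (reported alongside it)
    posterior_mean_proportion: float = np.nan


def _component_logpdf(x, means, sds):
    """(n, C) matrix of component normal log densities."""
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return -0.5 * z * z - np.log(sds)[None, :] - 0.5 * _LOG_2PI


def _weighted_quantile(x_sorted, w_sorted, q):
    """Inverse-CDF weighted quantile; equals the replicated-sample quantile
    for integer weights (used so that weighting === replication in the
    k-means initialisation)."""
    cw = np.cumsum(w_sorted)
    target = np.asarray(q) * cw[-1]
    idx = np.searchsorted(cw, target, side="left")
    idx = np.clip(idx, 0, len(x_sorted) - 1)
    return x_sorted[idx]


def _kmeans_init(x, w, n_components, rng, jitter):
    """Weighted 1-D Lloyd's algorithm from quantile-spread seeds."""
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    q = (np.arange(n_components) + 0.5) / n_components
    centers = _weighted_quantile(xs, ws, q).astype(float)
    if jitter:
        sd = np.sqrt(np.average((x - np.average(x, weights=w)) ** 2, weights=w))
        centers = centers + rng.normal(0.0, 0.1 * max(sd, 1e-8), size=n_components)
    centers = np.sort(centers)
    for _ in range(10):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        for c in range(n_components):
            m = assign == c
            if np.any(m):
                centers[c] = np.average(x[m], weights=w[m])
            else:  # reseed an empty cluster at the worst-fit point
                far = np.argmax(np.abs(x - centers[assign]))
                centers[c] = x[far]
        centers = np.sort(centers)
    assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    means = np.empty(n_components)
    sds = np.empty(n_components)
    props = np.empty(n_components)
    gvar = max(np.average((x - np.average(x, weights=w)) ** 2, weights=w), VAR_FLOOR)
    for c in range(n_components):
        m = assign == c
        wc = w[m].sum()
        props[c] = wc / w.sum()
        means[c] = np.average(x[m], weights=w[m]) if np.any(m) else centers[c]
        if np.any(m) and wc > 0:
            var = np.average((x[m] - means[c]) ** 2, weights=w[m])
        else:
            var = gvar
        sds[c] = np.sqrt(max(var, VAR_FLOOR, 0.05 * gvar))
    props = np.maximum(props, 1e-3)
    props /= props.sum()
    return means, sds, props


def _lse_rows(logcomp):
    m = logcomp.max(axis=1)
    return m + np.log(np.exp(logcomp - m[:, None]).sum(axis=1))


def _tail_init(x, w, n_components):
    """Initial parameters with a small component in the low tail."""
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    sd = np.sqrt(max(np.average((x - np.average(x, weights=w)) ** 2,
                                weights=w), VAR_FLOOR))
    means = np.empty(n_components)
    means[0] = _weighted_quantile(xs, ws, 0.02)
    if n_components > 1:
        q = 0.10 + 0.88 * (np.arange(n_components - 1) + 0.5) / (n_components - 1)
        means[1:] = _weighted_quantile(xs, ws, q)
    sds = np.full(n_components, max(sd / max(n_components - 1, 1), 0.05 * sd))
    props = np.full(n_components, 0.95 / max(n_components - 1, 1))
    props[0] = 0.05
    if n_components == 1:
        props[0] = 1.0
    props /= props.sum()
    return means, np.maximum(sds, np.sqrt(VAR_FLOOR)), props


def _em(x, w, means, sds, props, max_iter, tol):
    """Weighted EM; returns (means, sds, props, loglik, converged, path)."""
    path = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        logcomp = np.log(props)[None, :] + _component_logpdf(x, means, sds)
        lse = _lse_rows(logcomp)
        ll = float(np.dot(w, lse))
        path.append(ll)
        if prev > -np.inf and ll + 1e-10 * (1.0 + abs(ll)) < prev:
            logger.warning("EM log-likelihood decreased by %g", prev - ll)
        if prev > -np.inf and abs(ll - prev) <= tol * (1.0 + abs(ll)):
            converged = True
            break
        prev = ll
        r = np.exp(logcomp - lse[:, None])  # responsibilities
        wr = w[:, None] * r
        nk = wr.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        props = nk / w.sum()
        means = (wr * x[:, None]).sum(axis=0) / nk
        var = (wr * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, VAR_FLOOR))
    logcomp = np.log(props)[None, :] + _component_logpdf(x, means, sds)
    ll = float(np.dot(w, _lse_rows(logcomp)))
    path.append(ll)
    return means, sds, props, ll, converged, np.asarray(path)


def fit_weighted_gmm(x, weights=None, n_components=1, seed=0, *,
                     max_iter=500, tol=1e-8, n_init=5) -> MixtureFit:
    """Fit a C-component Gaussian mixture by weighted EM.

    Maximises ``sum_i w_i log f(x_i)`` where f is the mixture density, so an
    integer weight is exactly equivalent to replicating the observation.
    Initialisation is weighted k-means from quantile-spread seeds with
    ``n_init`` jittered restarts; the best final log-likelihood is kept.
    Deterministic given ``seed``.

    BIC = -2 loglik + (3C - 1) ln(n_obs); the effective sample size is the
    number of observations (weights are expected to be normalised to mean 1
    per cell, see :func:`decompose_screen_times`).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float).ravel()
    if w.shape != x.shape or np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise InvalidInputError("weights must be positive, finite, same length as x")
    if np.any(~np.isfinite(x)):
        raise InvalidInputError("x must be finite")
    if n_components < 1:
        raise InvalidInputError("n_components must be >= 1")
    if n < MIN_PER_COMPONENT * n_components:
        raise InsufficientDataError(
            f"need >= {MIN_PER_COMPONENT * n_components} observations for "
            f"C={n_components}, got {n}")

    p_free = 3 * n_components - 1

    if n_components == 1:  # closed-form weighted MLE
        mu = np.average(x, weights=w)
        var = max(np.average((x - mu) ** 2, weights=w), VAR_FLOOR)
        sd = np.sqrt(var)
        ll = float(np.dot(w, -0.5 * ((x - mu) / sd) ** 2 - np.log(sd)
                          - 0.5 * _LOG_2PI))
        return MixtureFit(1, [mu], [sd], [1.0], ll,
                          -2.0 * ll + p_free * np.log(n), True, n, seed,
                          loglik_path=np.asarray([ll]))

    rng = np.random.default_rng(seed)
    # short burn-in for every restart, then polish only the best one: the
    # restarts exist to escape poor initialisations, which reveal themselves
    # within a few dozen iterations
    burn = min(50, max_iter)
    cands = []
    for restart in range(n_init):
        if restart == 1:
            # low-tail start: a small lowest component seeded in the left
            # tail, where a minority C/IER class would sit -- plain
            # quantile-spread k-means tends to miss small-proportion
            # low-mean components
            means, sds, props = _tail_init(x, w, n_components)
        else:
            means, sds, props = _kmeans_init(x, w, n_components, rng,
                                             jitter=restart > 1)
        cands.append(_em(x, w, means, sds, props, burn, tol))
    if n <= 200:
        # small samples: the ML optimum is often a narrow component sitting
        # on a tight cluster of points; enumerate spike starts at (a subset
        # of) data points, with the remaining components spread by quantiles
        sd_all = np.sqrt(max(np.average((x - np.average(x, weights=w)) ** 2,
                                        weights=w), VAR_FLOOR))
        base_means, base_sds, base_props = _kmeans_init(
            x, w, max(n_components - 1, 1), np.random.default_rng(seed),
            jitter=False)
        for xi in np.sort(x)[:: max(1, n // 60)]:
            means = np.concatenate([[xi], base_means[: n_components - 1]])
            sds = np.concatenate([[max(0.05 * sd_all, np.sqrt(VAR_FLOOR))],
                                  np.full(n_components - 1, sd_all)])
            props = np.concatenate([[0.1],
                                    np.full(n_components - 1,
                                            0.9 / max(n_components - 1, 1))])
            props /= props.sum()
            cands.append(_em(x, w, means, sds, props, burn, tol))
    best = max(range(len(cands)), key=lambda i: cands[i][3])
    means, sds, props, ll, conv, path = cands[best]
    if not conv:
        means, sds, props, ll, conv, path2 = _em(x, w, means, sds, props,
                                                 max_iter - burn, tol)
        path = np.concatenate([path[:-1], path2])
    order = np.argsort(means, kind="stable")
    fit = MixtureFit(n_components, means[order], sds[order], props[order],
                     ll, -2.0 * ll + p_free * np.log(n), conv, n, seed,
                     loglik_path=path)
    if not conv:
        # routine for large C during BIC scans; the flag carries the state
        logger.info("EM did not converge in %d iterations (C=%d)",
                    max_iter, n_components)
    return fit


def fit_components_range(x, weights=None, max_components=9, seed=0,
                         **em_kwargs) -> list[MixtureFit]:
    """Fit C = 1..max_components, skipping C beyond the data-support rule."""
    x = np.asarray(x, dtype=float).ravel()
    if max_components < 1:
        raise InvalidInputError("max_components must be >= 1")
    c_max = min(max_components, max(1, x.size // MIN_PER_COMPONENT))
    fits = []
    for c in range(1, c_max + 1):
        fits.append(fit_weighted_gmm(x, weights, n_components=c,
                                     seed=seed + c, **em_kwargs))
    return fits


def select_components(x, weights=None, max_components=9, seed=0,
                      **em_kwargs) -> MixtureFit:
    """Return the fit with minimal BIC among C = 1..max_components.

    Ties in BIC go to the smaller C.
    """
    fits = fit_components_range(x, weights, max_components, seed, **em_kwargs)
    bics = np.asarray([f.bic for f in fits])
    return fits[int(np.argmin(bics))]


def posterior_cier(fit: MixtureFit, cier_component: int, x_value):
    """Bayes posterior p(z = c_CIER | x), computed in log space.

    ``cier_component`` is a 0-based component index.
    """
    if not 0 <= cier_component < fit.n_components:
        raise InvalidInputError("cier_component out of range")
    x = np.atleast_1d(np.asarray(x_value, dtype=float))
    logcomp = (np.log(fit.proportions)[None, :]
               + _component_logpdf(x, fit.means, fit.sds))
    post = np.exp(logcomp[:, cier_component] - logsumexp(logcomp, axis=1))
    post = np.clip(post, 0.0, 1.0)
    return float(post[0]) if np.isscalar(x_value) or np.ndim(x_value) == 0 else post


def attentiveness_weights(posteriors):
    """Elementwise complement w = 1 - posterior."""
    p = np.asarray(posteriors, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("posteriors must lie in [0, 1]")
    out = 1.0 - p
    return float(out) if out.ndim == 0 else out


def label_cier(fit: MixtureFit, x, weights=None) -> CierDecomposition:
    """Label the lowest-mean component as C/IER and derive weights.

    Single-component solutions are read as "no C/IER detected": all
    posteriors 0, all attentiveness weights 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    if fit.n_components == 1:
        post = np.zeros(x.size)
        return CierDecomposition(fit, None, 0.0, post, np.ones(x.size),
                                 float(np.exp(fit.means[0])),
                                 posterior_mean_proportion=0.0)
    means = fit.means
    c = int(np.argmin(means))
    if np.sum(np.isclose(means, means[c], rtol=0, atol=1e-12)) > 1:
        logger.warning("tie in component means; lowest index %d labelled C/IER", c)
    post = posterior_cier(fit, c, x)
    post = np.atleast_1d(post)
    if weights is None:
        pmean = float(np.mean(post)) if post.size else np.nan
    else:
        pmean = float(np.average(post, weights=np.asarray(weights, float)))
    return CierDecomposition(fit, c, float(fit.proportions[c]), post,
                             attentiveness_weights(post),
                             float(np.exp(means[c])),
                             posterior_mean_proportion=pmean)


def cell_seed(root_seed: int, group_id, scale_id) -> int:
    """Deterministic, ordering-independent per-cell seed below 2**31."""
    h = zlib.crc32(f"{group_id}|{scale_id}".encode("utf-8"))
    mixed = np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, h])
    return int(mixed.generate_state(1)[0] & 0x7FFFFFFF)


def decompose_screen_times(records: pd.DataFrame, *, max_components: int = 9,
                           transform: str = "per-item", seed: int = 0,
                           **em_kwargs):
    """Run the mixture decomposition per group-by-scale cell.

    Parameters
    ----------
    records : DataFrame
        Long format with columns ``respondent_id, group_id, scale_id,
        time_seconds, n_items, sampling_weight``.
    transform : {"per-item", "total"}
        ``"per-item"`` uses ln(t)/J (log geometric mean time per item, the
        default); ``"total"`` uses ln(t).
    seed : int
        Root seed; each cell gets a deterministic sub-seed independent of
        row order.

    Returns
    -------
    weights : DataFrame
        ``respondent_id, group_id, scale_id, posterior_cier,
        attentiveness_weight, not_assessed``.  Rows with missing or
        non-positive time get weight 1 and ``not_assessed = True``.
    summaries : dict
        ``(group_id, scale_id) -> {"selected": MixtureFit dict,
        "decomposition": {...}, "bic_path": [...]}``.
    """
    if transform not in ("per-item", "total"):
        raise InvalidInputError("transform must be 'per-item' or 'total'")
    required = ["respondent_id", "group_id", "scale_id", "time_seconds",
                "n_items", "sampling_weight"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise InvalidInputError(f"records missing columns: {missing}")

    out_rows = []
    summaries = {}
    for (g, s), cell in records.groupby(["group_id", "scale_id"], sort=True):
        t = pd.to_numeric(cell["time_seconds"], errors="coerce").to_numpy(float)
        j = cell["n_items"].to_numpy(float)
        v = cell["sampling_weight"].to_numpy(float)
        ok = np.isfinite(t) & (t > 0)
        post = np.zeros(len(cell))
        watt = np.ones(len(cell))
        cell_summary = None
        if ok.sum() >= MIN_CELL_SIZE:
            if transform == "per-item":
                xs = log_geometric_time(t[ok], j[ok])
            else:
                xs = np.log(t[ok])
            vs = v[ok] / v[ok].mean()  # normalise weights to mean 1 per cell
            cseed = cell_seed(seed, g, s)
            fits = fit_components_range(xs, vs, max_components, cseed,
                                        **em_kwargs)
            bics = np.asarray([f.bic for f in fits])
            best = fits[int(np.argmin(bics))]
            dec = label_cier(best, xs, weights=vs)
            post[ok] = dec.posteriors
            watt[ok] = dec.attentiveness_weights
            cell_summary = {
                "selected": best.to_dict(),
                "decomposition": {
                    "cier_component": dec.cier_component,
                    "cier_proportion": dec.cier_proportion,
                    "posterior_mean_proportion": dec.posterior_mean_proportion,
                    "mean_cier_time_per_item": dec.mean_cier_time_per_item,
                },
                "bic_path": [f.bic for f in fits],
            }
        else:
            logger.warning("cell (%s, %s): only %d usable times (< %d); "
                           "treated as single-component, all weights 1",
                           g, s, int(ok.sum()), MIN_CELL_SIZE)
            cell_summary = {"selected": None, "decomposition": None,
                            "bic_path": [], "note": "insufficient data"}
        summaries[(g, s)] = cell_summary
        out_rows.append(pd.DataFrame({
            "respondent_id": cell["respondent_id"].to_numpy(),
            "group_id": g, "scale_id": s,
            "posterior_cier": post,
            "attentiveness_weight": watt,
            "not_assessed": ~ok,
        }))
    weights = pd.concat(out_rows, ignore_index=True)
    return weights, summaries
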