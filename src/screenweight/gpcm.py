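"""Step 2: weighted marginal-maximum-likelihood multi-group GPCM.

The generalized partial credit model gives the probability of choosing
category k on item j as

    p(y = k | theta) = exp(sum_{l<=k} a_j (theta - b_jl))
                       / sum_r exp(sum_{l<=r} a_j (theta - b_jl)),

with the l = 0 term identically zero.  Item parameters are shared across
groups; the latent trait is N(mu_g, sigma_g^2) per group, with group 1 fixed
to N(0, 1) for identification.  Estimation is EM over a fixed rectangular
quadrature grid, with each case's log-likelihood contribution multiplied by a
non-negative case weight (attentiveness weight x sampling weight), i.e. a
pseudo-likelihood in the complex-survey sense.

The quadrature grid is fixed in the reference-group metric for every group,
so each EM cycle (E-step, per-item Newton-type M-step with
keep-old-if-worse, direct 2-parameter maximisation for free group moments)
is exactly monotone in the discretised marginal log-likelihood.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

MISSING = -1  # missing-response code in integer response matrices


@dataclasses.dataclass
class GpcmItemParams:
    discrimination: float
    step_difficulties: np.ndarray

    def __post_init__(self):
        self.step_difficulties = np.atleast_1d(
            np.asarray(self.step_difficulties, dtype=float))
        if not np.isfinite(self.discrimination):
            raise InvalidInputError("discrimination must be finite")
        if np.any(~np.isfinite(self.step_difficulties)):
            raise InvalidInputError("step difficulties must be finite")

    @property
    def n_categories(self) -> int:
        return len(self.step_difficulties) + 1


@dataclasses.dataclass
class GroupDistribution:
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise InvalidInputError("group sd must be positive")


@dataclasses.dataclass
class ResponseMatrix:
    """N x J integer responses (MISSING = -1) with group membership."""

    responses: np.ndarray
    group: np.ndarray
    max_category: np.ndarray = None

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=int)
        self.group = np.asarray(self.group, dtype=int)
        if self.responses.ndim != 2:
            raise InvalidInputError("responses must be N x J")
        if self.group.shape != (self.responses.shape[0],):
            raise InvalidInputError("group must have length N")
        if self.max_category is None:
            obs = np.where(self.responses == MISSING, 0, self.responses)
            self.max_category = obs.max(axis=0)
        self.max_category = np.asarray(self.max_category, dtype=int)
        obs = self.responses[self.responses != MISSING]
        if obs.size and obs.min() < 0:
            raise InvalidInputError("responses must be >= 0 or MISSING")
        for j in range(self.responses.shape[1]):
            col = self.responses[:, j]
            vals = np.unique(col[col != MISSING])
            if vals.size < 2:
                raise InvalidInputError(
                    f"item {j} has fewer than 2 observed categories")
            if vals.max() > self.max_category[j]:
                raise InvalidInputError(f"item {j} exceeds max_category")

    @property
    def n_respondents(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_groups(self) -> int:
        return int(self.group.max()) + 1

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, item_columns, group_column="group_id"):
        """Build from a wide table; NaN cells become MISSING.

        Group labels are mapped to 0-based indices in sorted label order
        (the first sorted label becomes the reference group).
        """
        labels = np.sort(df[group_column].unique())
        gmap = {lab: i for i, lab in enumerate(labels)}
        group = df[group_column].map(gmap).to_numpy(int)
        resp = df[item_columns].to_numpy(float)
        out = np.where(np.isfinite(resp), resp, MISSING).astype(int)
        rm = cls(out, group)
        rm.group_labels = labels
        return rm


@dataclasses.dataclass
class GpcmFit:
    items: list[GpcmItemParams]
    groups: list[GroupDistribution]
    loglik: float
    n_quadrature: int
    converged: bool
    n_cycles: int = 0
    loglik_path: np.ndarray = dataclasses.field(default=None, repr=False)
    category_maps: list = dataclasses.field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "items": [{"discrimination": it.discrimination,
                       "step_difficulties": it.step_difficulties.tolist()}
                      for it in self.items],
            "groups": [{"mean": g.mean, "sd": g.sd} for g in self.groups],
            "loglik": float(self.loglik),
            "n_quadrature": int(self.n_quadrature),
            "converged": bool(self.converged),
            "n_cycles": int(self.n_cycles),
        }


def gpcm_category_probs(item: GpcmItemParams, theta):
    """Category probabilities p_0..p_K at theta (vectorised over theta).

    Computed with max-subtraction in log space; rows sum to 1.
    """
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    a, b = item.discrimination, item.step_difficulties
    k = np.arange(item.n_categories)
    # cumulative sums s_k(theta) = a * (k*theta - sum_{l<=k} b_l), s_0 = 0
    bcum = np.concatenate([[0.0], np.cumsum(b)])
    s = a * (k[None, :] * th[:, None] - bcum[None, :])
    s -= s.max(axis=1, keepdims=True)
    p = np.exp(s)
    p /= p.sum(axis=1, keepdims=True)
    return p[0] if np.ndim(theta) == 0 else p


def _log_prob_table(items, nodes):
    """Per item: (K_j+1, Q) log category probabilities on the grid."""
    tables = []
    for it in items:
        p = gpcm_category_probs(it, nodes)  # (Q, K+1)
        tables.append(np.log(np.maximum(p.T, 1e-300)))
    return tables


def _group_log_weights(groups, nodes):
    """(G, Q) normalised discrete-normal log weights on the fixed grid."""
    out = []
    for g in groups:
        z = (nodes - g.mean) / g.sd
        lw = -0.5 * z * z - np.log(g.sd)
        out.append(lw - logsumexp(lw))
    return np.asarray(out)


def _case_log_marginals(items, groups, data: ResponseMatrix, nodes):
    """(N,) log marginal likelihoods and (N, Q) log joint table."""
    tables = _log_prob_table(items, nodes)
    logL = np.zeros((data.n_respondents, len(nodes)))
    for j in range(data.n_items):
        y = data.responses[:, j]
        obs = y != MISSING
        logL[obs] += tables[j][y[obs], :]
    logA = _group_log_weights(groups, nodes)
    logjoint = logA[data.group] + logL
    return logsumexp(logjoint, axis=1), logjoint


def weighted_marginal_loglik(items, groups, data: ResponseMatrix,
                             weights=None, n_quadrature: int = 61) -> float:
    """Weighted marginal log-likelihood sum_i w_i log p(y_i | a, b, gamma).

    The trait integral uses ``n_quadrature`` (>= 21) rectangle nodes on
    [-6, 6] in the reference-group metric; missing responses are skipped in
    the within-person product.
    """
    if n_quadrature < 21:
        raise InvalidInputError("n_quadrature must be >= 21")
    w = _check_weights(weights, data.n_respondents)
    nodes = np.linspace(-6.0, 6.0, n_quadrature)
    li, _ = _case_log_marginals(items, groups, data, nodes)
    return float(np.dot(w, li))


def _check_weights(weights, n):
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float).ravel()
    if w.shape != (n,):
        raise InvalidInputError("weights must have length N")
    if np.any(~np.isfinite(w)) or np.any(w < 0):
        raise InvalidInputError("weights must be finite and non-negative")
    if w.sum() <= 0:
        raise InvalidInputError("no effective sample: all case weights are zero")
    return w


def _collapse_unobserved(data: ResponseMatrix, w):
    """Remap categories never observed with positive weight onto neighbours."""
    resp = data.responses.copy()
    maps = []
    for j in range(data.n_items):
        y = resp[:, j]
        kmax = data.max_category[j]
        seen = [k for k in range(kmax + 1)
                if np.any((y == k) & (w > 0))]
        if len(seen) == kmax + 1:
            maps.append(None)
            continue
        remap = np.searchsorted(seen, np.arange(kmax + 1))
        remap = np.clip(remap, 0, len(seen) - 1)
        logger.warning("item %d: categories %s unobserved; collapsed onto "
                       "adjacent categories", j,
                       sorted(set(range(kmax + 1)) - set(seen)))
        obs = y != MISSING
        y[obs] = remap[y[obs]]
        maps.append({k: int(remap[k]) for k in range(kmax + 1)})
    new = ResponseMatrix(resp, data.group)
    return new, maps


def _item_mstep(item: GpcmItemParams, counts, nodes):
    """Maximise sum_{k,q} counts[k,q] log p_k(theta_q) over (a, b)."""
    K = item.n_categories - 1
    Rq = counts.sum(axis=0)
    kvec = np.arange(K + 1)

    def unpack(p):
        return p[0], p[1:]

    def negloglik(p):
        a, b = unpack(p)
        bcum = np.concatenate([[0.0], np.cumsum(b)])
        s = a * (kvec[:, None] * nodes[None, :] - bcum[:, None])  # (K+1, Q)
        lse = logsumexp(s, axis=0)
        val = np.sum(counts * s) - np.dot(Rq, lse)
        pk = np.exp(s - lse[None, :])
        d = counts - Rq[None, :] * pk  # (K+1, Q)
        u = kvec[:, None] * nodes[None, :] - bcum[:, None]
        ga = np.sum(d * u)
        gb = np.array([-a * d[m:, :].sum() for m in range(1, K + 1)])
        return -val, -np.concatenate([[ga], gb])

    p0 = np.concatenate([[item.discrimination], item.step_difficulties])
    f0 = negloglik(p0)[0]
    res = minimize(negloglik, p0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 50})
    if res.fun < f0:  # keep-old-if-worse guarantees monotone EM
        return GpcmItemParams(float(res.x[0]), res.x[1:]), float(f0 - res.fun)
    return item, 0.0


def _group_mstep(group: GroupDistribution, nq, nodes):
    """Maximise sum_q nq[q] log A_q(mu, sigma) for one free group."""
    tot = nq.sum()
    if tot <= 0:
        return group
    mu0 = float(np.dot(nq, nodes) / tot)
    var0 = float(np.dot(nq, (nodes - mu0) ** 2) / tot)
    sd0 = np.sqrt(max(var0, 1e-4))

    def neg(p):
        mu, lsd = p
        sd = np.exp(lsd)
        z = (nodes - mu) / sd
        lw = -0.5 * z * z - lsd
        lw -= logsumexp(lw)
        return -float(np.dot(nq, lw))

    best = min(
        (minimize(neg, np.array(s), method="Nelder-Mead",
                  options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 120})
         for s in ([group.mean, np.log(group.sd)], [mu0, np.log(sd0)])),
        key=lambda r: r.fun)
    cand = GroupDistribution(float(best.x[0]), float(np.exp(best.x[1])))
    if neg([group.mean, np.log(group.sd)]) < best.fun:
        return group
    return cand


@dataclasses.dataclass
class GpcmConfig:
    n_quadrature: int = 61
    max_cycles: int = 1000
    param_tol: float = 1e-5
    start_discrimination: float = 1.0


def fit_multigroup_gpcm(data: ResponseMatrix, weights=None,
                        config: GpcmConfig | None = None) -> GpcmFit:
    """Fit the weighted multi-group GPCM by EM.

    Group 1 (index 0) is fixed to N(0,1); remaining group means/SDs are free.
    Rows with all responses missing are dropped from estimation.  Convergence:
    max absolute parameter change < ``param_tol`` or ``max_cycles`` cycles.
    """
    config = config or GpcmConfig()
    w = _check_weights(weights, data.n_respondents)
    counts_per_group = np.bincount(data.group, minlength=data.n_groups)
    if np.any(counts_per_group == 0):
        raise InvalidInputError("every group must contain at least one case")

    all_missing = np.all(data.responses == MISSING, axis=1)
    if np.any(all_missing):
        logger.info("dropping %d all-missing rows from estimation",
                    int(all_missing.sum()))
        keep = ~all_missing
        data = ResponseMatrix(data.responses[keep], data.group[keep],
                              data.max_category)
        w = w[keep]
        if w.sum() <= 0:
            raise InvalidInputError("no effective sample after dropping "
                                    "all-missing rows")

    data, cat_maps = _collapse_unobserved(data, w)
    # estimate with mean-1 weights so solver tolerances see a scale-free
    # objective; report the loglik on the caller's weight scale
    w_scale = float(w.mean())
    w = w / w_scale
    nodes = np.linspace(-6.0, 6.0, config.n_quadrature)

    items = [GpcmItemParams(config.start_discrimination,
                            np.linspace(-1.0, 1.0, k) if k > 1 else [0.0])
             for k in data.max_category]
    groups = [GroupDistribution(0.0, 1.0) for _ in range(data.n_groups)]

    onehots = []
    for j in range(data.n_items):
        y = data.responses[:, j]
        K = data.max_category[j]
        oh = np.zeros((K + 1, data.n_respondents))
        obs = y != MISSING
        oh[y[obs], np.nonzero(obs)[0]] = 1.0
        onehots.append(oh)

    path = []
    converged = False
    n_cycles = 0
    for cycle in range(config.max_cycles):
        n_cycles = cycle + 1
        li, logjoint = _case_log_marginals(items, groups, data, nodes)
        ll = float(np.dot(w, li))
        path.append(ll)
        post = np.exp(logjoint - li[:, None]) * w[:, None]  # (N, Q)

        old = _flatten(items, groups)
        new_items = []
        for j in range(data.n_items):
            counts = onehots[j] @ post  # (K+1, Q)
            it, _ = _item_mstep(items[j], counts, nodes)
            new_items.append(it)
        items = new_items
        for g in range(1, data.n_groups):
            nq = post[data.group == g].sum(axis=0)
            groups[g] = _group_mstep(groups[g], nq, nodes)
        delta = np.max(np.abs(_flatten(items, groups) - old))
        if delta < config.param_tol:
            converged = True
            break
    li, _ = _case_log_marginals(items, groups, data, nodes)
    ll = float(np.dot(w, li)) * w_scale
    path.append(ll / w_scale)
    if not converged:
        logger.warning("GPCM EM stopped after %d cycles "
                       "(max parameter change still >= %g)",
                       config.max_cycles, config.param_tol)
    return GpcmFit(items, groups, ll, config.n_quadrature, converged,
                   n_cycles, np.asarray(path) * w_scale, cat_maps)


def _flatten(items, groups):
    parts = []
    for it in items:
        parts.append([it.discrimination])
        parts.append(it.step_difficulties)
    for g in groups[1:]:
        parts.append([g.mean, g.sd])
    return np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in parts])


def compare_fits(adjusted: GpcmFit, unadjusted: GpcmFit):
    """Group-level differences between an adjusted and an unadjusted fit.

    Both fits share the reference-group N(0,1) metric, so the primary
    "standardized" group mean/variance difference is simply the difference in
    that metric; a per-group-SD-scaled mean variant (mean / sd) is reported
    alongside.

    Returns
    -------
    table : DataFrame with one row per group.
    summary : dict with median absolute differences and middle-50% ranges
        across groups.
    """
    if len(adjusted.items) != len(unadjusted.items) or \
            len(adjusted.groups) != len(unadjusted.groups):
        raise InvalidInputError("fits have mismatched structures")
    rows = []
    for g, (ga, gu) in enumerate(zip(adjusted.groups, unadjusted.groups)):
        rows.append({
            "group": g,
            "mean_adjusted": ga.mean, "mean_unadjusted": gu.mean,
            "var_adjusted": ga.sd ** 2, "var_unadjusted": gu.sd ** 2,
            "mean_diff": ga.mean - gu.mean,
            "var_diff": ga.sd ** 2 - gu.sd ** 2,
            "scaled_mean_diff": ga.mean / ga.sd - gu.mean / gu.sd,
        })
    table = pd.DataFrame(rows)

    def med_iqr(v):
        av = np.abs(v.to_numpy(float))
        return (float(np.median(av)),
                [float(np.percentile(av, 25)), float(np.percentile(av, 75))])

    m_med, m_iqr = med_iqr(table["mean_diff"])
    v_med, v_iqr = med_iqr(table["var_diff"])
    s_med, s_iqr = med_iqr(table["scaled_mean_diff"])
    summary = {
        "median_abs_mean_diff": m_med, "iqr_abs_mean_diff": m_iqr,
        "median_abs_var_diff": v_med, "iqr_abs_var_diff": v_iqr,
        "median_abs_scaled_mean_diff": s_med,
        "iqr_abs_scaled_mean_diff": s_iqr,
    }
    return table, summary
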