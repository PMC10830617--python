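"""Validity-check statistics for the screen-time weighting procedure.

Threshold-based C/IER indicators (fixed per-item-time thresholds and the 30%
normative threshold), weighted correlations with omission counts,
point-biserial agreement between binary indicators and posterior C/IER
probabilities, and lagged rank-order consistency of posteriors across scale
positions.

Undefined statistics (zero variance, constant indicator, too few complete
pairs) are returned as NaN by explicit rule -- they never arise from silent
NaN arithmetic -- and the tidy-report writer records them as empty cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .gpcm import MISSING, ResponseMatrix

#: minimum number of pairwise-complete observations for a correlation
MIN_PAIRS = 3


def per_item_time(time_seconds, n_items):
    """Geometric mean time per item, t^(1/J), in seconds."""
    t = np.asarray(time_seconds, dtype=float)
    j = np.asarray(n_items, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise InvalidInputError("time_seconds must be positive and finite")
    return t ** (1.0 / j)


def fixed_threshold_indicator(time_seconds, n_items, threshold_seconds):
    """Flag 1 iff per-item time t^(1/J) is strictly below the threshold.

    The customary settings are 2 s and the more conservative 1 s per item.
    """
    if threshold_seconds <= 0:
        raise InvalidInputError("threshold_seconds must be positive")
    pit = per_item_time(time_seconds, n_items)
    out = (pit < threshold_seconds).astype(int)
    return int(out) if np.ndim(out) == 0 else out


def nt30_indicator(time_seconds, n_items, group_ids, fraction=0.30):
    """30% normative threshold: flag per-item times strictly below
    ``fraction`` x the unweighted group mean per-item time for the scale.

    All inputs belong to a single scale; the group mean is unweighted
    (sampling weights do not enter the normative threshold).
    """
    pit = np.atleast_1d(per_item_time(time_seconds, n_items))
    g = np.atleast_1d(np.asarray(group_ids))
    if g.shape != pit.shape:
        raise InvalidInputError("group_ids must align with times")
    if pit.size == 0:
        raise InvalidInputError("empty input")
    df = pd.Series(pit).groupby(pd.Series(g)).transform("mean").to_numpy()
    return (pit < fraction * df).astype(int)


def weighted_correlation(x, y, weights=None):
    """Weighted Pearson correlation with pairwise-complete filtering.

    Returns NaN (flagged undefined) when fewer than MIN_PAIRS complete pairs
    remain or either variable has zero weighted variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if y.shape != x.shape or w.shape != x.shape:
        raise InvalidInputError("x, y, weights must have equal length")
    if np.any(w < 0):
        raise InvalidInputError("weights must be non-negative")
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(w)
    x, y, w = x[ok], y[ok], w[ok]
    if x.size < MIN_PAIRS or w.sum() <= 0:
        return float("nan")
    mx = np.average(x, weights=w)
    my = np.average(y, weights=w)
    cov = np.average((x - mx) * (y - my), weights=w)
    vx = np.average((x - mx) ** 2, weights=w)
    vy = np.average((y - my) ** 2, weights=w)
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float(cov / np.sqrt(vx * vy))


def point_biserial(binary_indicator, values, weights=None):
    """Point-biserial correlation of a {0,1} indicator with a continuous
    vector (the Pearson correlation of the two).  Constant indicator -> NaN.
    """
    d = np.asarray(binary_indicator, dtype=float)
    if not np.all(np.isin(d[np.isfinite(d)], (0.0, 1.0))):
        raise InvalidInputError("indicator must be binary 0/1")
    return weighted_correlation(d, values, weights)


def omission_counts(responses):
    """Number of missing responses per respondent on one scale."""
    if isinstance(responses, ResponseMatrix):
        resp = responses.responses
    else:
        resp = np.asarray(responses)
        if resp.dtype.kind == "f":
            resp = np.where(np.isfinite(resp), resp, MISSING).astype(int)
    return (resp == MISSING).sum(axis=1)


def lagged_consistency(posterior_matrix, positions=None, max_lag: int = 15,
                       weights=None):
    """Rank-order consistency of C/IER posteriors across scale positions.

    For each lag l = 1..max_lag, averages the correlation between the
    posterior columns of every position pair (s, s + l); the average is a
    simple mean over available pairs, and undefined pair correlations are
    excluded (their count is reported).

    Parameters
    ----------
    posterior_matrix : (N, S) array
        Posterior C/IER probabilities, respondents x ordered scale slots.
    positions : sequence of int, optional
        Screen positions of the S columns (default 1..S).  Lags are taken in
        position units.

    Returns
    -------
    DataFrame with columns ``lag, mean_correlation, n_pairs, n_undefined``.
    """
    P = np.asarray(posterior_matrix, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise InvalidInputError("need a respondents x (>=2 scales) matrix")
    S = P.shape[1]
    pos = np.arange(1, S + 1) if positions is None else np.asarray(positions)
    if pos.shape != (S,):
        raise InvalidInputError("positions must have one entry per column")
    rows = []
    for lag in range(1, max_lag + 1):
        rs, undef = [], 0
        for s1 in range(S):
            for s2 in range(S):
                if pos[s2] - pos[s1] == lag:
                    r = weighted_correlation(P[:, s1], P[:, s2], weights)
                    if np.isnan(r):
                        undef += 1
                    else:
                        rs.append(r)
        rows.append({"lag": lag,
                     "mean_correlation": float(np.mean(rs)) if rs else float("nan"),
                     "n_pairs": len(rs), "n_undefined": undef})
    return pd.DataFrame(rows)


def validity_report(weights_df: pd.DataFrame, records: pd.DataFrame,
                    responses: dict, thresholds=(2.0, 1.0),
                    nt_fraction: float = 0.30) -> pd.DataFrame:
    """Tidy per-group-per-scale validity statistics.

    Combines the decomposition output (``weights_df`` from
    :func:`screenweight.timing.decompose_screen_times`), the screen records,
    and per-scale wide response tables into rows of
    ``group_id, scale_id, statistic, value, n``.

    Statistics: flag rates for each fixed threshold and NT30, the weighted
    correlation of posteriors with omission counts, and point-biserial
    correlations between each indicator and the posteriors.
    """
    merged = records.merge(
        weights_df[["respondent_id", "group_id", "scale_id", "posterior_cier"]],
        on=["respondent_id", "group_id", "scale_id"], how="inner")
    rows = []
    for (g, s), cell in merged.groupby(["group_id", "scale_id"], sort=True):
        t = pd.to_numeric(cell["time_seconds"], errors="coerce").to_numpy(float)
        ok = np.isfinite(t) & (t > 0)
        cell = cell[ok]
        if len(cell) == 0:
            continue
        t = t[ok]
        j = cell["n_items"].to_numpy(float)
        v = cell["sampling_weight"].to_numpy(float)
        post = cell["posterior_cier"].to_numpy(float)
        n = len(cell)
        inds = {f"flag_rate_{th:g}s":
                fixed_threshold_indicator(t, j, th) for th in thresholds}
        inds["flag_rate_nt30"] = nt30_indicator(
            t, j, np.zeros(n, dtype=int), fraction=nt_fraction)
        for name, d in inds.items():
            rows.append({"group_id": g, "scale_id": s, "statistic": name,
                         "value": float(np.mean(d)), "n": n})
            rows.append({"group_id": g, "scale_id": s,
                         "statistic": name.replace("flag_rate", "pbis_posterior"),
                         "value": point_biserial(d, post), "n": n})
        if s in responses:
            resp = responses[s]
            item_cols = [c for c in resp.columns if c.startswith("item_")]
            sub = cell[["respondent_id"]].merge(resp, on="respondent_id",
                                                how="left")
            om = omission_counts(sub[item_cols].to_numpy(float))
            rows.append({"group_id": g, "scale_id": s,
                         "statistic": "cor_posterior_omissions",
                         "value": weighted_correlation(post, om, v), "n": n})
    return pd.DataFrame(rows)
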