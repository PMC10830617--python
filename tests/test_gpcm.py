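"""Generalized partial credit model: probabilities, weighted MML, comparison."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import log_expit, logsumexp

import screenweight as sw
from screenweight.exceptions import InvalidInputError
from conftest import draw_gpcm_data, random_items


# ---------------------------------------------------------------------------
# category probabilities


def test_binary_symmetric_item_gives_half():
    item = sw.GpcmItemParams(1.0, [0.0])
    np.testing.assert_allclose(sw.gpcm_category_probs(item, 0.0), [0.5, 0.5],
                               atol=1e-12)


def test_zero_discrimination_gives_uniform():
    item = sw.GpcmItemParams(0.0, [-1.0, 2.0])
    np.testing.assert_allclose(sw.gpcm_category_probs(item, 3.7),
                               np.full(3, 1 / 3), atol=1e-12)


def test_hand_computed_three_category_probs():
    # a=1, b=(-1,1), theta=0: cumulative numerators exp(0), exp(1), exp(0)
    item = sw.GpcmItemParams(1.0, [-1.0, 1.0])
    e = np.exp(1.0)
    np.testing.assert_allclose(sw.gpcm_category_probs(item, 0.0),
                               np.array([1.0, e, 1.0]) / (2.0 + e),
                               atol=1e-12)


def test_probabilities_sum_to_one_and_survive_overflow():
    theta = np.linspace(-6, 6, 61)
    for a, b in [(1.2, [-0.5, 0.3, 1.1]), (35.0, [-2.0, 2.0]), (0.01, [0.0])]:
        p = sw.gpcm_category_probs(sw.GpcmItemParams(a, b), theta)
        assert np.all(np.isfinite(p))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# weighted marginal log-likelihood


def _toy():
    rng = np.random.default_rng(31)
    items = random_items(rng, 3, 2)
    data, _, _ = draw_gpcm_data(32, 60, items, [0.0, 0.4], [1.0, 1.1])
    groups = [sw.GroupDistribution(0.0, 1.0), sw.GroupDistribution(0.4, 1.1)]
    return items, groups, data


def test_unit_weights_reduce_to_unweighted():
    items, groups, data = _toy()
    lw = sw.weighted_marginal_loglik(items, groups, data,
                                     np.ones(data.n_respondents))
    lu = sw.weighted_marginal_loglik(items, groups, data, None)
    assert lw == pytest.approx(lu, abs=1e-12)


def test_doubling_weight_equals_duplicating_case():
    items, groups, data = _toy()
    w = np.ones(data.n_respondents)
    w[7] = 2.0
    resp2 = np.vstack([data.responses, data.responses[7]])
    grp2 = np.append(data.group, data.group[7])
    dup = sw.ResponseMatrix(resp2, grp2, data.max_category)
    assert sw.weighted_marginal_loglik(items, groups, data, w) == \
        pytest.approx(sw.weighted_marginal_loglik(items, groups, dup, None),
                      abs=1e-9)


def test_uninformative_binary_item_integrates_to_half():
    # a=0, K=1: p(y|theta) = 0.5 for every theta, so the marginal is 0.5
    items = [sw.GpcmItemParams(0.0, [0.0])]
    groups = [sw.GroupDistribution(0.0, 1.0)]
    data = sw.ResponseMatrix(np.array([[0], [1]]), np.array([0, 0]))
    ll = sw.weighted_marginal_loglik(items, groups, data,
                                     np.array([1.0, 0.0]))
    assert ll == pytest.approx(np.log(0.5), abs=1e-12)


def test_all_zero_weights_rejected():
    items, groups, data = _toy()
    with pytest.raises(InvalidInputError, match="no effective sample"):
        sw.weighted_marginal_loglik(items, groups, data,
                                    np.zeros(data.n_respondents))


# ---------------------------------------------------------------------------
# fitting


def test_parameter_recovery_two_groups():
    """J=6, K=3, N=3000, group 2 ~ N(0.5, 1.2^2): item RMSE <= 0.15 and
    group-2 mean within 0.08."""
    rng = np.random.default_rng(11)
    items = random_items(rng, 6, 3)
    data, _, _ = draw_gpcm_data(12, 1500, items, [0.0, 0.5], [1.0, 1.2])
    fit = sw.fit_multigroup_gpcm(data)
    assert fit.converged
    a_err = [fit.items[j].discrimination - items[j].discrimination
             for j in range(6)]
    b_err = np.concatenate([fit.items[j].step_difficulties
                            - items[j].step_difficulties for j in range(6)])
    assert np.sqrt(np.mean(np.square(a_err))) <= 0.15
    assert np.sqrt(np.mean(np.square(b_err))) <= 0.15
    assert fit.groups[1].mean == pytest.approx(0.5, abs=0.08)
    assert fit.groups[0].mean == 0.0 and fit.groups[0].sd == 1.0


def test_em_loglik_monotone_every_cycle():
    rng = np.random.default_rng(41)
    items = random_items(rng, 4, 2)
    data, _, _ = draw_gpcm_data(42, 250, items, [0.0, 0.3], [1.0, 1.1])
    fit = sw.fit_multigroup_gpcm(data, config=sw.GpcmConfig(max_cycles=200))
    assert np.all(np.diff(fit.loglik_path) >= -1e-9)


def test_zero_weight_rows_equal_subset_fit():
    rng = np.random.default_rng(51)
    items = random_items(rng, 4, 2)
    data, _, _ = draw_gpcm_data(52, 400, items, [0.0, 0.4], [1.0, 1.1])
    bad = np.zeros(data.n_respondents, dtype=bool)
    bad[::5] = True
    w = np.where(bad, 0.0, 1.0)
    full = sw.fit_multigroup_gpcm(data, w)
    sub = sw.ResponseMatrix(data.responses[~bad], data.group[~bad],
                            data.max_category)
    subset = sw.fit_multigroup_gpcm(sub)
    for fj, sj in zip(full.items, subset.items):
        assert fj.discrimination == pytest.approx(sj.discrimination, abs=1e-4)
        np.testing.assert_allclose(fj.step_difficulties, sj.step_difficulties,
                                   atol=1e-4)
    assert full.groups[1].mean == pytest.approx(subset.groups[1].mean,
                                                abs=1e-4)


def test_weight_scale_invariance():
    rng = np.random.default_rng(61)
    items = random_items(rng, 3, 2)
    data, _, _ = draw_gpcm_data(62, 300, items, [0.0, 0.4], [1.0, 1.1])
    w = rng.uniform(0.2, 1.0, data.n_respondents)
    f1 = sw.fit_multigroup_gpcm(data, w)
    f2 = sw.fit_multigroup_gpcm(data, 7.3 * w)
    # parameters agree to the EM stopping-rule precision (weights are
    # normalised to mean 1 internally, so invariance is exact up to
    # floating-point normalisation)
    for a, b in zip(f1.items, f2.items):
        assert a.discrimination == pytest.approx(b.discrimination, abs=2e-5)
        np.testing.assert_allclose(a.step_difficulties, b.step_difficulties,
                                   atol=2e-5)
    assert f2.loglik == pytest.approx(7.3 * f1.loglik, rel=1e-9)


def test_matches_direct_optimisation_on_2pl_instance():
    """Binary-item (2PL-equivalent) instance, N=200, single group: EM
    estimates match an independent direct optimisation of the weighted
    marginal likelihood within 1e-3.

    Three items are used -- the minimal identified 2PL configuration; with
    two binary items the marginal likelihood has a parameter ridge and
    "the" maximiser is not unique.
    """
    rng = np.random.default_rng(72)
    items = [sw.GpcmItemParams(1.0, [-0.3]), sw.GpcmItemParams(1.4, [0.5]),
             sw.GpcmItemParams(0.8, [0.1])]
    data, _, _ = draw_gpcm_data(73, 200, items, [0.0], [1.0])
    w = rng.uniform(0.5, 1.5, 200)
    fit = sw.fit_multigroup_gpcm(data, w,
                                 sw.GpcmConfig(param_tol=1e-7,
                                               max_cycles=4000))

    nodes = np.linspace(-6.0, 6.0, 61)
    logA = -0.5 * nodes ** 2
    logA -= logsumexp(logA)

    def negloglik(p):
        # independent marginal loglik: direct 2PL evaluation
        ll_nodes = np.zeros((data.n_respondents, nodes.size))
        for j in range(3):
            a, b = p[2 * j], p[2 * j + 1]
            lp1 = log_expit(a * (nodes - b))
            lp0 = log_expit(-a * (nodes - b))
            y = data.responses[:, j]
            ll_nodes += np.where(y[:, None] == 1, lp1[None, :], lp0[None, :])
        return -float(w @ logsumexp(logA[None, :] + ll_nodes, axis=1))

    res = minimize(negloglik, np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0]),
                   method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-12,
                            "maxiter": 8000, "maxfev": 12000})
    for j in range(3):
        assert fit.items[j].discrimination == pytest.approx(res.x[2 * j],
                                                            abs=1e-3)
        assert fit.items[j].step_difficulties[0] == pytest.approx(
            res.x[2 * j + 1], abs=1e-3)
    # the independent evaluator reproduces the EM's maximised loglik
    em_p = np.concatenate([[it.discrimination, it.step_difficulties[0]]
                           for it in fit.items])
    assert negloglik(em_p) == pytest.approx(-fit.loglik, abs=1e-8)


def test_unobserved_category_collapsed():
    rng = np.random.default_rng(81)
    items = random_items(rng, 3, 2)
    data, _, _ = draw_gpcm_data(82, 200, items, [0.0], [1.0])
    resp = data.responses.copy()
    resp[resp[:, 0] == 2, 0] = 1  # category 2 of item 0 never observed
    data2 = sw.ResponseMatrix(resp, data.group, data.max_category)
    fit = sw.fit_multigroup_gpcm(data2)
    assert fit.category_maps[0] is not None
    assert fit.items[0].n_categories == 2


def test_empty_group_rejected():
    data = sw.ResponseMatrix(np.array([[0], [1], [0], [1]]),
                             np.array([0, 0, 2, 2]))
    with pytest.raises(InvalidInputError):
        sw.fit_multigroup_gpcm(data)


def test_contamination_bias_reduced_in_most_replications():
    """20% C/IER-style contamination (uniform / straight-line / omissions):
    the attentiveness-weighted fit's group-mean bias is strictly smaller in
    absolute value than the unadjusted fit's in >= 45 of 50 replications."""
    K = 3
    cfg = sw.GpcmConfig(n_quadrature=31, max_cycles=60, param_tol=1e-3)
    wins = 0
    for r in range(50):
        rng = np.random.default_rng(1000 + r)
        items = random_items(rng, 6, K)
        half = 2000
        theta = np.concatenate([rng.normal(0, 1, half),
                                rng.normal(1.0, 1.2, half)])
        group = np.repeat([0, 1], half)
        resp = np.empty((2 * half, 6), dtype=int)
        for j, it in enumerate(items):
            p = sw.gpcm_category_probs(it, theta)
            u = rng.uniform(size=2 * half)
            resp[:, j] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
        contam = rng.uniform(size=2 * half) < 0.2
        idx = np.nonzero(contam)[0]
        style = rng.choice(3, size=idx.size, p=[0.5, 0.3, 0.2])
        for i, s in zip(idx, style):
            if s == 0:
                resp[i] = rng.integers(0, K + 1, size=6)
            elif s == 1:
                resp[i] = rng.integers(0, K + 1)
            else:
                resp[i] = sw.MISSING
            if s != 2:
                om = rng.uniform(size=6) < 0.25
                resp[i, om] = sw.MISSING
        keep = ~np.all(resp == sw.MISSING, axis=1)
        data = sw.ResponseMatrix(resp[keep], group[keep])
        w = np.where(contam, 0.02, 1.0)[keep]
        unadj = sw.fit_multigroup_gpcm(data, None, cfg)
        adj = sw.fit_multigroup_gpcm(data, w, cfg)
        wins += (abs(adj.groups[1].mean - 1.0)
                 < abs(unadj.groups[1].mean - 1.0))
    assert wins >= 45


# ---------------------------------------------------------------------------
# fit comparison


def _fit_with_groups(items, groups):
    return sw.GpcmFit(items, groups, 0.0, 61, True)


def test_identical_fits_compare_to_zero():
    rng = np.random.default_rng(91)
    items = random_items(rng, 2, 2)
    groups = [sw.GroupDistribution(0.0, 1.0), sw.GroupDistribution(0.5, 1.2)]
    table, summary = sw.compare_fits(_fit_with_groups(items, groups),
                                     _fit_with_groups(items, groups))
    assert (table["mean_diff"] == 0).all()
    assert (table["var_diff"] == 0).all()
    assert summary["median_abs_mean_diff"] == 0.0


def test_single_group_median_is_that_value():
    rng = np.random.default_rng(92)
    items = random_items(rng, 2, 2)
    a = _fit_with_groups(items, [sw.GroupDistribution(0.3, 1.0)])
    b = _fit_with_groups(items, [sw.GroupDistribution(0.1, 1.0)])
    _, summary = sw.compare_fits(a, b)
    assert summary["median_abs_mean_diff"] == pytest.approx(0.2)


def test_mismatched_structures_rejected():
    rng = np.random.default_rng(93)
    items = random_items(rng, 2, 2)
    a = _fit_with_groups(items, [sw.GroupDistribution(0.0, 1.0)])
    b = _fit_with_groups(items, [sw.GroupDistribution(0.0, 1.0),
                                 sw.GroupDistribution(0.1, 1.0)])
    with pytest.raises(InvalidInputError):
        sw.compare_fits(a, b)
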