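"""Screen-time transform, weighted mixture EM, C/IER labelling."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import screenweight as sw
from screenweight.exceptions import InsufficientDataError, InvalidInputError
from screenweight.timing import MixtureFit


# ---------------------------------------------------------------------------
# log geometric mean time


@pytest.mark.parametrize("t, j, expected", [
    (16.0, 4, np.log(2.0)),      # ln(16)/4 = ln 2
    (60.0, 1, np.log(60.0)),     # one-minute anchor, 4.0943
    (1.0, 1, 0.0),
    (1.0, 7, 0.0),
])
def test_log_geometric_time_values(t, j, expected):
    assert sw.log_geometric_time(t, j) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("t, j", [(0.0, 1), (-1.0, 2), (5.0, 0), (np.nan, 1)])
def test_log_geometric_time_rejects_invalid(t, j):
    with pytest.raises(InvalidInputError):
        sw.log_geometric_time(t, j)


# ---------------------------------------------------------------------------
# weighted EM


def test_single_component_is_closed_form_weighted_mle():
    rng = np.random.default_rng(0)
    x = rng.normal(1.0, 0.5, 200)
    w = rng.uniform(0.5, 2.0, 200)
    fit = sw.fit_weighted_gmm(x, w, n_components=1, seed=0)
    mu = np.average(x, weights=w)
    sd = np.sqrt(np.average((x - mu) ** 2, weights=w))
    assert fit.means[0] == pytest.approx(mu, abs=1e-12)
    assert fit.sds[0] == pytest.approx(sd, abs=1e-12)
    assert fit.proportions[0] == 1.0


@pytest.mark.parametrize("n_components", [1, 2, 3])
def test_integer_weights_equal_replication(n_components):
    """A point with weight 2 fits identically to that point duplicated."""
    rng = np.random.default_rng(3)
    x = np.concatenate([rng.normal(0, 0.4, 40), rng.normal(2, 0.4, 40)])
    w = np.ones(80)
    w[::5] = 2.0
    xrep = np.repeat(x, w.astype(int))
    fw = sw.fit_weighted_gmm(x, w, n_components=n_components, seed=9)
    fr = sw.fit_weighted_gmm(xrep, None, n_components=n_components, seed=9)
    np.testing.assert_allclose(fw.means, fr.means, atol=1e-6)
    np.testing.assert_allclose(fw.sds, fr.sds, atol=1e-6)
    np.testing.assert_allclose(fw.proportions, fr.proportions, atol=1e-6)
    assert fw.loglik == pytest.approx(fr.loglik, abs=1e-6)


def test_two_component_parameter_recovery():
    """n=5000 from 0.5 N(0,0.3^2) + 0.5 N(2,0.3^2): means within 0.05,
    proportions within 0.03 of truth."""
    rng = np.random.default_rng(11)
    x = np.concatenate([rng.normal(0, 0.3, 2500), rng.normal(2, 0.3, 2500)])
    fit = sw.fit_weighted_gmm(x, n_components=2, seed=5)
    assert fit.converged
    np.testing.assert_allclose(fit.means, [0.0, 2.0], atol=0.05)
    np.testing.assert_allclose(fit.proportions, [0.5, 0.5], atol=0.03)


def test_em_loglik_path_monotone():
    rng = np.random.default_rng(21)
    for rep in range(5):
        x = rng.normal(size=300) + (rng.uniform(size=300) < 0.3) * 2.0
        for c in (2, 3, 4):
            fit = sw.fit_weighted_gmm(x, n_components=c, seed=rep)
            assert np.all(np.diff(fit.loglik_path) >= -1e-9 *
                          (1 + np.abs(fit.loglik_path[:-1])))


def test_insufficient_data_raises():
    with pytest.raises(InsufficientDataError):
        sw.fit_weighted_gmm(np.arange(15.0), n_components=2, seed=0)


def _grid_oracle_loglik(x, w, n_components):
    """Dense grid search over (mu, sigma, pi); independent of the EM path."""
    mus = np.linspace(x.min(), x.max(), 16)
    sds = np.geomspace(0.05 * x.std(), 2 * x.std(), 12)
    # cache per-(mu, sigma) normal log densities: (16*12, n)
    grid = [(m, s, -0.5 * ((x - m) / s) ** 2 - np.log(s)
             - 0.5 * np.log(2 * np.pi))
            for m in mus for s in sds]
    if n_components == 1:
        return max(float(np.dot(w, lp)) for _, _, lp in grid)
    pis = np.linspace(0.05, 0.95, 9)
    lpi, l1mpi = np.log(pis), np.log(1 - pis)
    best = -np.inf
    for i, (m1, _, lp1) in enumerate(grid):
        for (m2, _, lp2) in grid[i:]:
            mix = np.logaddexp(lpi[:, None] + lp1[None, :],
                               l1mpi[:, None] + lp2[None, :])
            best = max(best, float((mix @ w).max()))
    return best


@pytest.mark.parametrize("n_components", [1, 2])
def test_em_beats_grid_oracle(n_components):
    """EM solution's weighted loglik dominates a dense independent grid
    search on small samples."""
    rng = np.random.default_rng(17)
    x = np.concatenate([rng.normal(0, 0.5, 25), rng.normal(1.5, 0.5, 25)])
    w = rng.uniform(0.5, 1.5, 50)
    fit = sw.fit_weighted_gmm(x, w, n_components=n_components, seed=2)
    oracle = _grid_oracle_loglik(x, w, n_components)
    assert fit.loglik >= oracle - 1e-9


# ---------------------------------------------------------------------------
# component selection by BIC


def test_select_components_separated_data_picks_at_least_two():
    rng = np.random.default_rng(23)
    x = np.concatenate([rng.normal(0, 0.3, 1000), rng.normal(0.9, 0.3, 1000)])
    fit = sw.select_components(x, seed=1)
    assert fit.n_components >= 2


def test_select_components_max_one_returns_single():
    rng = np.random.default_rng(29)
    fit = sw.select_components(rng.normal(size=500), max_components=1, seed=0)
    assert fit.n_components == 1


def test_null_data_rarely_yields_low_mean_component():
    """Pure N(0,1): across 50 seeded replications the selected solution's
    lowest-mean proportion is <= .10 in at least 90% of them."""
    ok = 0
    for r in range(50):
        rng = np.random.default_rng(200 + r)
        x = rng.normal(0, 1, 2000)
        fit = sw.select_components(x, seed=r)
        dec = sw.label_cier(fit, x)
        ok += dec.cier_proportion <= 0.10
    assert ok >= 45


def test_cier_proportion_recovery_over_replications():
    """d=3 two-component scenario: mean absolute error of the C/IER mixture
    proportion over 50 seeded replications is <= 0.02."""
    errs = []
    for r in range(50):
        rng = np.random.default_rng(100 + r)
        x = np.concatenate([rng.normal(0, 0.3, 1000),
                            rng.normal(0.9, 0.3, 1000)])
        fit = sw.select_components(x, seed=r)
        dec = sw.label_cier(fit, x)
        errs.append(abs(dec.cier_proportion - 0.5))
    assert np.mean(errs) <= 0.02


# ---------------------------------------------------------------------------
# labelling and posteriors


def _fit(means, sds, props):
    return MixtureFit(len(means), means, sds, props, 0.0, 0.0, True,
                      100, 0)


def test_single_component_gives_unit_weights():
    x = np.linspace(-1, 1, 20)
    dec = sw.label_cier(_fit([0.5], [1.0], [1.0]), x)
    assert dec.cier_component is None
    assert dec.cier_proportion == 0.0
    np.testing.assert_array_equal(dec.attentiveness_weights, 1.0)
    np.testing.assert_array_equal(dec.posteriors, 0.0)


def test_lowest_mean_component_is_labelled():
    fit = _fit([0.9, 0.1, 1.4], [0.3, 0.3, 0.3], [0.3, 0.2, 0.5])
    dec = sw.label_cier(fit, np.array([0.1, 1.0]))
    assert dec.cier_component == 1
    assert dec.cier_proportion == pytest.approx(0.2)
    assert dec.mean_cier_time_per_item == pytest.approx(np.exp(0.1))


def test_tied_means_take_lowest_index_with_warning(caplog):
    fit = _fit([0.5, 0.5], [0.2, 0.6], [0.5, 0.5])
    with caplog.at_level(logging.WARNING, logger="screenweight.timing"):
        dec = sw.label_cier(fit, np.array([0.0, 1.0]))
    assert dec.cier_component == 0
    assert any("tie" in r.message for r in caplog.records)


def test_posterior_symmetric_midpoint():
    fit = _fit([0.0, 2.0], [1.0, 1.0], [0.5, 0.5])
    assert sw.posterior_cier(fit, 0, 1.0) == pytest.approx(0.5, abs=1e-12)


def test_posterior_density_ratio_value():
    # p = 0.5 phi(0;0,1) / (0.5 phi(0;0,1) + 0.5 phi(0;2,1)) = 1/(1+e^-2)
    fit = _fit([0.0, 2.0], [1.0, 1.0], [0.5, 0.5])
    assert sw.posterior_cier(fit, 0, 0.0) == pytest.approx(
        1.0 / (1.0 + np.exp(-2.0)), abs=1e-12)


def test_posterior_limit_far_left_tail():
    fit = _fit([0.0, 2.0], [1.0, 1.0], [0.5, 0.5])
    assert sw.posterior_cier(fit, 0, -40.0) == pytest.approx(1.0, abs=1e-12)
    # far into the tail, log-space evaluation must not produce NaN
    assert np.isfinite(sw.posterior_cier(fit, 0, -500.0))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(x=st.floats(-50, 50))
def test_posteriors_normalise_over_components(x):
    fit = _fit([-1.0, 0.5, 2.0], [0.5, 1.0, 0.2], [0.2, 0.5, 0.3])
    total = sum(sw.posterior_cier(fit, c, x) for c in range(3))
    assert total == pytest.approx(1.0, abs=1e-12)


def test_attentiveness_weights_complement():
    np.testing.assert_allclose(
        sw.attentiveness_weights([0.0, 1.0, 0.8808]),
        [1.0, 0.0, 0.1192], atol=1e-12)


@pytest.mark.parametrize("bad", [[-0.1], [1.2], [np.nan]])
def test_attentiveness_weights_reject_out_of_range(bad):
    with pytest.raises(InvalidInputError):
        sw.attentiveness_weights(bad)


# ---------------------------------------------------------------------------
# decomposition driver


def test_decompose_flags_unusable_times(small_dataset):
    rec = small_dataset.screen_records.copy()
    rec.loc[rec.index[:3], "time_seconds"] = np.nan
    w, summaries = sw.decompose_screen_times(rec, max_components=3, seed=0)
    merged = rec.merge(w, on=["respondent_id", "group_id", "scale_id"])
    bad = merged[~np.isfinite(merged["time_seconds"])]
    assert len(bad) == 3
    assert (bad["attentiveness_weight"] == 1.0).all()
    assert bad["not_assessed"].all()
    assert len(summaries) == rec.groupby(["group_id", "scale_id"]).ngroups


def test_decompose_deterministic_and_order_independent(small_dataset):
    rec = small_dataset.screen_records
    w1, s1 = sw.decompose_screen_times(rec, max_components=3, seed=5)
    shuffled = rec.sample(frac=1.0, random_state=0)
    w2, s2 = sw.decompose_screen_times(shuffled, max_components=3, seed=5)
    m = w1.merge(w2, on=["respondent_id", "group_id", "scale_id"],
                 suffixes=("_a", "_b"))
    np.testing.assert_allclose(m["posterior_cier_a"], m["posterior_cier_b"],
                               atol=1e-12)
    for k in s1:
        assert s1[k]["bic_path"] == pytest.approx(s2[k]["bic_path"])
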