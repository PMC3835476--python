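import itertools
import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pfhaqlink.irt import (
    CalibrationModel,
    ItemParams,
    ModelKind,
    QuadratureGrid,
    category_probabilities,
    eap_pattern,
    fit_calibration,
    sum_score_eap_table,
    sum_score_posterior,
    test_information,
)

# ---------------------------------------------------------------------------
# hand-coded oracle: adjacent-category probabilities, written independently


def oracle_probs(theta, a, b):
    terms = [1.0]
    for k in range(1, len(b) + 1):
        terms.append(np.exp(sum(a * (theta - bh) for bh in b[:k])))
    terms = np.array(terms)
    return terms / terms.sum()


def oracle_pattern_probability(pattern, items, theta):
    p = 1.0
    for x, it in zip(pattern, items):
        p *= oracle_probs(theta, it.discrimination, list(it.thresholds))[x]
    return p


# ---------------------------------------------------------------------------
# category probabilities


def test_binary_item_crosses_half_at_threshold():
    item = ItemParams("b", thresholds=np.array([0.3]))
    np.testing.assert_allclose(category_probabilities(0.3, item), [0.5, 0.5])


def test_three_category_hand_value():
    # unnormalized terms at theta=0, a=1, b=(-1, 1): 1, e^1, e^0
    item = ItemParams("h", thresholds=np.array([-1.0, 1.0]))
    p = category_probabilities(0.0, item)
    np.testing.assert_allclose(np.round(p, 3), [0.212, 0.576, 0.212])


@given(
    st.floats(-4, 4),
    st.floats(0.3, 2.5),
    st.lists(st.floats(-3, 3), min_size=1, max_size=3),
)
def test_probabilities_normalize_and_match_oracle(theta, a, b):
    item = ItemParams("p", thresholds=np.sort(b), discrimination=a)
    p = category_probabilities(theta, item)
    assert p.shape == (len(b) + 1,)
    assert np.isclose(p.sum(), 1.0)
    np.testing.assert_allclose(p, oracle_probs(theta, a, np.sort(b)), atol=1e-12)


def test_nonfinite_theta_rejected():
    with pytest.raises(ValueError):
        category_probabilities(np.nan, ItemParams("x", thresholds=np.array([0.0])))


# ---------------------------------------------------------------------------
# EAP


def test_eap_matches_fine_grid_integration(toy_items, grid61):
    fine = np.linspace(-6, 6, 601)
    w = np.exp(-0.5 * fine**2)
    for pattern in [(0, 0, 0), (1, 2, 0), (2, 2, 2), (1, 1, 1)]:
        like = np.array([oracle_pattern_probability(pattern, toy_items, t) for t in fine])
        post = like * w
        oracle = np.sum(post * fine) / np.sum(post)
        est = eap_pattern(pattern, toy_items, grid61)
        assert abs(est.eap[0] - oracle) < 1e-6


def test_eap_monotone_in_disability(toy_items, grid61):
    worst = eap_pattern((2, 2, 2), toy_items, grid61)
    best = eap_pattern((0, 0, 0), toy_items, grid61)
    assert best.eap[0] < worst.eap[0]


def test_eap_symmetry(symmetric_items, grid61):
    est = eap_pattern((1, 1), symmetric_items, grid61)
    assert abs(est.eap[0]) < 1e-8


def test_eap_rejects_all_missing(toy_items, grid61):
    with pytest.raises(ValueError):
        eap_pattern((-1, -1, -1), toy_items, grid61)


# ---------------------------------------------------------------------------
# summed-score recursion (Lord-Wingersky)


def test_recursion_equals_pattern_enumeration(toy_items, grid61):
    dist = sum_score_posterior(toy_items, grid61)
    enum = np.zeros_like(dist)
    for pattern in itertools.product(range(3), repeat=3):
        s = sum(pattern)
        for q, t in enumerate(grid61.nodes):
            enum[q, s] += oracle_pattern_probability(pattern, toy_items, t)
    np.testing.assert_allclose(dist, enum, atol=1e-10)


def test_recursion_single_item(grid61):
    item = ItemParams("one", thresholds=np.array([-0.5, 0.8]))
    dist = sum_score_posterior([item], grid61)
    np.testing.assert_allclose(dist, category_probabilities(grid61.nodes, item))


def test_recursion_mass_conserved(toy_items, grid61):
    dist = sum_score_posterior(toy_items, grid61)
    np.testing.assert_allclose(dist.sum(axis=1), 1.0, atol=1e-10)


def test_score_table_rasch_sufficiency(toy_items, grid61):
    """Under the PCM the summed score is sufficient: the table EAP equals
    the pattern EAP of any pattern attaining that sum."""
    table = sum_score_eap_table(toy_items, grid61)
    for pattern in itertools.product(range(3), repeat=3):
        s = sum(pattern)
        est = eap_pattern(pattern, toy_items, grid61)
        assert abs(table.eap[s] - est.eap[0]) < 1e-6


def test_score_table_monotone_with_extreme_ends(toy_items, grid61):
    table = sum_score_eap_table(toy_items, grid61)
    assert np.all(np.diff(table.eap) > 0)
    assert table.eap[0] == table.eap.min() and table.eap[-1] == table.eap.max()


# ---------------------------------------------------------------------------
# information


def test_information_binary_item_quarter_at_threshold():
    item = ItemParams("b", thresholds=np.array([0.7]))
    np.testing.assert_allclose(test_information([item], np.array([0.7])), [0.25])


def test_information_additive(toy_items):
    theta = np.linspace(-3, 3, 21)
    total = test_information(toy_items, theta)
    parts = sum(test_information([it], theta) for it in toy_items)
    np.testing.assert_allclose(total, parts)


def test_information_translation_invariance(toy_items):
    delta = 0.8
    theta = np.linspace(-2, 2, 11)
    shifted = [
        ItemParams(it.item_id, thresholds=it.thresholds + delta, discrimination=it.discrimination)
        for it in toy_items
    ]
    np.testing.assert_allclose(
        test_information(shifted, theta + delta), test_information(toy_items, theta), atol=1e-12
    )


# ---------------------------------------------------------------------------
# estimation


def _simulate(items, n, seed):
    rng = np.random.default_rng(seed)
    theta = rng.standard_normal(n)
    resp = np.empty((n, len(items)), dtype=int)
    for j, it in enumerate(items):
        p = category_probabilities(theta, it)
        u = rng.random(n)
        resp[:, j] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return resp


@pytest.fixture(scope="module")
def small_fit(toy_items):
    resp = _simulate(toy_items, 600, seed=42)
    pcm = fit_calibration(resp, toy_items, ModelKind.PCM)
    gpcm = fit_calibration(resp, toy_items, ModelKind.GPCM)
    return resp, pcm, gpcm


def test_em_loglik_monotone(small_fit):
    _, pcm, gpcm = small_fit
    assert np.all(np.diff(pcm.loglik_trace) > -1e-8)
    assert np.all(np.diff(gpcm.loglik_trace) > -1e-8)


def test_nested_models_loglik_ordering(small_fit):
    _, pcm, gpcm = small_fit
    assert gpcm.log_likelihood >= pcm.log_likelihood - 1e-6


def test_small_sample_recovery(small_fit, toy_items):
    _, pcm, _ = small_fit
    est = np.concatenate([it.thresholds for it in pcm.items])
    true = np.concatenate([it.thresholds for it in toy_items])
    assert np.corrcoef(est, true)[0, 1] > 0.98


def test_minimum_sample_size_enforced(toy_items):
    resp = _simulate(toy_items, 50, seed=0)
    with pytest.raises(ValueError, match="at least"):
        fit_calibration(resp, toy_items)


def test_unobserved_category_collapses_with_warning(toy_items, caplog):
    resp = _simulate(toy_items, 400, seed=1)
    resp[resp[:, 0] == 2, 0] = 1  # category 2 of item 1 never observed
    with caplog.at_level(logging.WARNING):
        res = fit_calibration(resp, toy_items)
    assert "collapsing" in caplog.text
    assert res.items[0].n_categories == 2


def test_unobserved_category_strict_mode_errors(toy_items):
    resp = _simulate(toy_items, 400, seed=1)
    resp[resp[:, 0] == 2, 0] = 1
    with pytest.raises(ValueError, match="unobserved"):
        fit_calibration(resp, toy_items, on_unobserved="strict")


def test_mirt2_requires_dimensions():
    with pytest.raises(ValueError):
        CalibrationModel(kind=ModelKind.MIRT2)


def test_quadrature_weights_normalized():
    g1 = QuadratureGrid.make(61)
    g2 = QuadratureGrid.make(41, rho=0.73)
    assert abs(g1.weights.sum() - 1) < 1e-10
    assert abs(g2.weights.sum() - 1) < 1e-10
    assert abs(g2.marginal_weights.sum() - 1) < 1e-10
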