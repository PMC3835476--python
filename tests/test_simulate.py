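import numpy as np
import pytest

from pfhaqlink.instruments import HaqMethod
from pfhaqlink.irt import QuadratureGrid, category_probabilities
from pfhaqlink.linking import score_haq_matrix
from pfhaqlink.simulate import (
    SimulationConfig,
    default_item_params,
    simulate_dataset,
    simulate_longitudinal,
    simulate_responses,
    simulate_thetas,
)
from pfhaqlink.validation import classify_responder


def test_same_seed_reproduces_everything():
    a = simulate_dataset(SimulationConfig(n=200, seed=5))
    b = simulate_dataset(SimulationConfig(n=200, seed=5))
    assert np.array_equal(a.pf10, b.pf10)
    assert np.array_equal(a.haq_items, b.haq_items)
    assert np.array_equal(a.aid_flags, b.aid_flags)
    c = simulate_dataset(SimulationConfig(n=200, seed=6))
    assert not np.array_equal(a.pf10, c.pf10)


def test_two_dimensional_thetas_hit_target_correlation():
    cfg = SimulationConfig(n=100_000, two_dimensional=True, rho=0.73, seed=0)
    th = simulate_thetas(cfg, np.random.default_rng(0))
    r = np.corrcoef(th[:, 0], th[:, 1])[0, 1]
    assert r == pytest.approx(0.73, abs=0.01)
    cfg0 = SimulationConfig(n=100_000, two_dimensional=True, rho=0.0, seed=0)
    th0 = simulate_thetas(cfg0, np.random.default_rng(0))
    assert abs(np.corrcoef(th0[:, 0], th0[:, 1])[0, 1]) < 0.02


def test_category_frequencies_match_model():
    """Empirical marginal category frequencies equal the prior-integrated
    model probabilities within Monte-Carlo error."""
    cfg = SimulationConfig(n=100_000, seed=1)
    items = default_item_params()
    rng = np.random.default_rng(1)
    thetas = simulate_thetas(cfg, rng)
    data = simulate_responses(thetas, items, cfg, rng)
    grid = QuadratureGrid.make(101)
    # PF-10 item 1 (reverse-coded counts: response r stored as 3 - k)
    p_model = grid.weights @ category_probabilities(grid.nodes, items[0])
    freq = np.bincount(3 - data.pf10[:, 0], minlength=3) / cfg.n
    np.testing.assert_allclose(freq, p_model, atol=0.01)
    # HAQ category scores under ADI = the generating polytomous draw
    cats = score_haq_matrix(data.haq_items, data.aid_flags, HaqMethod.ADI)
    p_model = grid.weights @ category_probabilities(grid.nodes, items[10])
    freq = np.bincount(cats[:, 0], minlength=4) / cfg.n
    np.testing.assert_allclose(freq, p_model, atol=0.01)


def test_aid_flags_increase_with_disability():
    cfg = SimulationConfig(n=50_000, seed=2)
    data = simulate_dataset(cfg)
    theta = data.thetas[:, 0]
    deciles = np.quantile(theta, np.linspace(0, 1, 11))
    prevalence = [
        data.aid_flags[(theta >= lo) & (theta < hi)].mean()
        for lo, hi in zip(deciles[:-1], deciles[1:])
    ]
    assert prevalence[-1] > prevalence[0]
    # monotone trend across deciles
    assert np.polyfit(np.arange(10), prevalence, 1)[0] > 0


def test_sdi_at_least_adi_by_construction():
    data = simulate_dataset(SimulationConfig(n=2000, seed=3))
    sdi = score_haq_matrix(data.haq_items, data.aid_flags, HaqMethod.SDI)
    adi = score_haq_matrix(data.haq_items, data.aid_flags, HaqMethod.ADI)
    assert np.all(sdi >= adi)
    assert (sdi > adi).any()  # flags do bite somewhere


def test_haq_item_blocks_attain_intended_maximum():
    from pfhaqlink.instruments import HAQ_CATEGORIES

    data = simulate_dataset(SimulationConfig(n=5000, seed=4))
    cats = score_haq_matrix(data.haq_items, data.aid_flags, HaqMethod.ADI)
    for c, (_, idx) in enumerate(HAQ_CATEGORIES):
        assert np.array_equal(data.haq_items[:, list(idx)].max(axis=1), cats[:, c])


def test_longitudinal_responder_structure():
    cfg = SimulationConfig(seed=7)
    ldata = simulate_longitudinal(cfg)
    classified = classify_responder(ldata.das28_baseline, ldata.das28_followup)
    assert np.array_equal(classified, ldata.good_responder)
    # non-responders improve little on the latent scale
    change = ldata.baseline.thetas[:, 0] - ldata.followup.thetas[:, 0]
    assert change[~ldata.good_responder].mean() == pytest.approx(
        cfg.improvement_other, abs=0.15
    )
    assert change[ldata.good_responder].mean() == pytest.approx(cfg.improvement_good, abs=0.15)
    assert ldata.baseline.pf10.shape[0] == cfg.n_longitudinal


def test_cross_validation_scenario_effect_sizes_in_band():
    """The default longitudinal scenario produces 6-month effect sizes in
    the moderate range typical of an early-RA treat-to-target cohort."""
    from pfhaqlink.validation import effect_size_change

    cfg = SimulationConfig(n_longitudinal=276, theta_shift=-0.5, seed=11)
    cohort = simulate_longitudinal(cfg)
    pf0 = (cohort.baseline.pf10.sum(axis=1) - 10) / 20 * 100
    pf1 = (cohort.followup.pf10.sum(axis=1) - 10) / 20 * 100
    assert 0.3 <= effect_size_change(pf0, pf1, higher_is_better=True) <= 0.6
    for method in HaqMethod:
        h0 = score_haq_matrix(cohort.baseline.haq_items, cohort.baseline.aid_flags, method).mean(axis=1)
        h1 = score_haq_matrix(cohort.followup.haq_items, cohort.followup.aid_flags, method).mean(axis=1)
        assert 0.3 <= effect_size_change(h0, h1) <= 0.6


def test_pipeline_agreement_in_expected_band():
    """Observed vs crosswalk-predicted totals on a default synthetic
    baseline cohort agree at the group-adequate level (ICC 0.7-0.9)."""
    from pfhaqlink.io import load_published_crosswalk
    from pfhaqlink.validation import icc_a1

    data = simulate_dataset(SimulationConfig(n=532, theta_shift=-0.5, seed=13))
    cw = load_published_crosswalk(HaqMethod.SDI)
    pf = (data.pf10.sum(axis=1) - 10) / 20 * 100
    haq = score_haq_matrix(data.haq_items, data.aid_flags, HaqMethod.SDI).mean(axis=1)
    icc_haq = icc_a1(haq, np.array([cw.haq_from_pf10(v) for v in pf])).icc
    icc_pf = icc_a1(pf, np.array([cw.pf10_from_haq(v)[0] for v in haq])).icc
    assert 0.7 <= icc_haq <= 0.9
    assert 0.7 <= icc_pf <= 0.9


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n=0)
    with pytest.raises(ValueError):
        SimulationConfig(rho=1.5)
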