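import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pfhaqlink.validation import (
    _bca_adjusted_quantiles,
    anova_f,
    bca_interval,
    bland_altman,
    classify_responder,
    effect_size_change,
    icc_a1,
    relative_validity,
)

# ---------------------------------------------------------------------------
# ICC(A,1)


def test_icc_perfect_agreement():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    assert icc_a1(x, x.copy()).icc == pytest.approx(1.0)


def test_icc_absolute_agreement_penalizes_offset():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 50)
    y = x + 5.0
    rep = icc_a1(x, y)
    consistency_r = np.corrcoef(x, y)[0, 1]
    assert rep.icc < consistency_r


def test_icc_hand_computed_six_pairs():
    """Oracle: the two-way mean squares evaluated by hand arithmetic."""
    x = np.array([9.0, 6.0, 8.0, 7.0, 10.0, 6.0])
    y = np.array([2.0, 1.0, 4.0, 1.0, 5.0, 2.0])
    data = np.stack([x, y], axis=1)
    n, k = data.shape
    grand = data.mean()
    msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    mse = (
        (data - data.mean(axis=1, keepdims=True) - data.mean(axis=0, keepdims=True) + grand) ** 2
    ).sum() / ((n - 1) * (k - 1))
    expected = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
    assert icc_a1(x, y).icc == pytest.approx(expected, abs=1e-10)


def test_icc_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(7)
    x = rng.normal(50, 10, 60)
    y = x + rng.normal(1, 6, 60)
    rep = icc_a1(x, y)
    df = pd.DataFrame(
        {
            "targets": np.tile(np.arange(60), 2),
            "raters": np.repeat(["obs", "pred"], 60),
            "ratings": np.concatenate([x, y]),
        }
    )
    table = pg.intraclass_corr(data=df, targets="targets", raters="raters", ratings="ratings")
    row = table[table["Type"] == "ICC(A,1)"].iloc[0]
    assert rep.icc == pytest.approx(row["ICC"], abs=1e-9)
    np.testing.assert_allclose(rep.ci, row["CI95"], atol=5e-3)


def test_icc_symmetric_in_arguments():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 30)
    y = x + rng.normal(0.5, 0.8, 30)
    assert icc_a1(x, y).icc == pytest.approx(icc_a1(y, x).icc, abs=1e-12)


def test_icc_degenerate_input_rejected():
    flat = np.ones(10)
    with pytest.raises(ValueError, match="variance"):
        icc_a1(flat, flat)
    with pytest.raises(ValueError):
        icc_a1(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


def test_icc_group_level_flag():
    x = np.arange(20.0)
    assert icc_a1(x, x).adequate_for_group_level
    rng = np.random.default_rng(0)
    noisy = icc_a1(x, rng.permutation(x))
    assert not noisy.adequate_for_group_level


# ---------------------------------------------------------------------------
# Bland-Altman


def test_bland_altman_constant_offset():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    ba = bland_altman(x, x + 2.0)  # observed minus predicted = -2
    assert ba.mean_difference == pytest.approx(-2.0)
    assert ba.sd_difference == pytest.approx(0.0)
    assert ba.loa == pytest.approx((-2.0, -2.0))


def test_bland_altman_symmetric_differences():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    y = np.array([1.0, 0.0, 3.0, 2.0])
    assert bland_altman(x, y).mean_difference == pytest.approx(0.0)


def test_bland_altman_five_pair_arithmetic():
    x = np.array([10.0, 12.0, 9.0, 14.0, 11.0])
    y = np.array([11.0, 11.0, 10.0, 12.0, 12.0])
    d = x - y
    ba = bland_altman(x, y)
    assert ba.mean_difference == pytest.approx(d.mean())
    assert ba.loa[0] == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
    assert ba.loa[1] == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
    np.testing.assert_allclose(ba.means, (x + y) / 2)


def test_bland_altman_needs_two_pairs():
    with pytest.raises(ValueError):
        bland_altman(np.array([1.0]), np.array([1.0]))


# ---------------------------------------------------------------------------
# responder rule


@pytest.mark.parametrize(
    "baseline, followup, expected",
    [
        (5.0, 3.0, True),  # improved 2.0, final <= 3.2
        (4.0, 3.0, False),  # improvement 1.0 < 1.2
        (6.0, 3.4, False),  # final > 3.2
        (4.4, 3.2, True),  # boundary: exactly 1.2 and exactly 3.2
    ],
)
def test_responder_rule(baseline, followup, expected):
    assert classify_responder(baseline, followup) is expected


@given(st.floats(0, 10), st.floats(0, 10), st.floats(0.01, 2.0))
def test_responder_monotone_in_followup(baseline, followup, drop):
    """Lowering the follow-up DAS28 never demotes a good responder."""
    if classify_responder(baseline, followup):
        assert classify_responder(baseline, max(followup - drop, 0.0))


def test_responder_missing_is_unclassified():
    out = classify_responder(np.array([5.0, np.nan]), np.array([3.0, 2.0]))
    assert out.tolist() == [True, False]


# ---------------------------------------------------------------------------
# effect size


def test_effect_size_zero_without_change():
    b = np.array([1.0, 2.0, 3.0])
    assert effect_size_change(b, b.copy()) == pytest.approx(0.0)


def test_effect_size_one_sd_improvement():
    rng = np.random.default_rng(4)
    b = rng.normal(1.5, 0.5, 200)
    f = b - b.std(ddof=1)  # uniform improvement of one baseline SD
    assert effect_size_change(b, f) == pytest.approx(1.0)
    # function-coded scale: improvement is an increase
    assert effect_size_change(b, b + b.std(ddof=1), higher_is_better=True) == pytest.approx(1.0)


def test_effect_size_change_denominator():
    rng = np.random.default_rng(5)
    b = rng.normal(0, 1, 100)
    f = b - rng.normal(0.5, 0.2, 100)
    d = effect_size_change(b, f, denominator="change")
    change = b - f
    assert d == pytest.approx(change.mean() / change.std(ddof=1))


def test_effect_size_zero_sd_rejected():
    with pytest.raises(ValueError):
        effect_size_change(np.ones(5), np.zeros(5))


# ---------------------------------------------------------------------------
# relative validity and BCa


def test_rv_identity_when_predictions_match():
    rng = np.random.default_rng(6)
    g = rng.random(80) < 0.5
    change = rng.normal(0, 1, 80) - g * 1.0
    entry = relative_validity(change, change, g, n_boot=300, seed=0)
    assert entry.rv == pytest.approx(1.0)
    assert entry.rv_ci[0] <= 1.0 <= entry.rv_ci[1]


def test_rv_reproducible_with_seed():
    rng = np.random.default_rng(8)
    g = rng.random(60) < 0.5
    obs = rng.normal(0, 1, 60) - g * 0.8
    pred = obs + rng.normal(0, 0.3, 60)
    e1 = relative_validity(pred, obs, g, n_boot=200, seed=11)
    e2 = relative_validity(pred, obs, g, n_boot=200, seed=11)
    assert e1.rv_ci == e2.rv_ci


def test_anova_f_null_near_one():
    """With shuffled (null) labels, E[F] is about 1."""
    rng = np.random.default_rng(9)
    x = rng.normal(0, 1, 100)
    fs = [anova_f(x, rng.permutation(np.arange(100) < 50)) for _ in range(300)]
    assert np.mean(fs) == pytest.approx(1.0, abs=0.25)


def test_bca_reduces_to_percentile_without_bias_and_acceleration():
    rng = np.random.default_rng(10)
    boots = rng.normal(2.0, 0.5, 5000)
    lo, hi = _bca_adjusted_quantiles(boots, z0=0.0, a=0.0, alpha=0.05)
    np.testing.assert_allclose([lo, hi], np.quantile(boots, [0.025, 0.975]), atol=1e-12)


def test_bca_close_to_scipy_reference():
    from scipy.stats import bootstrap as scipy_bootstrap

    rng = np.random.default_rng(12)
    data = rng.normal(1.0, 2.0, 80)
    lo, hi = bca_interval(data, lambda rows: float(np.mean(rows)), n_boot=4000, rng=1)
    ref = scipy_bootstrap((data,), np.mean, method="BCa", n_resamples=4000, random_state=1)
    assert lo == pytest.approx(ref.confidence_interval.low, abs=0.1)
    assert hi == pytest.approx(ref.confidence_interval.high, abs=0.1)
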