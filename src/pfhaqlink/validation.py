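"""Cross-validation battery for a score crosswalk.

Agreement between observed and crosswalk-predicted totals is summarized
with the intraclass correlation ICC(A,1) — two-way model, absolute
agreement, single measurement — and with Bland-Altman limits of
agreement.  Longitudinal validity compares observed and predicted
6-month change scores: Cohen's d for the whole cohort, and the relative
validity RV = F_predicted / F_observed from one-way ANOVAs of change on
DAS28 responder status (good response: improvement >= 1.2 and final
score <= 3.2), with 95% bias-corrected and accelerated (BCa) bootstrap
confidence intervals over persons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "BlandAltman",
    "ResponderRule",
    "ValidityEntry",
    "icc_a1",
    "bland_altman",
    "bland_altman_plot",
    "classify_responder",
    "effect_size_change",
    "anova_f",
    "relative_validity",
    "bca_interval",
]


@dataclass(frozen=True)
class AgreementReport:
    """ICC(A,1) with F-based 95% CI plus paired summary statistics."""

    icc: float
    ci: tuple[float, float]
    mean_observed: float
    sd_observed: float
    mean_predicted: float
    sd_predicted: float
    mean_difference: float
    sd_difference: float
    loa: tuple[float, float]

    @property
    def adequate_for_group_level(self) -> bool:
        """Group-level use is conventionally supported when ICC >= 0.70."""
        return self.icc >= 0.70


def icc_a1(observed: np.ndarray, predicted: np.ndarray, alpha: float = 0.05) -> AgreementReport:
    """ICC(A,1): two-way, absolute agreement, single measurement.

    Computed from the two-way ANOVA mean squares for n subjects by k = 2
    raters (observed and predicted scores play the role of raters); the
    confidence interval is the standard F-based interval for the (A,1)
    estimator.  Differences follow the observed-minus-predicted
    convention.
    """
    x = np.asarray(observed, float)
    y = np.asarray(predicted, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two paired 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    data = np.stack([x, y], axis=1)
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    if np.allclose(data, grand):
        raise ValueError("ICC undefined: no variance in either measurement")
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    mse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2) / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))

    # F-based interval (McGraw & Wong) for absolute agreement, single measures
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        denom_extra = k * msc + (k * n - k - n) * mse
        lower = n * (msr - f_l * mse) / (f_l * denom_extra + n * msr)
        upper = n * (f_u * msr - mse) / (denom_extra + n * f_u * msr)
    else:
        lower = upper = 1.0

    d = x - y
    return AgreementReport(
        icc=float(icc),
        ci=(float(lower), float(upper)),
        mean_observed=float(x.mean()),
        sd_observed=float(x.std(ddof=1)),
        mean_predicted=float(y.mean()),
        sd_predicted=float(y.std(ddof=1)),
        mean_difference=float(d.mean()),
        sd_difference=float(d.std(ddof=1)),
        loa=(
            float(d.mean() - 1.96 * d.std(ddof=1)),
            float(d.mean() + 1.96 * d.std(ddof=1)),
        ),
    )


@dataclass(frozen=True)
class BlandAltman:
    """Per-pair differences and means with 95% limits of agreement."""

    differences: np.ndarray
    means: np.ndarray
    mean_difference: float
    sd_difference: float
    loa: tuple[float, float]


def bland_altman(observed: np.ndarray, predicted: np.ndarray) -> BlandAltman:
    """Bland-Altman method-comparison summary (observed minus predicted)."""
    x = np.asarray(observed, float)
    y = np.asarray(predicted, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two paired 1-D vectors with at least 2 pairs")
    d = x - y
    m = (x + y) / 2
    sd = float(d.std(ddof=1))
    md = float(d.mean())
    return BlandAltman(
        differences=d,
        means=m,
        mean_difference=md,
        sd_difference=sd,
        loa=(md - 1.96 * sd, md + 1.96 * sd),
    )


def bland_altman_plot(panels: Sequence[tuple[str, BlandAltman]], path: str | None = None):
    """Multi-panel Bland-Altman figure (one panel per scale direction)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ncols = 2
    nrows = (len(panels) + 1) // 2
    fig, axes = plt.subplots(nrows, ncols, figsize=(5 * ncols, 4 * nrows), squeeze=False)
    for ax, (title, ba) in zip(axes.ravel(), panels):
        ax.scatter(ba.means, ba.differences, s=12, alpha=0.6)
        ax.axhline(ba.mean_difference, color="k")
        for v in ba.loa:
            ax.axhline(v, color="k", linestyle="--")
        ax.set_title(title)
        ax.set_xlabel("mean of observed and predicted")
        ax.set_ylabel("observed - predicted")
    for ax in axes.ravel()[len(panels) :]:
        ax.set_visible(False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


@dataclass(frozen=True)
class ResponderRule:
    """DAS28 good-response rule: improvement and final-score thresholds."""

    improvement: float = 1.2
    final: float = 3.2


def classify_responder(
    das28_baseline: float | np.ndarray,
    das28_followup: float | np.ndarray,
    rule: ResponderRule = ResponderRule(),
) -> np.ndarray:
    """Good responder iff baseline - followup >= improvement and followup <= final.

    Vectorized; NaN in either value yields False (unclassifiable persons
    should be excluded upstream).
    """
    b = np.asarray(das28_baseline, float)
    f = np.asarray(das28_followup, float)
    ok = np.isfinite(b) & np.isfinite(f)
    good = ok & (b - f >= rule.improvement) & (f <= rule.final)
    return good if good.ndim else bool(good)


def effect_size_change(
    baseline: np.ndarray,
    followup: np.ndarray,
    *,
    improvement_positive: bool = True,
    higher_is_better: bool = False,
    denominator: str = "baseline",
) -> float:
    """Cohen's d for baseline-to-follow-up change.

    d = mean(change) / SD(baseline) by default (``denominator="change"``
    uses the change-score SD).  With ``improvement_positive`` the sign is
    flipped as needed so that improvement is positive: for
    disability-coded scales (higher = worse) improvement is a score
    decrease, for function-coded scales an increase.
    """
    b = np.asarray(baseline, float)
    f = np.asarray(followup, float)
    if b.shape != f.shape or b.ndim != 1:
        raise ValueError("need paired 1-D vectors")
    change = f - b
    if denominator == "baseline":
        sd = b.std(ddof=1)
    elif denominator == "change":
        sd = change.std(ddof=1)
    else:
        raise ValueError("denominator must be 'baseline' or 'change'")
    if sd == 0:
        raise ValueError("zero SD in the effect-size denominator")
    d = change.mean() / sd
    if improvement_positive and not higher_is_better:
        d = -d
    return float(d)


def anova_f(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way ANOVA F statistic of values on a grouping vector."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise ValueError("need at least two groups with >= 2 members each")
    return float(stats.f_oneway(*samples).statistic)


def bca_interval(
    data: np.ndarray,
    statistic: Callable[[np.ndarray], float],
    *,
    n_boot: int = 2000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """BCa bootstrap CI of a statistic over rows of ``data``.

    Bias correction z0 comes from the proportion of bootstrap replicates
    below the point estimate; acceleration from the jackknife.  With
    z0 = 0 and acceleration 0 the interval reduces to the percentile
    interval.  Resamples producing a non-finite statistic (e.g. a
    degenerate group) are redrawn.
    """
    rng = np.random.default_rng(rng)
    data = np.asarray(data)
    n = data.shape[0]
    theta_hat = statistic(data)

    boots = np.empty(n_boot)
    redraws = 0
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            v = statistic(data[idx])
            if np.isfinite(v):
                boots[i] = v
                break
            redraws += 1
            if redraws > 100 * n_boot:
                raise RuntimeError("bootstrap statistic non-finite in nearly all resamples")

    # bias correction
    prop = np.mean(boots < theta_hat)
    prop = min(max(prop, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
    z0 = stats.norm.ppf(prop)

    # jackknife acceleration
    jack = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        jack[i] = statistic(data[mask])
        mask[i] = True
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0

    return _bca_adjusted_quantiles(boots, z0, a, alpha)


def _bca_adjusted_quantiles(
    boots: np.ndarray, z0: float, a: float, alpha: float
) -> tuple[float, float]:
    """Endpoint selection of the BCa interval; with z0 = a = 0 this is
    exactly the percentile interval."""
    z = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = stats.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
    lo, hi = np.quantile(boots, adj)
    return float(lo), float(hi)


@dataclass(frozen=True)
class ValidityEntry:
    """Longitudinal-validity summary for one measure."""

    effect_size: float
    mean_change_by_group: dict[str, tuple[float, float]]
    f_observed: float
    f_predicted: float
    rv: float
    rv_ci: tuple[float, float]
    n_boot: int
    seed: int | None


def relative_validity(
    changes_predicted: np.ndarray,
    changes_observed: np.ndarray,
    good_responder: np.ndarray,
    *,
    n_boot: int = 2000,
    seed: int | None = None,
) -> ValidityEntry:
    """Relative validity of predicted vs observed change scores.

    RV = F_predicted / F_observed from one-way ANOVAs of the change
    scores on responder status, with a seeded 95% BCa bootstrap CI
    resampling persons (keeping each person's predicted change, observed
    change and group label together).
    """
    cp = np.asarray(changes_predicted, float)
    co = np.asarray(changes_observed, float)
    g = np.asarray(good_responder, bool)
    if not (cp.shape == co.shape == g.shape) or cp.ndim != 1:
        raise ValueError("need three aligned 1-D vectors")

    def stat(rows: np.ndarray) -> float:
        grp = rows[:, 2].astype(bool)
        if grp.sum() < 2 or (~grp).sum() < 2:
            return np.nan
        f_p = anova_f(rows[:, 0], grp)
        f_o = anova_f(rows[:, 1], grp)
        return f_p / f_o if f_o > 0 else np.nan

    data = np.column_stack([cp, co, g.astype(float)])
    f_pred = anova_f(cp, g)
    f_obs = anova_f(co, g)
    ci = bca_interval(data, stat, n_boot=n_boot, rng=seed)

    d_total = float(np.mean(co))  # raw mean change; Cohen's d is computed upstream per scale
    groups = {
        "good": (float(co[g].mean()), float(co[g].std(ddof=1))),
        "non_or_moderate": (float(co[~g].mean()), float(co[~g].std(ddof=1))),
    }
    return ValidityEntry(
        effect_size=d_total,
        mean_change_by_group=groups,
        f_observed=f_obs,
        f_predicted=f_pred,
        rv=f_pred / f_obs,
        rv_ci=ci,
        n_boot=n_boot,
        seed=seed,
    )
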