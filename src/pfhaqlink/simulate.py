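"""Synthetic item-level data with the structure the linking analysis assumes.

The generator emulates a rheumatoid-arthritis registry cohort that
completed both instruments: a unidimensional (or correlated
two-dimensional, rho defaulting to 0.73) latent disability trait with
standard-normal margins; PF-10 items targeted at somewhat better
function than the HAQ-DI categories (the HAQ measures worse-function
levels more precisely); aids/devices use increasing with disability so
that standard HAQ scoring (SDI) is at least the alternative scoring
(ADI); and a 6-month follow-up in which improvement concentrates in
DAS28 good responders.

Scenario defaults mirror the cohorts the crosswalk methodology targets:
a calibration-like sample of n = 1791 and a cross-validation-like cohort
of n = 532 at baseline / n = 276 longitudinal with better baseline
function (latent mean shifted by -0.5) and roughly half good responders.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .irt import ItemParams, _probs
from .linking import HAQ_CATEGORY_IDS, PF10_ITEM_IDS
from .instruments import HAQ_CATEGORIES

__all__ = [
    "SimulationConfig",
    "Dataset",
    "LongitudinalDataset",
    "default_item_params",
    "simulate_thetas",
    "simulate_responses",
    "simulate_dataset",
    "simulate_longitudinal",
]


def default_item_params(
    two_dimensional: bool = False,
    pf_discriminations: np.ndarray | None = None,
    haq_discriminations: np.ndarray | None = None,
) -> list[ItemParams]:
    """Stylized generating parameters for the 18 "items".

    PF-10 item locations span lower (better-function) latent levels and
    HAQ-DI category locations are shifted toward worse function, so the
    two test-information curves peak at different disability levels.
    Threshold layouts are stylized, not estimates from any cohort.
    """
    pf_loc = np.linspace(-1.6, 0.8, 10)
    haq_loc = np.linspace(-0.8, 1.6, 8)
    pf_a = np.ones(10) if pf_discriminations is None else np.asarray(pf_discriminations, float)
    haq_a = np.ones(8) if haq_discriminations is None else np.asarray(haq_discriminations, float)
    items = [
        ItemParams(item_id=pid, thresholds=loc + np.array([-0.7, 0.7]), discrimination=a)
        for pid, loc, a in zip(PF10_ITEM_IDS, pf_loc, pf_a)
    ]
    items += [
        ItemParams(
            item_id=cid,
            thresholds=loc + np.array([-1.0, 0.0, 1.0]),
            discrimination=a,
            dimension=2 if two_dimensional else 1,
        )
        for cid, loc, a in zip(HAQ_CATEGORY_IDS, haq_loc, haq_a)
    ]
    return items


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for the synthetic cohorts."""

    n: int = 1791
    two_dimensional: bool = False
    rho: float = 0.73
    theta_shift: float = 0.0
    aid_intercept: float = -2.0
    aid_slope: float = 1.0
    # longitudinal block
    n_longitudinal: int = 276
    good_fraction: float = 134 / 276
    improvement_good: float = 0.9
    improvement_other: float = 0.1
    followup_noise_sd: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not -1 < self.rho < 1:
            raise ValueError("rho must be in (-1, 1)")
        if not 0 <= self.good_fraction <= 1:
            raise ValueError("good_fraction must be a probability")


@dataclass(frozen=True)
class Dataset:
    """One simulated cross-sectional assessment."""

    pf10: np.ndarray  # (n, 10), original 1-3 coding
    haq_items: np.ndarray  # (n, 20), 0-3
    aid_flags: np.ndarray  # (n, 8), bool
    thetas: np.ndarray  # (n, 1) or (n, 2)


@dataclass(frozen=True)
class LongitudinalDataset:
    baseline: Dataset
    followup: Dataset
    das28_baseline: np.ndarray
    das28_followup: np.ndarray
    good_responder: np.ndarray


def simulate_thetas(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent disability draws: (n, 1) or correlated (n, 2)."""
    if config.two_dimensional:
        cov = np.array([[1.0, config.rho], [config.rho, 1.0]])
        th = rng.multivariate_normal(np.zeros(2), cov, size=config.n)
    else:
        th = rng.standard_normal((config.n, 1))
    return th + config.theta_shift


def _draw_categorical(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise categorical draw from an (n, m) probability matrix."""
    u = rng.random(p.shape[0])
    return (p.cumsum(axis=1) < u[:, None]).sum(axis=1)


def simulate_responses(
    thetas: np.ndarray,
    items: list[ItemParams],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Dataset:
    """Item-level PF-10 and HAQ-DI responses plus aid/device flags.

    PF-10 responses are drawn per item from the adjacent-category model
    and stored in the original 1-3 coding.  For each HAQ category the
    category score (its intended item maximum) is drawn from the model,
    one of the category's items is set to that maximum and the rest are
    drawn uniformly below it.  Aid flags follow a logistic model in the
    latent disability, so flag prevalence rises with disability and
    SDI >= ADI by construction of the scoring rule.
    """
    thetas = np.atleast_2d(thetas)
    n = thetas.shape[0]
    pf_items = [it for it in items if it.item_id in PF10_ITEM_IDS]
    haq_items_p = [it for it in items if it.item_id in HAQ_CATEGORY_IDS]

    pf = np.empty((n, 10), dtype=int)
    for j, it in enumerate(pf_items):
        th = thetas[:, it.dimension - 1] if thetas.shape[1] > 1 else thetas[:, 0]
        p = _probs(th, it.discrimination, it.thresholds)
        pf[:, j] = 3 - _draw_categorical(p, rng)  # back to 1-3, higher = better

    haq = np.zeros((n, 20), dtype=int)
    theta_haq = thetas[:, -1] if thetas.shape[1] > 1 else thetas[:, 0]
    for c, (it, (_, idx)) in enumerate(zip(haq_items_p, HAQ_CATEGORIES)):
        th = thetas[:, it.dimension - 1] if thetas.shape[1] > 1 else thetas[:, 0]
        p = _probs(th, it.discrimination, it.thresholds)
        cat_score = _draw_categorical(p, rng)
        cols = list(idx)
        # one item carries the category maximum; the rest fall uniformly below it
        carrier = rng.integers(0, len(cols), n)
        for pos, col in enumerate(cols):
            haq[:, col] = np.where(carrier == pos, cat_score, rng.integers(0, cat_score + 1))

    flags = rng.random((n, 8)) < expit(config.aid_intercept + config.aid_slope * theta_haq)[:, None]
    return Dataset(pf10=pf, haq_items=haq, aid_flags=flags, thetas=thetas)


def simulate_dataset(
    config: SimulationConfig, items: list[ItemParams] | None = None
) -> Dataset:
    """Cross-sectional cohort under the configured latent structure."""
    rng = np.random.default_rng(config.seed)
    if items is None:
        items = default_item_params(two_dimensional=config.two_dimensional)
    thetas = simulate_thetas(config, rng)
    return simulate_responses(thetas, items, config, rng)


def simulate_longitudinal(
    config: SimulationConfig, items: list[ItemParams] | None = None
) -> LongitudinalDataset:
    """Baseline + 6-month follow-up with DAS28 responder structure.

    Follow-up latent disability is baseline minus a group-specific
    improvement plus noise; DAS28 pairs are generated to satisfy (good
    responders) or fail (others) the good-response rule by construction.
    """
    rng = np.random.default_rng(config.seed)
    if items is None:
        items = default_item_params(two_dimensional=config.two_dimensional)
    cfg_n = replace(config, n=config.n_longitudinal)
    theta0 = simulate_thetas(cfg_n, rng)
    n = cfg_n.n
    good = rng.random(n) < config.good_fraction
    improvement = np.where(good, config.improvement_good, config.improvement_other)
    theta1 = theta0 - improvement[:, None] + rng.normal(0, config.followup_noise_sd, theta0.shape)

    baseline = simulate_responses(theta0, items, cfg_n, rng)
    followup = simulate_responses(theta1, items, cfg_n, rng)

    das_final = np.empty(n)
    das_base = np.empty(n)
    ng = int(good.sum())
    das_final[good] = rng.uniform(1.6, 3.2, ng)
    das_base[good] = np.minimum(das_final[good] + 1.2 + np.abs(rng.normal(0.9, 0.6, ng)), 9.9)
    n_other = n - ng
    base_o = np.clip(rng.normal(4.3, 1.2, n_other), 1.0, 10.0)
    impr_o = rng.normal(0.3, 0.5, n_other)
    final_o = np.clip(base_o - impr_o, 0.3, 10.0)
    # repair accidental good responses among the "other" group
    bad = (base_o - final_o >= 1.2) & (final_o <= 3.2)
    final_o[bad] = base_o[bad] - 0.8
    das_base[~good] = base_o
    das_final[~good] = final_o

    return LongitudinalDataset(
        baseline=baseline,
        followup=followup,
        das28_baseline=das_base,
        das28_followup=das_final,
        good_responder=good,
    )
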