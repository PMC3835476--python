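"""Polytomous IRT estimation: PCM, GPCM, and a between-item 2-D GPCM.

All models are adjacent-category logit models for ordered responses
X_j in {0, ..., m_j - 1}:

    P(X_j = k | theta) ∝ exp( sum_{h<=k} a_j (theta_d(j) - b_jh) )

with discrimination a_j (fixed at 1 under the partial credit model) and
thresholds b_j1..b_j,m_j-1.  The latent trait is oriented so that higher
theta means worse physical function.  Structural parameters are estimated
by marginal maximum likelihood via EM over a fixed rectangular quadrature
grid; the latent prior per dimension is standard normal (identification),
and in the two-dimensional between-item model the inter-dimension
correlation rho is estimated by profile likelihood on a grid.

Person scoring uses the expected a posteriori (EAP) method; summed-score
EAP tables are computed with the Lord-Wingersky recursion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .instruments import MISSING

__all__ = [
    "ModelKind",
    "ItemParams",
    "CalibrationModel",
    "CalibrationResult",
    "QuadratureGrid",
    "ThetaEstimate",
    "ScoreTable",
    "category_probabilities",
    "expected_item_score",
    "item_score_variance",
    "fit_calibration",
    "eap_pattern",
    "eap_patterns",
    "sum_score_posterior",
    "sum_score_eap_table",
    "test_information",
]

logger = logging.getLogger(__name__)


class ModelKind(str, Enum):
    PCM = "PCM"
    GPCM = "GPCM"
    MIRT2 = "MIRT2"


@dataclass(frozen=True)
class ItemParams:
    """Parameters of one polytomous item.

    ``thresholds`` are the m_j - 1 adjacent-category crossing locations
    b_jh on the latent scale; ``dimension`` is 1-based and only relevant
    for the two-dimensional model.
    """

    item_id: str
    thresholds: np.ndarray
    discrimination: float = 1.0
    dimension: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds", np.atleast_1d(np.asarray(self.thresholds, float)))
        if self.thresholds.ndim != 1 or self.thresholds.size < 1:
            raise ValueError("need at least one threshold")
        if not self.discrimination > 0:
            raise ValueError(f"discrimination must be > 0, got {self.discrimination}")
        if self.dimension not in (1, 2):
            raise ValueError("dimension must be 1 or 2")

    @property
    def n_categories(self) -> int:
        return self.thresholds.size + 1


@dataclass(frozen=True)
class CalibrationModel:
    """Model specification for a calibration run."""

    kind: ModelKind = ModelKind.PCM
    dimensions: tuple[int, ...] | None = None  # per-item, 1-based; None = all on dim 1
    rho_init: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ModelKind(self.kind))
        if self.kind is ModelKind.MIRT2 and self.dimensions is None:
            raise ValueError("MIRT2 requires per-item dimension assignments")


@dataclass(frozen=True)
class QuadratureGrid:
    """Rectangular quadrature for the latent prior (1-D or 2-D product).

    ``nodes`` is the shared per-dimension node vector; ``weights`` is the
    normalized prior mass (length Q in 1-D, Q x Q in 2-D with correlation
    ``rho``).
    """

    nodes: np.ndarray
    weights: np.ndarray
    rho: float | None = None

    @classmethod
    def make(cls, n_nodes: int = 61, bound: float = 6.0, rho: float | None = None) -> "QuadratureGrid":
        nodes = np.linspace(-bound, bound, n_nodes)
        if rho is None:
            w = stats.norm.pdf(nodes)
            return cls(nodes=nodes, weights=w / w.sum())
        w = _bivariate_weights(nodes, rho)
        return cls(nodes=nodes, weights=w, rho=rho)

    def with_rho(self, rho: float) -> "QuadratureGrid":
        return QuadratureGrid(nodes=self.nodes, weights=_bivariate_weights(self.nodes, rho), rho=rho)

    @property
    def marginal_weights(self) -> np.ndarray:
        """Per-dimension marginal prior mass (equals weights in 1-D)."""
        if self.weights.ndim == 1:
            return self.weights
        return self.weights.sum(axis=1)


def _bivariate_weights(nodes: np.ndarray, rho: float) -> np.ndarray:
    if not -1 < rho < 1:
        raise ValueError(f"rho must be in (-1, 1), got {rho}")
    x = nodes[:, None]
    y = nodes[None, :]
    q = (x**2 - 2 * rho * x * y + y**2) / (1 - rho**2)
    w = np.exp(-0.5 * q)
    return w / w.sum()


@dataclass(frozen=True)
class ThetaEstimate:
    """EAP estimate: posterior mean(s) and SD(s), one entry per dimension."""

    eap: np.ndarray
    posterior_sd: np.ndarray


@dataclass(frozen=True)
class ScoreTable:
    """Summed score -> EAP concordance for one instrument.

    Scores are in the disability-coded summed metric (higher = worse
    function); ``eap`` is strictly increasing in the score.
    """

    instrument: str
    scores: np.ndarray
    eap: np.ndarray
    posterior_sd: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.eap) > 0):
            raise ValueError("score-table EAPs must be strictly increasing in the summed score")


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted item parameters plus estimation metadata."""

    model: CalibrationModel
    items: tuple[ItemParams, ...]
    log_likelihood: float
    rho: float | None
    n_iterations: int
    converged: bool
    loglik_trace: np.ndarray
    grid: QuadratureGrid


# ---------------------------------------------------------------------------
# Model primitives


def category_probabilities(theta: float | np.ndarray, item: ItemParams) -> np.ndarray:
    """Category probabilities of an adjacent-category item at theta.

    Returns shape (m_j,) for scalar theta, else (len(theta), m_j).
    """
    th = np.asarray(theta, float)
    if not np.all(np.isfinite(th)):
        raise ValueError("theta must be finite")
    scalar = th.ndim == 0
    th = np.atleast_1d(th)
    p = _probs(th, item.discrimination, item.thresholds)
    return p[0] if scalar else p


def _probs(theta: np.ndarray, a: float, b: np.ndarray) -> np.ndarray:
    """(Q, m) category probabilities; numerically stable."""
    steps = a * (theta[:, None] - b[None, :])
    psi = np.concatenate([np.zeros((theta.size, 1)), np.cumsum(steps, axis=1)], axis=1)
    psi -= psi.max(axis=1, keepdims=True)
    p = np.exp(psi)
    p /= p.sum(axis=1, keepdims=True)
    return p


def expected_item_score(theta: float | np.ndarray, item: ItemParams) -> np.ndarray:
    p = category_probabilities(theta, item)
    k = np.arange(item.n_categories)
    return p @ k


def item_score_variance(theta: float | np.ndarray, item: ItemParams) -> np.ndarray:
    p = category_probabilities(theta, item)
    k = np.arange(item.n_categories)
    m1 = p @ k
    return p @ (k**2) - m1**2


def test_information(items: Sequence[ItemParams], theta: np.ndarray) -> np.ndarray:
    """Test information curve I(theta) = sum_j a_j^2 Var(X_j | theta)."""
    theta = np.atleast_1d(np.asarray(theta, float))
    info = np.zeros_like(theta)
    for it in items:
        info += it.discrimination**2 * item_score_variance(theta, it)
    return info


test_information.__test__ = False  # "test information" is the psychometric term, not a pytest item


# ---------------------------------------------------------------------------
# Marginal maximum likelihood (EM)


def _item_prob_tables(items: Sequence[ItemParams], nodes: np.ndarray) -> list[np.ndarray]:
    return [_probs(nodes, it.discrimination, it.thresholds) for it in items]


def _pattern_likelihood(
    responses: np.ndarray, tables: list[np.ndarray], cols: Sequence[int]
) -> np.ndarray:
    """(n, Q) likelihood of each person's responses over the node grid.

    Missing responses (MISSING sentinel) contribute a factor of 1.
    """
    n = responses.shape[0]
    Q = tables[0].shape[0]
    L = np.ones((n, Q))
    for t, j in zip(tables, cols):
        x = responses[:, j]
        obs = x != MISSING
        L[obs] *= t[:, x[obs]].T
    return L


def _complete_loglik_item(params: np.ndarray, r: np.ndarray, nodes: np.ndarray, free_a: bool):
    """Negative expected complete-data loglik and gradient for one item.

    ``params`` = thresholds, prefixed by log-discrimination when free_a.
    ``r`` is the (Q, m) expected count table from the E-step.
    """
    if free_a:
        a = float(np.exp(params[0]))
        b = params[1:]
    else:
        a = 1.0
        b = params
    p = _probs(nodes, a, b)
    ll = float(np.sum(r * np.log(np.clip(p, 1e-300, None))))
    nq = r.sum(axis=1)
    # gradient wrt b_h: -a * sum_q (r_ge[q,h] - n_q * p_ge[q,h])
    r_ge = np.cumsum(r[:, ::-1], axis=1)[:, ::-1][:, 1:]
    p_ge = np.cumsum(p[:, ::-1], axis=1)[:, ::-1][:, 1:]
    gb = -a * (r_ge.sum(axis=0) - nq @ p_ge)
    if free_a:
        m = r.shape[1]
        # t_k(q) = sum_{h<=k} (theta_q - b_h)
        t = np.concatenate(
            [np.zeros((nodes.size, 1)), np.cumsum(nodes[:, None] - b[None, :], axis=1)], axis=1
        )
        tbar = np.sum(p * t, axis=1)
        ga = a * (np.sum(r * t) - nq @ tbar)
        g = np.concatenate([[ga], gb])
    else:
        g = gb
    return -ll, -g


def _mstep_item(item: ItemParams, r: np.ndarray, nodes: np.ndarray, free_a: bool) -> ItemParams:
    if free_a:
        x0 = np.concatenate([[np.log(item.discrimination)], item.thresholds])
    else:
        x0 = item.thresholds.copy()
    res = optimize.minimize(
        _complete_loglik_item, x0, args=(r, nodes, free_a), jac=True, method="L-BFGS-B"
    )
    x = res.x
    if free_a:
        return replace(item, discrimination=float(np.exp(x[0])), thresholds=x[1:])
    return replace(item, thresholds=x)


def _profile_rho(L1: np.ndarray, L2: np.ndarray, nodes: np.ndarray, grid: np.ndarray) -> tuple[float, float]:
    """Maximize the marginal loglik over rho on a grid; returns (rho, loglik)."""
    best = (-np.inf, 0.0)
    for rho in grid:
        W = _bivariate_weights(nodes, rho)
        s = np.sum((L1 @ W) * L2, axis=1)
        ll = float(np.sum(np.log(np.clip(s, 1e-300, None))))
        if ll > best[0]:
            best = (ll, float(rho))
    return best[1], best[0]


def fit_calibration(
    responses: np.ndarray,
    items: Sequence[ItemParams],
    model: CalibrationModel | ModelKind | str = ModelKind.PCM,
    *,
    n_nodes: int = 61,
    bound: float = 6.0,
    tol: float = 1e-4,
    max_iter: int = 500,
    min_n: int = 100,
    on_unobserved: str = "collapse",
) -> CalibrationResult:
    """Marginal maximum likelihood fit by EM over a rectangular grid.

    ``responses`` is an (n, J) integer matrix of category scores with the
    MISSING sentinel for absent responses; ``items`` supplies ids,
    category counts and starting values (thresholds default to 0 works).
    Identification fixes the latent prior standard normal per dimension;
    under PCM all discriminations are fixed at 1.

    ``on_unobserved``: "collapse" merges an unobserved category into its
    lower neighbour (with a warning); "strict" raises.
    """
    if isinstance(model, (str, ModelKind)):
        model = CalibrationModel(kind=ModelKind(model))
    responses = np.asarray(responses, dtype=int)
    n, J = responses.shape
    if J != len(items):
        raise ValueError(f"responses have {J} columns but {len(items)} items given")
    if n < min_n:
        raise ValueError(f"need at least {min_n} persons for a stable calibration, got {n}")

    items = [it for it in items]
    if model.kind is ModelKind.MIRT2:
        dims = model.dimensions
        if len(dims) != J:
            raise ValueError("dimension assignment length must equal item count")
        items = [replace(it, dimension=d) for it, d in zip(items, dims)]
    else:
        items = [replace(it, dimension=1) for it in items]

    items, responses = _check_categories(items, responses, on_unobserved)
    free_a = model.kind is not ModelKind.PCM

    nodes = np.linspace(-bound, bound, n_nodes)
    two_dim = model.kind is ModelKind.MIRT2
    rho = float(model.rho_init) if two_dim else None

    w1 = stats.norm.pdf(nodes)
    w1 = w1 / w1.sum()

    cols1 = [j for j, it in enumerate(items) if it.dimension == 1]
    cols2 = [j for j, it in enumerate(items) if it.dimension == 2]
    if two_dim and (not cols1 or not cols2):
        raise ValueError("MIRT2 needs items on both dimensions")

    trace: list[float] = []
    converged = False
    it_count = 0
    coarse_rho_grid = np.arange(-0.9, 0.91, 0.05)

    for it_count in range(1, max_iter + 1):
        tables = _item_prob_tables(items, nodes)
        if not two_dim:
            L = _pattern_likelihood(responses, tables, range(J))
            marg = L @ w1
            ll = float(np.sum(np.log(np.clip(marg, 1e-300, None))))
            post = L * w1[None, :]
            post /= post.sum(axis=1, keepdims=True)
            post_by_dim = {1: post}
        else:
            L1 = _pattern_likelihood(responses[:, cols1], [tables[j] for j in cols1], range(len(cols1)))
            L2 = _pattern_likelihood(responses[:, cols2], [tables[j] for j in cols2], range(len(cols2)))
            W = _bivariate_weights(nodes, rho)
            A2 = L2 @ W.T  # (n, Q1): integrates dim-2 out
            A1 = L1 @ W  # (n, Q2)
            marg = np.sum(L1 * A2, axis=1)
            ll = float(np.sum(np.log(np.clip(marg, 1e-300, None))))
            post1 = L1 * A2 / marg[:, None]
            post2 = L2 * A1 / marg[:, None]
            post_by_dim = {1: post1, 2: post2}

        trace.append(ll)

        new_items = []
        max_change = 0.0
        for j, item in enumerate(items):
            post = post_by_dim[item.dimension]
            x = responses[:, j]
            r = np.zeros((n_nodes, item.n_categories))
            for k in range(item.n_categories):
                mask = x == k
                if mask.any():
                    r[:, k] = post[mask].sum(axis=0)
            new = _mstep_item(item, r, nodes, free_a)
            max_change = max(
                max_change,
                float(np.max(np.abs(new.thresholds - item.thresholds))),
                abs(new.discrimination - item.discrimination),
            )
            new_items.append(new)
        items = new_items

        if two_dim:
            tables = _item_prob_tables(items, nodes)
            L1 = _pattern_likelihood(responses[:, cols1], [tables[j] for j in cols1], range(len(cols1)))
            L2 = _pattern_likelihood(responses[:, cols2], [tables[j] for j in cols2], range(len(cols2)))
            new_rho, _ = _profile_rho(L1, L2, nodes, coarse_rho_grid)
            max_change = max(max_change, abs(new_rho - rho))
            rho = new_rho

        if max_change < tol:
            converged = True
            break

    if two_dim:
        # profile-likelihood refinement of rho: 0.01 grid, then one 0.001 pass
        tables = _item_prob_tables(items, nodes)
        L1 = _pattern_likelihood(responses[:, cols1], [tables[j] for j in cols1], range(len(cols1)))
        L2 = _pattern_likelihood(responses[:, cols2], [tables[j] for j in cols2], range(len(cols2)))
        rho, _ = _profile_rho(L1, L2, nodes, np.arange(-0.94, 0.95, 0.01))
        fine = np.arange(max(-0.949, rho - 0.01), min(0.949, rho + 0.01) + 1e-9, 0.001)
        rho, ll = _profile_rho(L1, L2, nodes, fine)
        trace.append(ll)

    if not converged:
        raise RuntimeError(
            f"EM did not converge in {max_iter} iterations "
            f"(last loglik {trace[-1]:.4f}); trace available in exception args",
            np.asarray(trace),
        )

    grid = QuadratureGrid.make(n_nodes, bound, rho=rho)
    return CalibrationResult(
        model=model,
        items=tuple(items),
        log_likelihood=trace[-1],
        rho=rho,
        n_iterations=it_count,
        converged=converged,
        loglik_trace=np.asarray(trace),
        grid=grid,
    )


def _check_categories(items, responses, on_unobserved):
    """Collapse (or reject) categories never observed in the data."""
    out_items = []
    responses = responses.copy()
    for j, it in enumerate(items):
        x = responses[:, j]
        observed = np.zeros(it.n_categories, dtype=bool)
        vals = x[x != MISSING]
        if vals.min(initial=0) < 0 or vals.max(initial=0) >= it.n_categories:
            raise ValueError(f"item {it.item_id}: responses outside 0..{it.n_categories - 1}")
        observed[np.unique(vals)] = True
        if observed.sum() < 2:
            raise ValueError(f"item {it.item_id}: fewer than 2 observed categories")
        if observed.all():
            out_items.append(it)
            continue
        if on_unobserved == "strict":
            raise ValueError(f"item {it.item_id}: unobserved categories {np.flatnonzero(~observed).tolist()}")
        logger.warning(
            "item %s: collapsing unobserved categories %s",
            it.item_id,
            np.flatnonzero(~observed).tolist(),
        )
        # relabel observed categories consecutively; thresholds shrink to match
        relabel = np.cumsum(observed) - 1
        obs = x != MISSING
        x[obs] = relabel[x[obs]]
        responses[:, j] = x
        out_items.append(replace(it, thresholds=it.thresholds[: observed.sum() - 1]))
    return out_items, responses


# ---------------------------------------------------------------------------
# EAP scoring


def eap_patterns(
    responses: np.ndarray, items: Sequence[ItemParams], grid: QuadratureGrid
) -> ThetaEstimate:
    """EAP estimates for each row of a response matrix.

    For a 2-D grid the two dimension-specific EAPs are estimated
    concurrently under the joint bivariate prior.
    """
    responses = np.asarray(responses, dtype=int)
    if np.all(responses == MISSING, axis=1).any():
        raise ValueError("at least one response pattern is entirely missing")
    nodes = grid.nodes
    tables = _item_prob_tables(items, nodes)
    if grid.weights.ndim == 1:
        L = _pattern_likelihood(responses, tables, range(len(items)))
        post = L * grid.weights[None, :]
        post /= post.sum(axis=1, keepdims=True)
        mean = post @ nodes
        var = post @ nodes**2 - mean**2
        return ThetaEstimate(eap=mean[:, None], posterior_sd=np.sqrt(np.clip(var, 0, None))[:, None])
    cols1 = [j for j, it in enumerate(items) if it.dimension == 1]
    cols2 = [j for j, it in enumerate(items) if it.dimension == 2]
    L1 = _pattern_likelihood(responses[:, cols1], [tables[j] for j in cols1], range(len(cols1)))
    L2 = _pattern_likelihood(responses[:, cols2], [tables[j] for j in cols2], range(len(cols2)))
    W = grid.weights
    marg = np.sum((L1 @ W) * L2, axis=1)
    post1 = L1 * (L2 @ W.T) / marg[:, None]
    post2 = L2 * (L1 @ W) / marg[:, None]
    means = np.stack([post1 @ nodes, post2 @ nodes], axis=1)
    variances = np.stack(
        [post1 @ nodes**2 - means[:, 0] ** 2, post2 @ nodes**2 - means[:, 1] ** 2], axis=1
    )
    return ThetaEstimate(eap=means, posterior_sd=np.sqrt(np.clip(variances, 0, None)))


def eap_pattern(
    pattern: Sequence[int], items: Sequence[ItemParams], grid: QuadratureGrid
) -> ThetaEstimate:
    """EAP estimate for a single response pattern."""
    est = eap_patterns(np.asarray(pattern, dtype=int)[None, :], items, grid)
    return ThetaEstimate(eap=est.eap[0], posterior_sd=est.posterior_sd[0])


# ---------------------------------------------------------------------------
# Summed-score machinery (Lord-Wingersky recursion)


def sum_score_posterior(items: Sequence[ItemParams], grid: QuadratureGrid) -> np.ndarray:
    """P(S = s | theta_q) for every node q and attainable summed score s.

    Computed by the item-by-item convolution recursion over category
    scores; requires a unidimensional item set (all items on one
    dimension with a 1-D grid).  Returns shape (Q, S_max + 1).
    """
    if grid.weights.ndim != 1:
        raise ValueError("sum_score_posterior requires a unidimensional grid")
    nodes = grid.nodes
    dist = np.ones((nodes.size, 1))
    for it in items:
        p = _probs(nodes, it.discrimination, it.thresholds)
        m = it.n_categories
        new = np.zeros((nodes.size, dist.shape[1] + m - 1))
        for k in range(m):
            new[:, k : k + dist.shape[1]] += p[:, k : k + 1] * dist
        dist = new
    return dist


def sum_score_eap_table(
    items: Sequence[ItemParams], grid: QuadratureGrid, instrument: str = ""
) -> ScoreTable:
    """Summed score -> EAP table via the recursion and the latent prior.

    theta(s) = sum_q theta_q P(s | theta_q) w_q / sum_q P(s | theta_q) w_q.
    """
    dist = sum_score_posterior(items, grid)
    w = grid.marginal_weights
    mass = w @ dist  # marginal P(S = s)
    if np.any(mass <= 0):
        raise ValueError("some attainable summed scores carry zero marginal probability")
    nodes = grid.nodes
    num = (w * nodes) @ dist
    eap = num / mass
    e2 = (w * nodes**2) @ dist / mass
    sd = np.sqrt(np.clip(e2 - eap**2, 0, None))
    scores = np.arange(dist.shape[1])
    return ScoreTable(instrument=instrument, scores=scores, eap=eap, posterior_sd=sd)
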