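"""Crosswalk construction between the PF-10 and the HAQ-DI.

The linking procedure co-calibrates the 10 (reverse-coded) PF-10 items
and the 8 HAQ-DI category scores in one polytomous IRT model, derives an
EAP scoring table per instrument for every attainable summed score with
the item parameters fixed at the joint calibration, and then links each
observed total score on one instrument to the total score on the other
whose EAP is nearest on the latent scale.  Observed scores whose EAP lies
beyond the other instrument's most extreme EAP clip to that instrument's
extreme score.  The whole procedure is run separately for the standard
(SDI) and alternative (ADI) HAQ scoring and for each of the three nested
models (PCM, GPCM, between-item two-dimensional GPCM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .instruments import (
    DEFAULT_NORM_COEFFICIENTS,
    HaqMethod,
    NormCoefficients,
    ScaleId,
    pf10_norm_based,
    reverse_pf10_items,
    score_haq_categories,
)
from .irt import (
    CalibrationModel,
    CalibrationResult,
    ItemParams,
    ModelKind,
    QuadratureGrid,
    ScoreTable,
    fit_calibration,
    sum_score_eap_table,
)

__all__ = [
    "Crosswalk",
    "LinkingResult",
    "ModelComparison",
    "co_calibrate",
    "instrument_score_tables",
    "nearest_link",
    "build_crosswalk",
    "apply_crosswalk",
    "compare_models",
    "score_haq_matrix",
]

PF10_ITEM_IDS = tuple(f"pf{i:02d}" for i in range(1, 11))
HAQ_CATEGORY_IDS = (
    "dressing_grooming",
    "rising",
    "eating",
    "walking",
    "hygiene",
    "reach",
    "grip",
    "activities",
)


@dataclass(frozen=True)
class Crosswalk:
    """Bidirectional observed-score concordance table.

    ``haq_to_pf10`` maps each of the 25 attainable HAQ-DI totals to a
    predicted PF-10 raw score (with its norm-based companion);
    ``pf10_to_haq`` maps each of the 21 attainable PF-10 raw scores to a
    predicted HAQ-DI total.  ``haq_eap`` / ``pf10_eap`` carry the latent
    locations behind each observed score when the crosswalk was built by
    this package (None for the published table, which ships as data).
    """

    method: HaqMethod
    model: ModelKind | None
    observed_haq: np.ndarray
    predicted_pf10: np.ndarray
    predicted_pf10_norm: np.ndarray
    observed_pf10: np.ndarray
    observed_pf10_norm: np.ndarray
    predicted_haq: np.ndarray
    haq_eap: np.ndarray | None = None
    pf10_eap: np.ndarray | None = None
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.observed_haq.size != 25 or self.observed_pf10.size != 21:
            raise ValueError("crosswalk must be total over the 25 HAQ and 21 PF-10 scores")
        # monotone in the disability direction: worse observed function
        # never maps to better predicted function
        if np.any(np.diff(self.predicted_pf10) > 0):  # observed_haq ascending
            raise ValueError("predicted PF-10 must be non-increasing in observed HAQ")
        if np.any(np.diff(self.predicted_haq) > 0):  # observed_pf10 ascending
            raise ValueError("predicted HAQ must be non-increasing in observed PF-10")

    def pf10_from_haq(self, haq_score: float) -> tuple[float, float]:
        """Predicted (raw, norm-based) PF-10 score for an observed HAQ total."""
        i = _lookup(self.observed_haq, haq_score, "HAQ-DI")
        return float(self.predicted_pf10[i]), float(self.predicted_pf10_norm[i])

    def haq_from_pf10(self, pf10_raw: float) -> float:
        """Predicted HAQ-DI total for an observed PF-10 raw score."""
        i = _lookup(self.observed_pf10, pf10_raw, "PF-10")
        return float(self.predicted_haq[i])


def _lookup(attainable: np.ndarray, value: float, label: str) -> int:
    hits = np.flatnonzero(np.isclose(attainable, value, atol=1e-9))
    if hits.size == 0:
        nearest = attainable[np.argmin(np.abs(attainable - value))]
        raise ValueError(
            f"{value} is not an attainable {label} score; nearest attainable value is {nearest}"
        )
    return int(hits[0])


def apply_crosswalk(crosswalk: Crosswalk, observed: float, scale: ScaleId | str):
    """Convert an observed total score through a crosswalk.

    ``scale`` names the scale of the observed value (PF10_RAW, HAQ_SDI or
    HAQ_ADI).  Returns the predicted HAQ total for a PF-10 input, or a
    (raw, norm-based) PF-10 pair for a HAQ input.
    """
    scale = ScaleId(scale)
    if scale is ScaleId.PF10_RAW:
        return crosswalk.haq_from_pf10(observed)
    if scale in (ScaleId.HAQ_SDI, ScaleId.HAQ_ADI):
        expect = HaqMethod.SDI if scale is ScaleId.HAQ_SDI else HaqMethod.ADI
        if crosswalk.method is not expect:
            raise ValueError(
                f"crosswalk uses {crosswalk.method.value} scoring but a {scale.value} score was given"
            )
        return crosswalk.pf10_from_haq(observed)
    raise ValueError(f"cannot convert from scale {scale}")


@dataclass(frozen=True)
class LinkingResult:
    """Everything produced by one end-to-end crosswalk construction."""

    calibration: CalibrationResult
    pf10_table: ScoreTable
    haq_table: ScoreTable
    crosswalk: Crosswalk


@dataclass(frozen=True)
class ModelComparison:
    """Crosswalks and agreement statistics for the three nested models."""

    results: Mapping[str, LinkingResult]
    icc: Mapping[str, Mapping[str, tuple[float, float, float]]]
    prediction_correlations: Mapping[tuple[str, str, str], float]


def score_haq_matrix(
    haq_items: np.ndarray, aid_flags: np.ndarray, method: HaqMethod | str
) -> np.ndarray:
    """Per-person 8-column HAQ category-score matrix."""
    haq_items = np.asarray(haq_items, dtype=int)
    aid_flags = np.asarray(aid_flags, dtype=bool)
    return np.array(
        [score_haq_categories(r, f, method) for r, f in zip(haq_items, aid_flags)], dtype=int
    )


def _default_items() -> list[ItemParams]:
    items = [ItemParams(item_id=i, thresholds=np.zeros(2)) for i in PF10_ITEM_IDS]
    items += [ItemParams(item_id=i, thresholds=np.zeros(3), dimension=2) for i in HAQ_CATEGORY_IDS]
    return items


def co_calibrate(
    pf10_reversed: np.ndarray,
    haq_category_scores: np.ndarray,
    model: ModelKind | str = ModelKind.PCM,
    **fit_kwargs,
) -> CalibrationResult:
    """Joint calibration of the 18 PF-10 + HAQ-DI "items".

    ``pf10_reversed`` is (n, 10) in the disability coding 0-2;
    ``haq_category_scores`` is (n, 8) in 0-3.  Under the two-dimensional
    model PF-10 items load on dimension 1 and HAQ categories on
    dimension 2.
    """
    pf10_reversed = np.asarray(pf10_reversed, dtype=int)
    haq_category_scores = np.asarray(haq_category_scores, dtype=int)
    if pf10_reversed.shape[0] != haq_category_scores.shape[0]:
        raise ValueError(
            "PF-10 and HAQ matrices must describe the same persons: "
            f"{pf10_reversed.shape[0]} vs {haq_category_scores.shape[0]} rows"
        )
    if pf10_reversed.shape[1] != 10 or haq_category_scores.shape[1] != 8:
        raise ValueError("expected 10 PF-10 columns and 8 HAQ category columns")
    responses = np.hstack([pf10_reversed, haq_category_scores])
    kind = ModelKind(model)
    if kind is ModelKind.MIRT2:
        spec = CalibrationModel(kind=kind, dimensions=(1,) * 10 + (2,) * 8)
    else:
        spec = CalibrationModel(kind=kind)
    return fit_calibration(responses, _default_items(), spec, **fit_kwargs)


def instrument_score_tables(
    calibration: CalibrationResult,
) -> tuple[ScoreTable, ScoreTable]:
    """Instrument-specific summed-score EAP tables at the joint parameters.

    The item parameters stay fixed at the co-calibration values.  Under
    the two-dimensional model each instrument's table is computed on its
    own dimension; because each latent margin of the joint prior is
    standard normal, the table integrates over that margin, and the two
    tables are compared directly on the common latent metric.
    """
    pf_items = [it for it in calibration.items if it.item_id in PF10_ITEM_IDS]
    haq_items = [it for it in calibration.items if it.item_id in HAQ_CATEGORY_IDS]
    grid1 = QuadratureGrid.make(calibration.grid.nodes.size, calibration.grid.nodes.max())
    pf_table = sum_score_eap_table(pf_items, grid1, instrument="PF-10")
    haq_table = sum_score_eap_table(haq_items, grid1, instrument="HAQ-DI")
    return pf_table, haq_table


def nearest_link(table_a: ScoreTable, table_b: ScoreTable) -> np.ndarray:
    """Directional map A -> B by nearest EAP on the latent scale.

    For each summed score s of instrument A the linked score is the
    summed score t of B minimizing |theta_A(s) - theta_B(t)|.  When two
    candidates are equidistant, the one indicating better function
    (lower disability-coded score) wins.  Scores of A beyond B's most
    extreme EAP clip to B's extreme score.
    """
    if table_a.scores.size == 0 or table_b.scores.size == 0:
        raise ValueError("cannot link empty score tables")
    diffs = np.abs(table_a.eap[:, None] - table_b.eap[None, :])
    # argmin returns the first (lowest disability) index among exact ties
    return table_b.scores[np.argmin(diffs, axis=1)]


def build_crosswalk(
    pf10_responses: np.ndarray,
    haq_items: np.ndarray,
    aid_flags: np.ndarray,
    model: ModelKind | str = ModelKind.PCM,
    method: HaqMethod | str = HaqMethod.SDI,
    norm_coef: NormCoefficients = DEFAULT_NORM_COEFFICIENTS,
    **fit_kwargs,
) -> LinkingResult:
    """End-to-end crosswalk construction from item-level data.

    ``pf10_responses`` is (n, 10) in the original 1-3 coding; ``haq_items``
    is (n, 20) in 0-3 with ``aid_flags`` (n, 8).  HAQ categories are
    scored under ``method``, PF-10 items are reverse-coded, the 18 "items"
    are co-calibrated under ``model``, and nearest-EAP links are built in
    both directions.
    """
    method = HaqMethod(method)
    pf_rev = np.asarray([reverse_pf10_items(r) for r in np.asarray(pf10_responses, int)])
    haq_cat = score_haq_matrix(haq_items, aid_flags, method)
    calibration = co_calibrate(pf_rev, haq_cat, model, **fit_kwargs)
    pf_table, haq_table = instrument_score_tables(calibration)
    return crosswalk_from_tables(pf_table, haq_table, method, calibration, norm_coef)


def crosswalk_from_tables(
    pf_table: ScoreTable,
    haq_table: ScoreTable,
    method: HaqMethod,
    calibration: CalibrationResult | None = None,
    norm_coef: NormCoefficients = DEFAULT_NORM_COEFFICIENTS,
) -> LinkingResult:
    """Assemble a Crosswalk from two instrument score tables."""
    # summed disability metrics: PF-10 sum 0..20 (raw = 100 - 5s), HAQ sum 0..24 (total = s/8)
    pf_link = nearest_link(haq_table, pf_table)  # HAQ sum -> PF sum
    haq_link = nearest_link(pf_table, haq_table)  # PF sum -> HAQ sum

    observed_haq = haq_table.scores / 8.0
    predicted_pf10_raw = 100.0 - 5.0 * pf_link
    predicted_pf10_norm = np.array([pf10_norm_based(v, norm_coef) for v in predicted_pf10_raw])

    # reorder the PF-10 direction to ascending raw score (worst function first)
    pf_raw_desc = 100.0 - 5.0 * pf_table.scores  # scores ascending disability
    order = np.argsort(pf_raw_desc)
    observed_pf10 = pf_raw_desc[order]
    observed_pf10_norm = np.array([pf10_norm_based(v, norm_coef) for v in observed_pf10])
    predicted_haq = (haq_link / 8.0)[order]

    crosswalk = Crosswalk(
        method=method,
        model=calibration.model.kind if calibration is not None else None,
        observed_haq=observed_haq,
        predicted_pf10=predicted_pf10_raw,
        predicted_pf10_norm=predicted_pf10_norm,
        observed_pf10=observed_pf10,
        observed_pf10_norm=observed_pf10_norm,
        predicted_haq=predicted_haq,
        haq_eap=haq_table.eap.copy(),
        pf10_eap=pf_table.eap[order].copy(),
    )
    return LinkingResult(
        calibration=calibration, pf10_table=pf_table, haq_table=haq_table, crosswalk=crosswalk
    )


def compare_models(
    pf10_responses: np.ndarray,
    haq_items: np.ndarray,
    aid_flags: np.ndarray,
    method: HaqMethod | str = HaqMethod.SDI,
    models: Sequence[ModelKind | str] = (ModelKind.PCM, ModelKind.GPCM, ModelKind.MIRT2),
    **fit_kwargs,
) -> ModelComparison:
    """Crosswalks under the nested models plus within-sample agreement.

    For each model the crosswalk is built on the given sample and the
    observed totals are compared with the crosswalk-predicted totals via
    ICC(A,1) in all four directions (HAQ from PF-10 and PF-10 from HAQ,
    under the requested scoring method); predictions are also correlated
    pairwise across models.
    """
    from .validation import icc_a1

    method = HaqMethod(method)
    pf10_responses = np.asarray(pf10_responses, int)
    pf_raw = (pf10_responses.sum(axis=1) - 10) / 20 * 100
    haq_total = score_haq_matrix(haq_items, aid_flags, method).mean(axis=1)

    results: dict[str, LinkingResult] = {}
    icc: dict[str, dict[str, tuple[float, float, float]]] = {}
    predictions: dict[tuple[str, str], np.ndarray] = {}
    for model in models:
        kind = ModelKind(model)
        res = build_crosswalk(pf10_responses, haq_items, aid_flags, kind, method, **fit_kwargs)
        results[kind.value] = res
        cw = res.crosswalk
        pred_haq = np.array([cw.haq_from_pf10(v) for v in pf_raw])
        pred_pf = np.array([cw.pf10_from_haq(v)[0] for v in haq_total])
        predictions[(kind.value, "haq")] = pred_haq
        predictions[(kind.value, "pf10")] = pred_pf
        haq_rep = icc_a1(haq_total, pred_haq)
        pf_rep = icc_a1(pf_raw, pred_pf)
        icc[kind.value] = {
            f"HAQ_{method.value}": (haq_rep.icc, *haq_rep.ci),
            "PF10": (pf_rep.icc, *pf_rep.ci),
        }

    corr: dict[tuple[str, str, str], float] = {}
    names = [ModelKind(m).value for m in models]
    for i, m1 in enumerate(names):
        for m2 in names[i + 1 :]:
            for target in ("haq", "pf10"):
                r = np.corrcoef(predictions[(m1, target)], predictions[(m2, target)])[0, 1]
                corr[(m1, m2, target)] = float(r)
    return ModelComparison(results=results, icc=icc, prediction_correlations=corr)
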