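# pfhaqlink

IRT-based co-calibration and score crosswalks between the two most
widely used self-reported physical-function instruments in rheumatoid
arthritis (RA): the **SF-36 physical functioning scale (PF-10)** — 10
items, raw score 0–100 in steps of 5, higher = better function — and the
**Health Assessment Questionnaire disability index (HAQ-DI)** — 20 items
in 8 categories of daily living, index 0–3 in steps of 0.125, higher =
more disability.  Because RA studies report either instrument, a
*crosswalk* (concordance table) that maps each observed total score on
one scale to its group-level equivalent on the other makes results
comparable across studies and usable in meta-analysis.

The package is aimed at outcomes researchers and psychometricians: it
ships the published RA crosswalk as a ready-to-use converter, and it
implements the full methodology for building and validating such a
crosswalk on new data.

## The method

Let the item responses follow an adjacent-category logit model on a
latent disability trait θ (higher θ = worse function):

    P(X_j = k | θ) ∝ exp( Σ_{h≤k} a_j (θ − b_jh) ),   k = 0, …, m_j − 1

with item discriminations a_j and thresholds b_jh.  Three nested models
are supported: the **partial credit model** (PCM; all a_j = 1), the
**generalized partial credit model** (GPCM; a_j free) and a between-item
**two-dimensional GPCM** in which PF-10 items load on one latent
dimension, HAQ-DI category scores on the other, and the dimensions are
correlated (ρ, estimated by profile likelihood).  Structural parameters
are estimated by marginal maximum likelihood (EM over a rectangular
quadrature grid, standard-normal prior per dimension); persons are
scored by the expected a posteriori (EAP) method.

Crosswalk construction follows the total-score linking recipe:

1. score HAQ categories (standard SDI or alternative ADI rule),
   reverse-code the PF-10 items, and jointly calibrate the 18 "items";
2. with the item parameters fixed, compute each instrument's summed-score
   → EAP table via the Lord–Wingersky recursion,
   θ(s) = Σ_q θ_q P(s|θ_q) w_q / Σ_q P(s|θ_q) w_q;
3. link each observed total score to the score on the other instrument
   with the nearest EAP on the latent scale (ties go to better function;
   scores beyond the other scale's range clip to its extreme).

Model fit is judged by grouped observed-vs-expected item scores:
ES = |observed − expected| / m_j within low/average/high latent-score
groups, acceptable when every ES < 0.10 (equivalently, score-frequency
differences of 2.5% for 4-category and 3.33% for 3-category items).
A crosswalk is validated with ICC(A,1) agreement (≥ 0.70 supports
group-level use), Bland–Altman limits of agreement, Cohen's *d* for
6-month change, and relative validity RV = F_predicted / F_observed
from one-way ANOVAs on DAS28 responder status (good response:
improvement ≥ 1.2 and final score ≤ 3.2), with BCa bootstrap CIs.

## Worked example

```python
from pfhaqlink import (HaqMethod, ScaleId, apply_crosswalk,
                       load_published_crosswalk, score_pf10_raw)

pf10 = [2, 2, 3, 2, 3, 2, 2, 3, 3, 3]        # 1 = limited a lot ... 3 = not limited
raw = score_pf10_raw(pf10)                    # -> 75.0
cw = load_published_crosswalk(HaqMethod.SDI)
apply_crosswalk(cw, raw, ScaleId.PF10_RAW)    # -> 0.375
apply_crosswalk(cw, 1.000, ScaleId.HAQ_SDI)   # -> (55.0, 38.1)
```

Running `python examples/01_score_and_convert.py` prints:

```
PF-10 raw score:        75  (norm-based 46.5)
HAQ-DI (SDI):           1.500
HAQ-DI (ADI):           1.375

PF-10 75 maps to HAQ-SDI 0.375 on the published crosswalk
HAQ-SDI 1.000 maps to PF-10 55 (norm-based 38.1)
```

A PF-10 of 75 corresponds, at the group level, to a HAQ-SDI of 0.375
(mild disability); the patient's own HAQ-SDI of 1.500 is higher because
crosswalked scores are population equivalences, not individual
predictions — individual-level use is explicitly out of scope.  The
other examples build a crosswalk from a synthetic calibration cohort
(`02`), compare the three nested models (`03`), and run the
cross-validation battery on a synthetic early-RA cohort (`04`); e.g.
`04` prints ICC(A,1) = 0.76 for both directions with wide limits of
agreement, and RV intervals covering 1.

A thin CLI wraps the same pipeline:

```sh
pfhaqlink convert 1.000 --scale HAQ_SDI
pfhaqlink simulate --out runs/demo --n 500 --seed 1
```

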