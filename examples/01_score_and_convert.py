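"""Score both instruments for one patient and convert through the
published crosswalk.

Prints the PF-10 raw and norm-based scores, the HAQ-DI under standard
(SDI) and alternative (ADI) scoring, and the crosswalk-predicted score
on the other instrument.  The predicted values are group-level
equivalents: they say which HAQ-DI (or PF-10) level corresponds to the
same underlying disability, not what this individual would have scored.
"""

import numpy as np

from pfhaqlink import (
    HaqMethod,
    ScaleId,
    apply_crosswalk,
    load_published_crosswalk,
    pf10_norm_based,
    score_haq_categories,
    score_haq_total,
    score_pf10_raw,
)

# PF-10 items: 1 = limited a lot ... 3 = not limited at all
pf10 = [2, 2, 3, 2, 3, 2, 2, 3, 3, 3]
# HAQ-DI items: 0 = without difficulty ... 3 = unable to do
haq = [1, 0, 1, 1, 0, 0, 1, 2, 1, 0, 1, 0, 2, 1, 1, 0, 1, 1, 2, 1]
# aids/devices or help used for walking (category 4) and grip (category 7)
flags = np.array([False, False, False, True, False, False, True, False])

raw = score_pf10_raw(pf10)
print(f"PF-10 raw score:        {raw:.0f}  (norm-based {pf10_norm_based(raw):.1f})")
for method in (HaqMethod.SDI, HaqMethod.ADI):
    total = score_haq_total(score_haq_categories(haq, flags, method))
    print(f"HAQ-DI ({method.value}):           {total:.3f}")

cw = load_published_crosswalk(HaqMethod.SDI)
pred_haq = apply_crosswalk(cw, raw, ScaleId.PF10_RAW)
pred_pf, pred_pf_norm = apply_crosswalk(cw, 1.000, ScaleId.HAQ_SDI)
print(f"\nPF-10 {raw:.0f} maps to HAQ-SDI {pred_haq:.3f} on the published crosswalk")
print(f"HAQ-SDI 1.000 maps to PF-10 {pred_pf:.0f} (norm-based {pred_pf_norm:.1f})")
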