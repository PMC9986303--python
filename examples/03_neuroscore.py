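"""Score a neurological assessment sheet and derive the subscores.

The composite rubric has 10 criteria (0 = normal).  This sheet describes a
moderately affected animal: apathetic demeanour, left-sided postural
deficits with knuckling, and lateral drifting on wheelbarrowing.
"""

import pandas as pd

from ovigait.neuroscore import DEFAULT_RUBRIC, rubric_max_total, validate_sheet

entries = {
    (1, "base"): 1.0,             # apathetic
    (5, "base"): 1.0,             # dysmetric limb movement
    (7, "base_left"): 3.0,        # delayed adjustment of both limbs
    (7, "knuckling_FL_L"): 0.25,
    (8, "base_left"): 1.0,        # delayed hopping response
    (9, "base_FL_L"): 1.0,
    (9, "drag_FL_L"): 0.25,
    (10, "base"): 1.0,            # drifting to side
}
rows = []
for crit in DEFAULT_RUBRIC.criteria:
    for comp in crit.components():
        value = entries.get((crit.id, comp))
        if value is not None or comp.startswith("base"):
            rows.append({"animal": "S07", "session": "D3", "criterion": crit.id,
                         "component": comp, "value": value or 0.0})

score = validate_sheet(pd.DataFrame(rows))
total, note = rubric_max_total()
for name, value in score.subscores().items():
    print(f"{name:15s} {value:5.2f}")
print(f"(rubric maximum {total}; {note})")
# Total 8.5 of 36.5: a clear left-lateralized deficit, dominated by the
# contralateral postural reactions.
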