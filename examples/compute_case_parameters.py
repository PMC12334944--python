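"""Compute personalized reference intervals and RCVs for the packaged case.

Loads the 10-measurand CBC/differential case (set points from a 3-result
steady-state history, population CV_I/CV_G, laboratory CV_A) and prints the
full derived parameter table: both prRI routes, both RCVs, the index of
individuality and the recommended route per measurand.
"""

import pandas as pd

from persoref import RunConfig, compute_parameters
from persoref.case_table import load_case

rows = load_case()
table = compute_parameters([r.profile for r in rows],
                           {r.profile.measurand_name: r.hsp for r in rows},
                           RunConfig())

pd.set_option("display.width", 200)
cols = ["measurand", "hsp", "cv_t", "ii", "prri_pop_lower", "prri_pop_upper",
        "rcv_pop", "prri_ind_lower", "prri_ind_upper", "rcv_ind",
        "recommended_route"]
print(table[cols].to_string(index=False))
print(
    "\nEach row: the patient's set point (hsp), her total variation (cv_t, %),"
    "\nthe index of individuality (ii; < 0.6 means population intervals track"
    "\nthis person poorly), the personalized interval from population BV"
    "\n(prri_pop, z-based) and from her own variation (prri_ind, t-based with"
    "\nn-1 = 2 df), and the change thresholds (rcv_*, %). With only 3"
    "\nsteady-state results the t-based interval is too wide to be useful, so"
    "\nmeasurands with acceptable analytical noise are routed to the"
    "\npopulation formula; monocytes, eosinophils and basophils, whose CV_A"
    "\nexceeds half of CV_I, fall back to change-based (RCV) monitoring."
)
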