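"""Quantify inter-assessor consistency with an intraclass correlation.

Simulates two elicitation panels for the same 20 flagged trials: one on a
plain scale (assessors disagree more per trial) and one anchored on the
empirical bias distribution (assessors agree more).  The ICC is the share of
variation in processed opinion means explained by trials rather than
assessors; its CI comes from a parametric bootstrap of the mixed model.
"""

import numpy as np
import pandas as pd

from biasmeta import (
    default_bias_table,
    icc_with_ci,
    priors_from_table,
    process_elicitations,
    simulate_elicitations,
    simulate_meta_analysis,
)

table = default_bias_table()
records, truth = simulate_meta_analysis(n_trials=20, bias_spec=table, seed=8)
flagged = {t: b for t, b in truth.biases.items() if truth.profiles[t] != "LLL"}
references = priors_from_table(records, table)


def panel_icc(strategy, seed):
    panel = simulate_elicitations(
        flagged, strategy=strategy, seed=seed, references=references
    )
    normals = process_elicitations(panel, references)
    frame = pd.DataFrame(
        {
            "trial_id": [n.trial_id for n in normals],
            "assessor_id": [n.assessor_id for n in normals],
            "mean": [n.mean for n in normals],
        }
    )
    return icc_with_ci(frame, n_boot=400, seed=seed)


for strategy, label in (("a", "plain scale"), ("b", "data-informed")):
    res = panel_icc(strategy, seed=5)
    print(
        f"strategy {strategy} ({label}): ICC {100 * res.icc:.0f}% "
        f"(95% CI {100 * res.ci[0]:.0f}-{100 * res.ci[1]:.0f}%)"
    )
print(
    "\nA low ICC means assessor disagreement dominates; anchoring opinions "
    "on the empirical distribution makes panels far more consistent."
)
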