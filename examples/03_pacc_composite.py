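"""Scoring the cognitive composite from raw component scores.

Standardizes four component tests against a baseline cognitively-normal
reference, reorients them so higher z is always better (Trails B is
log-transformed and reversed), and sums them into the composite. A
subject-visit needs at least two components for a score.
"""

import numpy as np
import pandas as pd

from polyrisk_cog import DEFAULT_BATTERY, fit_reference, pacc_change, score_pacc

rng = np.random.default_rng(0)
rows = []
for i in range(30):  # baseline cognitively-normal reference stratum
    rows.append({"subject_id": f"CN{i}", "visit": "bl",
                 "adas_delayed_recall": rng.normal(3, 2), "mmse": rng.normal(29, 1.2),
                 "logical_memory": rng.normal(13, 4),
                 "trails_b": float(rng.lognormal(4.5, 0.35))})
wide = pd.DataFrame(rows)
ref = fit_reference(wide, DEFAULT_BATTERY)

# one declining subject; month-60 visit is missing the MMSE and Trails B
subject = pd.DataFrame(
    [
        {"subject_id": "P1", "visit": "bl", "adas_delayed_recall": 3.0,
         "mmse": 29.0, "logical_memory": 13.0, "trails_b": 90.0},
        {"subject_id": "P1", "visit": "m24", "adas_delayed_recall": 4.5,
         "mmse": 28.0, "logical_memory": 10.0, "trails_b": 120.0},
        {"subject_id": "P1", "visit": "m60", "adas_delayed_recall": 6.0,
         "mmse": np.nan, "logical_memory": 6.0, "trails_b": np.nan},
    ]
)
scored = score_pacc(subject, ref, DEFAULT_BATTERY)
print(scored.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
changes = pacc_change(scored)
print("\nchange from baseline:")
print(changes[["visit", "change"]].to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print("\nEach z is (value - CN baseline mean) / CN baseline sd, sign-flipped "
      "for higher-is-worse tests; the composite is their sum (NA with < 2 "
      "components). Negative change = cognitive decline.")
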