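"""Dose-dependent growth inhibition, normalized to untreated wells.

Simulates an erythromycin-like toxicity series on a reporter-free strain and
reports exponential-phase growth rates relative to the no-chemical control.
"""

import numpy as np

import biosensorkit as bk

params = bk.ToxicityParams(ic50=5e-5, steepness=1.5, max_inhibition=1.0)
exp = bk.simulate_toxicity_plate(
    {"erythromycin": params},
    {"erythromycin": list(np.geomspace(5e-6, 5e-3, 6))},
    seed=2,
)
profile = bk.toxicity_profile(exp, mode="rate")
print(profile.round(4).to_string(index=False))
print(
    "\nnormalized_value = exponential-phase growth rate relative to untreated"
    "\nwells (1.0 = no growth effect; the dose at 0.5 is the effective IC50)."
)
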