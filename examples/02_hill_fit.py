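"""Fit the modified Hill transfer function to extracted expression velocities.

Simulates the arabinose-sensor titration, extracts each well's maximum
growth-normalized expression rate, fits
v(I) = Vmin + Vmax * I^h / (I^h + K_L^h), and compares the fit to the
generating parameters.
"""

import biosensorkit as bk

cfg = bk.preset_config(sensors=("AraC",), seed=1)
exp = bk.simulate_plate(cfg)

velocities = bk.max_velocities(exp)
print(
    velocities[["concentration", "replicate", "max_rate"]].to_string(
        index=False,
        formatters={"concentration": "{:.3g}".format, "max_rate": "{:.1f}".format},
    )
)

fit = bk.fit_sensor(exp, "AraC")
truth = bk.TABLE1[("AraC", "high")].expression
print("\n            fitted                generating")
print(f"Vmax   {fit.v_max:9.1f} +/- {fit.se['v_max']:<8.1f} {truth.v_max}")
print(f"Vmin   {fit.v_min:9.1f} +/- {fit.se['v_min']:<8.1f} {truth.v_min}")
print(f"h      {fit.h:9.2f} +/- {fit.se['h']:<8.2f} {truth.hill_h}")
print(f"K_L    {fit.k_half:9.3g} +/- {fit.se['k_half']:<8.2g} {truth.k_half}")
print(
    "\nVmax/Vmin are maximal/basal promoter activities (AFU OD^-1 s^-1),"
    "\nh the cooperativity, K_L the lumped half-maximal concentration (M)."
)
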