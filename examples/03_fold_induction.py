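"""Fold induction with propagated uncertainty, and the lower-bound rule.

The first case has a clearly measurable uninduced signal, so a point
estimate with a propagated standard error is reported. The second case has
an uninduced signal buried in the strain's autofluorescence, so only a lower
bound on the fold induction is defensible.
"""

from biosensorkit.dose_response import fold_induction_from_stats

point = fold_induction_from_stats(1000.0, 10.0, 100.0, 5.0, 50.0, 2.0)
print(f"measurable uninduced signal : F = {point.value:.1f} +/- {point.se:.2f}")

bound = fold_induction_from_stats(1000.0, 10.0, 52.0, 3.0, 50.0, 2.0)
print(f"uninduced within background : F > {bound.value:.1f}  (lower bound)")

print(
    "\nF is background-subtracted induced over uninduced output. When the"
    "\nuninduced mean sits within the control autofluorescence (its doubled-SE"
    "\ninterval touches zero) the ratio is undefined and the bound divides the"
    "\nlower induced bound by the upper uninduced bound instead."
)
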