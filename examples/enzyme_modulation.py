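"""Operating-point dependence of sensitivities in a modulated enzyme module.

An enzyme-catalysed conversion A -> B with competitive activation and
inhibition (activator Act drives inactive enzyme E0 into the active pool
against inhibitor Inh; total enzyme xE + xC + xE0 = 10).  Because the
kinetics saturate, the linearized gains depend on where the system sits on
its Michaelis-Menten curve.
"""

import numpy as np

import bgsens as bg
from bgsens.linear_analysis import gain_vs_operating_point

enz = bg.fixture("enzyme_module")
sens = bg.augment(enz)

amounts = np.geomspace(0.02, 500.0, 10)
df = gain_vs_operating_point(sens, "A", amounts, output_flow="r2")
cols = ["A", "flow", "lambda[A]", "lambda[r1]", "lambda[r2]", "lambda[Act]", "lambda[Inh]"]
print(df[cols].to_string(index=False, float_format=lambda v: f"{v:8.3f}"))

print("\nThe steady flow saturates at Vmax = e0*kappa2*KC = 10. At saturation")
print("all gains shown vanish except the catalytic channel lambda[r2]; the")
print("activator and inhibitor gains are antisymmetric and peak near half of")
print("the saturated flow, where modulation is most effective.")
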