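"""Sloppy-parameter analysis of the chain's flow through r1.

The quadratic response cost Q = L~.T H L~ measures how much the observed
flow trajectory moves when the two rate-constant perturbations
(lambda_1, lambda_2) step.  Eigenvectors of H with large eigenvalues are
stiff parameter combinations; small ones are sloppy.
"""

import numpy as np

import bgsens as bg

net = bg.fixture("abc_chain")
sens = bg.augment(net)
lin = bg.linearize(sens, outputs=["r1"])
inputs = ["lambda[r1]", "lambda[r2]"]

dec_inf = bg.steady_hessian(lin, inputs=inputs)
print("H_inf =")
print(np.round(dec_inf.H, 4))
print(f"sigma = {np.round(dec_inf.sigma, 4)}")
print(f"V1 = {np.round(dec_inf.V[:, 0], 3)}  (steady-state: rank one, one stiff direction)")

dec1 = bg.response_hessian(lin, tf=1.0, inputs=inputs)
print(f"\nH(tf=1) sigma = {np.round(dec1.sigma, 4)}")
print(f"V1 = {np.round(dec1.V[:, 0], 3)}")

trunc = bg.significant_modes(dec1)
print(f"significant modes kept: {len(trunc.sigma)} of {len(dec1.sigma)}")
print("(the finite horizon keeps a second, transient mode that H_inf lacks)")

ct = bg.cost_contour(dec_inf, level=1.0)
print(f"\nQ_inf = 1 contour: {ct.kind} (the sloppy direction is unconstrained,")
print("so the ellipse degenerates to two parallel lines perpendicular to V1).")
ct1 = bg.cost_contour(dec1, level=1.0)
print(f"Q(tf=1) = 1 contour: {ct1.kind}, {len(ct1.points)} sampled points.")
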