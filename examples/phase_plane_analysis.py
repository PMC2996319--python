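"""Locate and classify the homeostatic equilibria of an exemplar model.

Loads the bistable-trigger exemplar, traces its nullclines, finds every
equilibrium, and prints the phase-plane structure: three nullcline
intersections, of which the low and high states are stable and the
middle one is a saddle — the signature of a cytokine trigger.
"""

import cytodyn as cd

p = cd.load_exemplar("trigger")
null_A, null_B = cd.compute_nullclines(p, resolution=200)
eqs = cd.find_equilibria(p)

print(f"A-nullcline: {len(null_A.branches)} branch(es), "
      f"B-nullcline: {len(null_B.branches)} branch(es)")
print(f"equilibria found: {len(eqs)}")
for i, e in enumerate(eqs, start=1):
    re = ", ".join(f"{z.real:+.4f}{z.imag:+.4f}j" for z in e.eigenvalues)
    print(f"  H{i}: A={e.state.conc_A:.4f}  B={e.state.conc_B:.4f}  "
          f"{e.stability:13s} eigenvalues [{re}]")

report = cd.classify_regime(p)
print(f"regime: {report.regime}")
# The two filled (stable) states are the low and high homeostatic levels;
# pulses of cytokine A or B can switch the tissue between them.
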