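"""Switching a bistable cytokine trigger between its two stable levels.

In the trigger regime two stable homeostatic levels (H1 low, H3 high)
coexist, separated by a saddle.  A transient pulse of cytokine A pushes
the system from H1 to H3; a pulse of the inhibitory cytokine B brings it
back.  This is the model's picture of lesional vs perilesional tissue.
"""

import cytodyn as cd

p = cd.load_exemplar("trigger")
stables = [e for e in cd.find_equilibria(p) if e.is_stable]
H1, H3 = stables
print(f"H1 (low):  A={H1.state.conc_A:.4f}  B={H1.state.conc_B:.4f}")
print(f"H3 (high): A={H3.state.conc_A:.4f}  B={H3.state.conc_B:.4f}")

up = cd.switch_test(
    p, H1, cd.PulseProtocol("A", amplitude=0.05, onset=5.0, duration=5.0),
    t_settle=300.0, stable_equilibria=stables,
)
print(f"A-pulse from H1 settles at: "
      f"{'H3' if up is H3 else 'H1' if up is H1 else up}")

down = cd.switch_test(
    p, H3, cd.PulseProtocol("B", amplitude=0.2, onset=5.0, duration=5.0),
    t_settle=300.0, stable_equilibria=stables,
)
print(f"B-pulse from H3 settles at: "
      f"{'H1' if down is H1 else 'H3' if down is H3 else down}")

sub = cd.switch_test(
    p, H1, cd.PulseProtocol("A", amplitude=0.005, onset=5.0, duration=5.0),
    t_settle=300.0, stable_equilibria=stables,
)
print(f"sub-threshold A-pulse from H1 settles at: "
      f"{'H1' if sub is H1 else sub}")
# the switch has a threshold: small pulses relax back, large ones flip
# the tissue to the other homeostatic level, where it then stays.
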