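"""Impulse amplification in a healthy (monostable) immune sub-system.

Starts the tuned excitable healthy exemplar at its unique homeostatic
point, applies a brief, very small external pulse of cytokine A, and
measures the peak system response relative to what the same pulse would
produce against linear clearance alone.  A healthy system near the
excitability boundary amplifies small inflammatory signals by orders of
magnitude and still returns to the same homeostatic point.
"""

import numpy as np

import cytodyn as cd

p = cd.load_exemplar("healthy_excitable")
eq = cd.find_equilibria(p)[0]
print(f"homeostatic point: A={eq.state.conc_A:.5f}  B={eq.state.conc_B:.5f} "
      f"({eq.stability})")

pulse = cd.PulseProtocol(target="A", amplitude=1e-4, onset=5.0, duration=1.0)
traj = cd.simulate(p, eq.state, 400.0, pulse)

ratio = cd.response_amplification(traj)
peak_dev = np.abs(traj.states - eq.state.as_array()).max()
final_dist = np.hypot(*(traj.states[-1] - eq.state.as_array()))
print(f"pulse: amplitude {pulse.amplitude:g} for {pulse.duration:g} time units")
print(f"peak deviation from homeostasis: {peak_dev:.4f}")
print(f"amplification ratio (response / passive pulse): {ratio:.1f}")
print(f"distance to homeostasis at t=400: {final_dist:.2e}")
# ratio >> 100: the coupled populations amplify the signal ~two orders of
# magnitude, then the system relaxes back to the same equilibrium.
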