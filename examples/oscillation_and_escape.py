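"""Sustained cytokine oscillations, and escaping them with a small pulse.

The pure oscillatory exemplar has no stable equilibrium: concentrations
settle onto a limit cycle.  The coexisting exemplar additionally has a
stable homeostatic point; there, a small well-timed pulse of cytokine A
applied while the system is oscillating carries it across the saddle
into the basin of the stable point — oscillation stops.
"""

import cytodyn as cd

# 1. pure oscillation
p_osc = cd.load_exemplar("oscillatory_pure")
(eq,) = cd.find_equilibria(p_osc)
cycle = cd.detect_limit_cycle(p_osc, eq)
print(f"pure oscillatory regime: equilibrium at A={eq.state.conc_A:.4f} "
      f"is {eq.stability}")
print(f"limit cycle: period {cycle.period:.3f}, amplitudes "
      f"dA={cycle.amplitude_A:.3f}, dB={cycle.amplitude_B:.3f}")

# 2. coexisting stable point + cycle, with pulse-driven escape
p_co = cd.load_exemplar("oscillatory_coexisting")
report = cd.classify_regime(p_co)
cycle = report.cycles[0]
stable = [e for e in report.equilibria if e.is_stable][0]
print(f"\ncoexisting regime: {report.regime}")
print(f"stable point: A={stable.state.conc_A:.3f}  B={stable.state.conc_B:.3f}")
print(f"cycle period: {cycle.period:.2f}")

for amplitude in (0.02, 0.1):
    pulse = cd.PulseProtocol("A", amplitude, onset=0.25 * cycle.period,
                             duration=5.0)
    escaped = cd.oscillation_escape_test(
        p_co, pulse, cycle=cycle, stable_eq=stable, t_settle=600.0
    )
    print(f"A-pulse amplitude {amplitude}: "
          f"{'escaped to stable homeostasis' if escaped else 'still oscillating'}")
# a sufficiently large (but still small vs the response) pulse ends the
# oscillation; an insufficient one leaves the system on the cycle.
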