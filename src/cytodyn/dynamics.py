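"""Numerical integration, pulse protocols and response metrics.

The integrator is scipy's stiff-capable adaptive LSODA.  Pulse protocols
are square additive source terms; integration is split at the pulse
edges so the discontinuity is never smeared across a solver step.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .params import CytokineState, ModelParameters
from .rates import rhs_xy

__all__ = [
    "PulseProtocol",
    "Trajectory",
    "SolverFailure",
    "simulate",
    "response_amplification",
    "switch_test",
    "oscillation_escape_test",
]

#: default solver tolerances (relative, absolute)
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
#: a state is "settled" at an equilibrium when within this distance of it
SETTLE_TOL = 1e-4
#: fraction of the settling horizon the state must dwell at the attractor
DWELL_FRACTION = 0.1


class SolverFailure(RuntimeError):
    """ODE solver failed (step-size collapse); carries the failing time."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:g})")
        self.t_fail = t_fail


@dataclass(frozen=True)
class PulseProtocol:
    """External cytokine application: a square additive source pulse.

    ``amplitude`` (concentration/time) is added to the source term of the
    target cytokine on ``[onset, onset + duration]``.  With
    ``mode='jump'`` the pulse is instead applied as an instantaneous
    state increment of ``amplitude * duration`` at ``onset``.
    """

    target: str
    amplitude: float
    onset: float
    duration: float
    mode: str = "source"

    def __post_init__(self):
        if self.target not in ("A", "B"):
            raise ValueError("target must be 'A' or 'B'")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.mode not in ("source", "jump"):
            raise ValueError("mode must be 'source' or 'jump'")


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered states from numerical integration."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 2): columns conc_A, conc_B
    parameters: ModelParameters
    protocol: Optional[PulseProtocol] = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.states, dtype=float)
        if t.ndim != 1 or s.shape != (t.size, 2):
            raise ValueError("times must be 1-D and states (n, 2)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", s)

    @property
    def conc_A(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def conc_B(self) -> np.ndarray:
        return self.states[:, 1]

    def final_state(self) -> CytokineState:
        a, b = self.states[-1]
        return CytokineState(max(a, 0.0), max(b, 0.0))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "conc_A": self.conc_A, "conc_B": self.conc_B}
        )


def _segment(p, y0, t0, t1, extra_src, rtol, atol, n_out, method):
    """Integrate one smooth segment; returns (times, states)."""
    sa, sb = extra_src

    def f(t, y):
        dA, dB = rhs_xy(max(y[0], 0.0), max(y[1], 0.0), p)
        return [dA + sa, dB + sb]

    t_eval = np.linspace(t0, t1, max(n_out, 2))
    sol = solve_ivp(
        f, (t0, t1), y0, method=method, rtol=rtol, atol=atol, t_eval=t_eval
    )
    if not sol.success:
        raise SolverFailure(sol.message, sol.t[-1] if sol.t.size else t0)
    return sol.t, sol.y.T


def simulate(
    p: ModelParameters,
    initial: CytokineState,
    t_end: float,
    protocol: Optional[PulseProtocol] = None,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    n_out: int = 2000,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model from ``initial`` to ``t_end``.

    With a protocol, the target cytokine's source term is augmented by
    ``amplitude`` on the pulse window (square pulse); the integration is
    restarted at the pulse edges.  Output is sampled on a fixed uniform
    grid of ``n_out`` points per segment, so identical inputs give
    bitwise-identical output.
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    y0 = initial.as_array()
    edges: list[tuple[float, float, tuple[float, float]]] = []
    if protocol is None:
        edges.append((0.0, t_end, (0.0, 0.0)))
    elif protocol.mode == "jump":
        t_jump = min(protocol.onset, t_end)
        if t_jump > 0:
            edges.append((0.0, t_jump, (0.0, 0.0)))
        if t_jump < t_end:
            edges.append((t_jump, t_end, (0.0, 0.0)))
    else:
        src = (
            (protocol.amplitude, 0.0)
            if protocol.target == "A"
            else (0.0, protocol.amplitude)
        )
        t1 = min(protocol.onset, t_end)
        t2 = min(protocol.onset + protocol.duration, t_end)
        if t1 > 0:
            edges.append((0.0, t1, (0.0, 0.0)))
        if t2 > t1:
            edges.append((t1, t2, src))
        if t_end > t2:
            edges.append((t2, t_end, (0.0, 0.0)))

    n_seg = max(len(edges), 1)
    per_seg = max(n_out // n_seg, 16)
    times_all, states_all = [], []
    jump_pending = protocol is not None and protocol.mode == "jump"
    for i, (t0, t1, src) in enumerate(edges):
        if jump_pending and t0 >= protocol.onset:
            delta = protocol.amplitude * protocol.duration
            y0 = y0.copy()
            y0[0 if protocol.target == "A" else 1] += delta
            jump_pending = False
        t, s = _segment(p, y0, t0, t1, src, rtol, atol, per_seg, method)
        y0 = s[-1]
        if times_all:  # drop duplicated edge point
            t, s = t[1:], s[1:]
        times_all.append(t)
        states_all.append(s)
    states = np.clip(np.concatenate(states_all), 0.0, None)
    return Trajectory(
        times=np.concatenate(times_all),
        states=states,
        parameters=p,
        protocol=protocol,
    )


def response_amplification(traj: Trajectory) -> float:
    """Peak system response relative to the decoupled-pulse yardstick.

    Numerator: maximal deviation over time of either cytokine from its
    pre-pulse level (the state at pulse onset).  Denominator: the peak
    excess concentration the same square pulse would produce if the
    target cytokine obeyed pure first-order decay at its linear
    clearance, ``(amp/lam)(1 - exp(-lam*dur))`` (or ``amp*dur`` for zero
    clearance).  A ratio of 1 means no amplification beyond the passive
    pulse response.
    """
    protocol = traj.protocol
    if protocol is None:
        raise ValueError("trajectory has no pulse protocol")
    i0 = int(np.searchsorted(traj.times, protocol.onset))
    i0 = min(max(i0, 0), len(traj.times) - 1)
    baseline = traj.states[i0]
    deviation = np.abs(traj.states - baseline).max()
    p = traj.parameters
    lam = p.linear_clearance_A if protocol.target == "A" else p.linear_clearance_B
    amp, dur = protocol.amplitude, protocol.duration
    if amp <= 0:
        raise ValueError("amplification undefined for zero-amplitude pulse")
    if lam > 0:
        yardstick = amp / lam * (1.0 - np.exp(-lam * dur))
    else:
        yardstick = amp * dur
    return float(deviation / yardstick)


def _nearest_equilibrium(state: np.ndarray, equilibria) -> tuple[int, float]:
    d = [float(np.hypot(*(state - e.state.as_array()))) for e in equilibria]
    i = int(np.argmin(d))
    return i, d[i]


def _settled_at(traj: Trajectory, equilibria, t_settle: float) -> Optional[int]:
    """Index of the equilibrium the tail of ``traj`` dwells at, else None."""
    if not equilibria:
        return None
    dwell_start = traj.times[-1] - DWELL_FRACTION * t_settle
    tail = traj.states[traj.times >= dwell_start]
    i, _ = _nearest_equilibrium(traj.states[-1], equilibria)
    target = equilibria[i].state.as_array()
    dist = np.hypot(tail[:, 0] - target[0], tail[:, 1] - target[1])
    return i if np.all(dist < SETTLE_TOL) else None


def switch_test(
    p: ModelParameters,
    from_eq,
    protocol: PulseProtocol,
    t_settle: float,
    *,
    stable_equilibria=None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
):
    """Which stable equilibrium does the system settle into after a pulse?

    Starts at ``from_eq`` (a stable equilibrium), applies the pulse, and
    integrates for ``t_settle`` past the pulse.  Returns the settled
    :class:`~cytodyn.phase.Equilibrium` (nearest stable equilibrium the
    trajectory dwells at for the final 10% of the horizon), or the string
    ``"unsettled"``.
    """
    from .phase import find_equilibria  # local import avoids module cycle

    if stable_equilibria is None:
        stable_equilibria = [e for e in find_equilibria(p) if e.is_stable]
    if not stable_equilibria:
        raise ValueError("switch_test requires at least one stable equilibrium")
    t_end = protocol.onset + protocol.duration + t_settle
    traj = simulate(p, from_eq.state, t_end, protocol, rtol=rtol, atol=atol)
    i = _settled_at(traj, stable_equilibria, t_settle)
    return stable_equilibria[i] if i is not None else "unsettled"


def oscillation_escape_test(
    p: ModelParameters,
    protocol: PulseProtocol,
    *,
    cycle=None,
    stable_eq=None,
    t_settle: float = 400.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> bool:
    """Does a pulse applied on-cycle return the system to the stable point?

    Requires a regime where a stable equilibrium coexists with a limit
    cycle.  The initial state is taken on the cycle orbit at the phase
    corresponding to ``protocol.onset`` modulo the period, the pulse is
    applied, and the test reports whether the trajectory settles at the
    stable equilibrium (dwelling within tolerance for the final 10% of
    the settling horizon) rather than returning to the cycle.  Escape is
    phase-dependent: the same pulse can succeed at one phase and fail at
    another.
    """
    from .phase import detect_limit_cycle, find_equilibria

    if cycle is None or stable_eq is None:
        eqs = find_equilibria(p)
        if stable_eq is None:
            stables = [e for e in eqs if e.is_stable]
            if not stables:
                raise ValueError("no stable equilibrium: not a coexisting regime")
            stable_eq = stables[0]
        if cycle is None:
            for e in eqs:
                if not e.is_stable and e.stability != "saddle":
                    cycle = detect_limit_cycle(p, e)
                    if cycle is not None:
                        break
            if cycle is None:
                raise ValueError("no limit cycle found: not a coexisting regime")
    phase = (protocol.onset / cycle.period) % 1.0
    idx = int(phase * (len(cycle.orbit) - 1))
    a0, b0 = cycle.orbit[idx]
    start = CytokineState(max(a0, 0.0), max(b0, 0.0))
    proto0 = dataclasses.replace(protocol, onset=0.0)
    t_end = proto0.duration + t_settle
    traj = simulate(p, start, t_end, proto0, rtol=rtol, atol=atol)
    i = _settled_at(traj, [stable_eq], t_settle)
    return i is not None
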