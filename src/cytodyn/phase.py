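"""Phase-plane analysis: nullclines, equilibria, stability, limit cycles.

The two nullclines are the zero sets of the two time derivatives; their
intersections are the homeostatic equilibria.  Because production of A
is strictly monotone in its single inhibitor B, the A-nullcline can be
inverted in closed form (a unique B for each admissible A), which turns
the 2-D root problem into a robust 1-D scan along that curve.  All roots
are then polished in 2-D and verified to tight tolerance.

Stability is classified from the eigenvalues of the finite-difference
Jacobian; limit cycles are detected from the peak train of a long
integration seeded just off an unstable equilibrium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.signal import find_peaks

from .params import CytokineState, ModelParameters
from .rates import dissipative_box, jacobian, rhs_xy, uptake_rate

__all__ = [
    "Nullcline",
    "Equilibrium",
    "LimitCycle",
    "BasinMap",
    "compute_nullclines",
    "find_equilibria",
    "classify_stability",
    "detect_limit_cycle",
    "vector_field",
    "basin_map",
    "default_window",
]

log = logging.getLogger(__name__)

ROOT_TOL = 1e-9          # |rhs| verification bound for equilibria
MERGE_RADIUS = 1e-5      # distinct-equilibrium merge radius
STABILITY_MARGIN = 1e-7  # |Re(eigenvalue)| below this is marginal
WINDOW_FACTOR = 3.0      # analysis window = this multiple of the dissipative box
SETTLE_TOL_BASIN = 1e-3  # basin labeling settlement tolerance


@dataclass(frozen=True)
class Nullcline:
    """Zero set of one cytokine's time derivative, as polyline branches."""

    which: str  # 'A' or 'B'
    branches: tuple[np.ndarray, ...]  # each (k, 2) array of (conc_A, conc_B)

    @property
    def points(self) -> np.ndarray:
        """All branch points concatenated, (n, 2)."""
        if not self.branches:
            return np.empty((0, 2))
        return np.concatenate(self.branches)


@dataclass(frozen=True)
class Equilibrium:
    """A root of the ODE right-hand side with its local linearization."""

    state: CytokineState
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    stability: str  # stable-node | stable-focus | saddle | unstable-node
    #               | unstable-focus | center-marginal

    @property
    def is_stable(self) -> bool:
        return self.stability.startswith("stable")

    @property
    def leading_real_part(self) -> float:
        return float(np.max(self.eigenvalues.real))


@dataclass(frozen=True)
class LimitCycle:
    """An isolated periodic orbit, sampled over one period."""

    period: float
    amplitude_A: float
    amplitude_B: float
    orbit: np.ndarray  # (m, 2) samples of one period
    enclosed_equilibrium: Optional[Equilibrium] = None

    def encloses(self, point) -> bool:
        """Ray-casting winding test: is ``point`` inside the orbit?"""
        x, y = (point.as_array() if isinstance(point, CytokineState)
                else np.asarray(point, float))
        px, py = self.orbit[:, 0], self.orbit[:, 1]
        qx, qy = np.roll(px, -1), np.roll(py, -1)
        cross = (py > y) != (qy > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xin = px + (y - py) * (qx - px) / (qy - py)
        return bool(np.sum(cross & (x < xin)) % 2)


@dataclass(frozen=True)
class BasinMap:
    """Attractor label for each initial state on a rectangular lattice."""

    A_values: np.ndarray
    B_values: np.ndarray
    labels: np.ndarray  # (nB, nA) int; -1 = unresolved
    attractors: tuple  # Equilibrium or LimitCycle per label index

    @property
    def unresolved_fraction(self) -> float:
        return float(np.mean(self.labels < 0))


def default_window(p: ModelParameters) -> tuple[float, float, float, float]:
    """Analysis window ``(A_lo, A_hi, B_lo, B_hi)``.

    Spans WINDOW_FACTOR times the dissipative bounding box, so every
    equilibrium of the bounded system lies inside.
    """
    a_max, b_max = dissipative_box(p)
    return 0.0, WINDOW_FACTOR * a_max, 0.0, WINDOW_FACTOR * b_max


# ---------------------------------------------------------------------------
# closed-form A-nullcline reduction
# ---------------------------------------------------------------------------

def _removal_A(A, p: ModelParameters):
    out = uptake_rate(A, p.receptor_A) + p.linear_clearance_A * np.asarray(A, float)
    if p.protease_A is not None:
        c = np.asarray(A, float)
        out = out + p.protease_A.vmax * c / (p.protease_A.km + c)
    return out


def _a_nullcline_B(A, p: ModelParameters):
    """B on the A-nullcline for each A; NaN where no admissible B exists.

    Solves ``basal + qmax * act(A) * (K/(K+B))^h = removal_A(A)`` for B.
    """
    pa = p.production_A
    A = np.asarray(A, dtype=float)
    R = _removal_A(A, p)
    act = 1.0
    if p.self_activation_A:
        Ka = pa.activator_dissociation[0]
        act = (A / (Ka + A)) ** pa.hill
    denom = pa.max_rate * act
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (R - pa.basal_rate) / np.where(denom > 0, denom, np.nan)
        x = np.where(x > 0, x, np.nan) ** (1.0 / pa.hill)
        K = pa.inhibitor_dissociation[0]
        B = K * (1.0 - x) / x
    B = np.where((x > 0) & (x <= 1.0), B, np.nan)
    return B


def _dB_dt(A, B, p: ModelParameters):
    _, g = rhs_xy(A, B, p)
    return g


def _scan_grid(lo: float, hi: float, n: int) -> np.ndarray:
    """Uniform plus log-spaced scan points covering [lo, hi]."""
    uni = np.linspace(lo, hi, n)
    if hi > 0:
        logs = np.geomspace(max(hi * 1e-9, 1e-12), hi, n // 2)
        return np.unique(np.concatenate([uni, logs]))
    return uni


def _h_on_curve(a, p: ModelParameters):
    """dB/dt along the closed-form A-nullcline at abscissa(s) ``a``."""
    b = _a_nullcline_B(a, p)
    return _dB_dt(a, b, p)


def _curve_roots(
    A_grid: np.ndarray, in_domain: np.ndarray, p: ModelParameters
) -> list[np.ndarray]:
    """Roots of dB/dt along the A-nullcline over the scan grid ``A_grid``.

    ``in_domain`` marks grid points where the nullcline admits a B >= 0.
    Equilibria can form close pairs (e.g. a saddle and a node just before
    a fold), so beyond plain sign-change bracketing, the neighborhood of
    every sign change, every local minimum of |dB/dt| and every
    domain-segment end is rescanned on a locally refined grid.
    """
    out: list[np.ndarray] = []
    idx = np.where(in_domain)[0]
    if idx.size < 2:
        return out
    A = A_grid[idx]
    h = np.asarray(_h_on_curve(A, p))
    good = np.isfinite(h)
    idx, A, h = idx[good], A[good], h[good]
    if A.size < 2:
        return out
    # a domain break is where masked-out grid points were skipped
    seg_break = np.diff(idx) > 1

    refine: set[int] = set()
    absh = np.abs(h)
    for i in range(A.size):
        if i > 0 and h[i - 1] * h[i] < 0:
            refine.update((i - 1, i))
        is_min = (i == 0 or absh[i] <= absh[i - 1]) and (
            i == A.size - 1 or absh[i] <= absh[i + 1]
        )
        if is_min:
            refine.add(i)
        if i < A.size - 1 and seg_break[i]:
            refine.update((i, i + 1))
    refine.update((0, A.size - 1))

    def brackets(xs, hs):
        res = []
        for i in range(xs.size - 1):
            if hs[i] == 0.0:
                res.append((xs[i], xs[i]))
            elif hs[i] * hs[i + 1] < 0:
                res.append((xs[i], xs[i + 1]))
        if hs.size and hs[-1] == 0.0:
            res.append((xs[-1], xs[-1]))
        return res

    # global pass: every sign change between in-domain neighbors
    all_brackets = []
    for i in range(A.size - 1):
        if seg_break[i]:
            continue
        if h[i] == 0.0:
            all_brackets.append((A[i], A[i]))
        elif h[i] * h[i + 1] < 0:
            all_brackets.append((A[i], A[i + 1]))
    if h[-1] == 0.0:
        all_brackets.append((A[-1], A[-1]))

    # local refinement pass: catch root pairs hidden inside one interval
    for i in sorted(refine):
        lo = A[i - 1] if (i > 0 and not seg_break[i - 1]) else A[i]
        hi = A[i + 1] if (i < A.size - 1 and not seg_break[i]) else A[i]
        if hi <= lo:
            continue
        xs = np.linspace(lo, hi, 257)
        hs = np.asarray(_h_on_curve(xs, p))
        fine_ok = np.isfinite(hs)
        all_brackets.extend(brackets(xs[fine_ok], hs[fine_ok]))

    seen: list[float] = []
    for lo, hi in all_brackets:
        if lo == hi:
            a_root = lo
        else:
            try:
                a_root = optimize.brentq(
                    lambda a: float(_h_on_curve(a, p)), lo, hi,
                    xtol=1e-14, rtol=1e-15,
                )
            except ValueError:  # pragma: no cover - failed bracket
                log.debug("bracket failed on [%g, %g]", lo, hi)
                continue
        if any(abs(a_root - s) < 1e-12 * (1 + abs(a_root)) for s in seen):
            continue
        seen.append(a_root)
        b_root = float(_a_nullcline_B(a_root, p))
        if np.isfinite(b_root):
            out.append(np.array([a_root, b_root]))
    return out


def _polish(seed: np.ndarray, p: ModelParameters) -> Optional[np.ndarray]:
    def fun(y):
        dA, dB = rhs_xy(max(y[0], 0.0), max(y[1], 0.0), p)
        return [dA, dB]

    sol = optimize.root(fun, seed, method="hybr", tol=1e-13)
    y = sol.x
    if y[0] < 0 or y[1] < 0:
        y = np.clip(y, 0.0, None)
    if np.max(np.abs(fun(y))) < ROOT_TOL:
        return y
    return None


def find_equilibria(
    p: ModelParameters,
    window: Optional[tuple[float, float, float, float]] = None,
    seeds: Optional[Sequence] = None,
    *,
    n_scan: int = 400,
    merge_radius: float = MERGE_RADIUS,
    margin: float = STABILITY_MARGIN,
) -> list[Equilibrium]:
    """All distinct equilibria of the model inside the analysis window.

    Candidates come from a dense scan along the closed-form A-nullcline
    (sign changes of dB/dt along it), supplemented by any user seeds;
    every candidate is polished by a 2-D root solve, verified to
    ``|rhs| < 1e-9``, deduplicated within ``merge_radius`` and returned
    sorted by ``conc_A`` with stability classified.
    """
    if window is None:
        window = default_window(p)
    a_lo, a_hi, b_lo, b_hi = window
    if a_lo < 0 or b_lo < 0:
        raise ValueError("analysis window must lie in the nonnegative quadrant")

    candidates: list[np.ndarray] = []
    if p.production_A.max_rate > 0:
        A = _scan_grid(a_lo, a_hi, n_scan)
        # domain edges of the A-nullcline: where removal exactly exhausts
        # maximal production (inhibition factor -> 1, B -> 0).  Equilibria
        # can sit arbitrarily close to these edges, so seed them explicitly.
        pa = p.production_A

        def _excess(a):
            act = 1.0
            if p.self_activation_A:
                Ka = pa.activator_dissociation[0]
                act = (np.asarray(a, float) / (Ka + a)) ** pa.hill
            return _removal_A(a, p) - pa.basal_rate - pa.max_rate * act

        exc = np.asarray(_excess(A))
        edges = []
        for i in range(A.size - 1):
            if exc[i] * exc[i + 1] < 0:
                a_edge = optimize.brentq(
                    lambda a: float(_excess(a)), A[i], A[i + 1], xtol=1e-14
                )
                edges.append(a_edge)
                candidates.append(np.array([a_edge, 0.0]))
        if edges:
            # equilibria cluster where the nullcline dives to B=0: densify
            # the scan geometrically toward each domain edge, both sides
            gap = (a_hi - a_lo) / n_scan
            extra = []
            for a_edge in edges:
                delta = np.geomspace(1e-11 * (1.0 + a_edge), 2 * gap, 48)
                extra.append(a_edge - delta)
                extra.append(a_edge + delta)
            A = np.unique(np.clip(np.concatenate([A, *extra]), a_lo, a_hi))
        B = _a_nullcline_B(A, p)
        ok = np.isfinite(B)
        candidates.extend(_curve_roots(A, ok, p))
    else:
        # degenerate: dA/dt independent of B; A-nullcline is the set of
        # vertical lines where removal_A(A) = basal.  With zero basal and
        # strictly increasing removal that is the B axis (A = 0).
        A_roots = []
        Agrid = _scan_grid(a_lo, a_hi, n_scan)
        r = np.asarray(_removal_A(Agrid, p)) - p.production_A.basal_rate
        if abs(r[0]) < ROOT_TOL:
            A_roots.append(Agrid[0])
        for i in range(r.size - 1):
            if r[i] * r[i + 1] < 0:
                A_roots.append(
                    optimize.brentq(
                        lambda a: float(_removal_A(a, p)) - p.production_A.basal_rate,
                        Agrid[i],
                        Agrid[i + 1],
                        xtol=1e-14,
                    )
                )
        for a0 in A_roots:
            Bgrid = _scan_grid(b_lo, b_hi, n_scan)
            g = np.asarray(_dB_dt(np.full_like(Bgrid, a0), Bgrid, p))
            if abs(g[0]) < ROOT_TOL:
                candidates.append(np.array([a0, Bgrid[0]]))
            for i in range(g.size - 1):
                if g[i] * g[i + 1] < 0:
                    b_root = optimize.brentq(
                        lambda b: float(_dB_dt(a0, b, p)), Bgrid[i], Bgrid[i + 1],
                        xtol=1e-14,
                    )
                    candidates.append(np.array([a0, b_root]))

    for s in seeds or []:
        arr = s.as_array() if isinstance(s, CytokineState) else np.asarray(s, float)
        candidates.append(arr)

    roots: list[np.ndarray] = []
    for c in candidates:
        y = _polish(c, p)
        if y is None:
            log.debug("root polish failed from seed %s", c)
            continue
        if not (a_lo - merge_radius <= y[0] <= a_hi + merge_radius):
            continue
        if not (b_lo - merge_radius <= y[1] <= b_hi + merge_radius):
            continue
        if all(np.hypot(*(y - r)) > merge_radius for r in roots):
            roots.append(y)
    roots.sort(key=lambda y: y[0])
    return [
        classify_stability(CytokineState(y[0], y[1]), p, margin=margin)
        for y in roots
    ]


def classify_stability(
    state: CytokineState,
    p: ModelParameters,
    *,
    margin: float = STABILITY_MARGIN,
) -> Equilibrium:
    """Classify an equilibrium candidate from its Jacobian eigenvalues.

    Real parts below ``-margin`` for both eigenvalues give a stable node
    (real eigenvalues) or focus (complex pair); mixed signs a saddle;
    both above ``+margin`` an unstable node/focus.  Any real part within
    ``margin`` of zero is reported as ``center-marginal`` rather than
    guessed.
    """
    J = jacobian(state, p)
    eig = np.linalg.eigvals(J)
    re = eig.real
    oscillatory = bool(np.max(np.abs(eig.imag)) > margin)
    if np.all(re < -margin):
        stability = "stable-focus" if oscillatory else "stable-node"
    elif np.all(re > margin):
        stability = "unstable-focus" if oscillatory else "unstable-node"
    elif np.min(re) < -margin and np.max(re) > margin:
        stability = "saddle"
    else:
        stability = "center-marginal"
    return Equilibrium(state=state, jacobian=J, eigenvalues=eig, stability=stability)


# ---------------------------------------------------------------------------
# nullcline tracing (generic sweep + bisection, branch stitching)
# ---------------------------------------------------------------------------

def _slice_roots(f, lo: float, hi: float, n: int) -> list[float]:
    """All roots of scalar ``f`` on [lo, hi] by sign scan + bisection."""
    xs = _scan_grid(lo, hi, n)
    vals = np.array([f(x) for x in xs])
    roots = []
    if abs(vals[0]) == 0.0:
        roots.append(xs[0])
    for i in range(len(xs) - 1):
        v0, v1 = vals[i], vals[i + 1]
        if v1 == 0.0:
            roots.append(xs[i + 1])
        elif v0 * v1 < 0:
            roots.append(optimize.brentq(f, xs[i], xs[i + 1], xtol=1e-12))
    return roots


def compute_nullclines(
    p: ModelParameters,
    window: Optional[tuple[float, float, float, float]] = None,
    resolution: int = 200,
) -> tuple[Nullcline, Nullcline]:
    """Trace the A- and B-nullclines inside the window.

    The B-nullcline is swept along ``conc_A`` (solving each slice for
    ``conc_B``) and the A-nullcline along ``conc_B`` (solving for
    ``conc_A``); multiple roots per slice yield separate branches,
    stitched by proximity across consecutive slices, never interpolated
    across branches.
    """
    if window is None:
        window = default_window(p)
    a_lo, a_hi, b_lo, b_hi = window
    if a_lo < 0 or b_lo < 0:
        raise ValueError("window must lie in the nonnegative quadrant")

    def trace(sweep_vals, solve_lo, solve_hi, f_of, order):
        # order: how to assemble (sweep, root) into (conc_A, conc_B)
        open_branches: list[list[np.ndarray]] = []
        closed: list[np.ndarray] = []
        jump = 0.15 * (solve_hi - solve_lo) + 1e-12
        for s in sweep_vals:
            roots = _slice_roots(lambda x: f_of(s, x), solve_lo, solve_hi, 60)
            pts = [np.array(order(s, r)) for r in roots]
            matched = [False] * len(pts)
            next_open: list[list[np.ndarray]] = []
            for br in open_branches:
                last = br[-1]
                best, bestd = None, jump
                for k, pt in enumerate(pts):
                    if matched[k]:
                        continue
                    d = abs(pt[order.solve_axis] - last[order.solve_axis])
                    if d < bestd:
                        best, bestd = k, d
                if best is not None:
                    matched[best] = True
                    br.append(pts[best])
                    next_open.append(br)
                else:
                    closed.append(np.array(br))
            for k, pt in enumerate(pts):
                if not matched[k]:
                    next_open.append([pt])
            open_branches = next_open
        closed.extend(np.array(br) for br in open_branches)
        return tuple(br for br in closed if len(br) >= 2)

    class _OrderAB:  # sweep = conc_A, solved = conc_B
        solve_axis = 1

        def __call__(self, s, r):
            return (s, r)

    class _OrderBA:  # sweep = conc_B, solved = conc_A
        solve_axis = 0

        def __call__(self, s, r):
            return (r, s)

    def f_A(b, a):  # dA/dt as a function of solved conc_A at swept conc_B
        dA, _ = rhs_xy(a, b, p)
        return float(dA)

    def f_B(a, b):  # dB/dt as a function of solved conc_B at swept conc_A
        _, dB = rhs_xy(a, b, p)
        return float(dB)

    sweep_A = _scan_grid(a_lo, a_hi, resolution)
    sweep_B = _scan_grid(b_lo, b_hi, resolution)
    null_B = Nullcline(which="B", branches=trace(sweep_A, b_lo, b_hi, f_B, _OrderAB()))
    null_A = Nullcline(which="A", branches=trace(sweep_B, a_lo, a_hi, f_A, _OrderBA()))
    return null_A, null_B


# ---------------------------------------------------------------------------
# limit-cycle detection via peak-train statistics
# ---------------------------------------------------------------------------

def _refined_peaks(t: np.ndarray, y: np.ndarray, prominence: float):
    """Peak times and heights with parabolic sub-sample refinement."""
    idx, _ = find_peaks(y, prominence=prominence)
    idx = idx[(idx > 0) & (idx < y.size - 1)]
    if idx.size == 0:
        return np.empty(0), np.empty(0)
    dt = t[1] - t[0]
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    denom = y0 - 2 * y1 + y2
    delta = np.where(np.abs(denom) > 0, 0.5 * (y0 - y2) / np.where(denom != 0, denom, 1.0), 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    t_pk = t[idx] + delta * dt
    h_pk = y1 - 0.25 * (y0 - y2) * delta
    return t_pk, h_pk


def detect_limit_cycle(
    p: ModelParameters,
    near: Equilibrium,
    horizon: float = 600.0,
    *,
    offset: float = 1e-3,
    n_peaks: int = 5,
    rel_tol: float = 0.01,
) -> Optional[LimitCycle]:
    """Detect a limit cycle around an unstable equilibrium.

    Two stages.  A cheap probe integrates from a small offset off
    ``near`` over ``horizon`` (extended automatically when the peak train
    suggests a longer period or a slow escape from the equilibrium) to
    ride out the transient and estimate a period.  A refined integration
    then covers ~10 estimated periods at tight tolerance; the cycle is
    accepted when the last ``n_peaks`` peak heights of ``conc_A`` and the
    inter-peak intervals (parabolically interpolated to sub-sample
    precision) each agree to ``rel_tol`` relative.  Returns None, with a
    debug-level diagnostic, when no convergent peak train is found or
    the trajectory escapes the analysis window.
    """
    from .dynamics import simulate  # deferred: dynamics imports this module's API

    if near.is_stable:
        raise ValueError("detect_limit_cycle requires an unstable equilibrium")
    x0 = near.state.as_array()
    scale = 1.0 + np.abs(x0)
    start = CytokineState(*(x0 + offset * scale))
    a_lo, a_hi, b_lo, b_hi = default_window(p)

    # slow escape from a weakly unstable point needs a longer probe
    growth = max(near.leading_real_part, 1e-3)
    probe_h = max(horizon, min(60.0 / growth, 20 * horizon))

    def probe(h):
        traj = simulate(p, start, h, n_out=30000, rtol=1e-7, atol=1e-9)
        if traj.states[:, 0].max() > a_hi or traj.states[:, 1].max() > b_hi:
            return None, None
        keep = traj.times >= 0.5 * h
        t, A = traj.times[keep], traj.conc_A[keep]
        spread = A.max() - A.min()
        if spread < 1e-8:
            return traj, np.empty(0)
        t_pk, _ = _refined_peaks(t, A, prominence=0.05 * spread)
        return traj, t_pk

    max_probe = 200 * probe_h
    traj = t_pk = None
    for _ in range(4):
        traj, t_pk = probe(probe_h)
        if traj is None:
            log.debug("trajectory escaped analysis window: no cycle")
            return None
        if t_pk.size >= n_peaks + 1:
            break
        if probe_h >= max_probe:
            break
        if t_pk.size >= 2:  # period estimate available: extend accordingly
            est = float(np.mean(np.diff(t_pk)))
            probe_h = min(2 * probe_h + 12 * est * (n_peaks + 2), max_probe)
        else:
            probe_h = min(4 * probe_h, max_probe)
    if t_pk is None or t_pk.size < n_peaks + 1:
        log.debug("insufficient peaks (%d) within horizon %g",
                  0 if t_pk is None else t_pk.size, probe_h)
        return None
    period_est = float(np.mean(np.diff(t_pk[-(n_peaks + 1):])))

    # refined stage: restart from the settled tail, resolve ~10 periods
    y_end = traj.states[-1]
    h2 = 10.5 * period_est
    traj2 = simulate(
        p, CytokineState(max(y_end[0], 0), max(y_end[1], 0)), h2,
        n_out=max(6000, 800 * 10), rtol=1e-9, atol=1e-11,
    )
    t, A, B = traj2.times, traj2.conc_A, traj2.conc_B
    spread = A.max() - A.min()
    if spread < 1e-8:
        return None
    t_pk, h_pk = _refined_peaks(t, A, prominence=0.05 * spread)
    if t_pk.size < n_peaks + 1:
        log.debug("refined stage lost the peak train")
        return None
    t_pk, h_pk = t_pk[-(n_peaks + 1):], h_pk[-(n_peaks + 1):]
    intervals = np.diff(t_pk)
    if intervals.min() <= 0:
        return None
    h_ok = (h_pk.max() - h_pk.min()) <= rel_tol * abs(h_pk.mean())
    i_ok = (intervals.max() - intervals.min()) <= rel_tol * intervals.mean()
    if not (h_ok and i_ok):
        log.debug("peak train not converged: heights %s intervals %s",
                  h_pk, intervals)
        return None
    period = float(intervals.mean())
    sel = (t >= t_pk[-2]) & (t <= t_pk[-1])
    orbit = np.column_stack([A[sel], B[sel]])
    return LimitCycle(
        period=period,
        amplitude_A=float(A[sel].max() - A[sel].min()),
        amplitude_B=float(B[sel].max() - B[sel].min()),
        orbit=orbit,
        enclosed_equilibrium=near,
    )


# ---------------------------------------------------------------------------
# vector field and basin-of-attraction map
# ---------------------------------------------------------------------------

def vector_field(
    p: ModelParameters,
    window: Optional[tuple[float, float, float, float]] = None,
    resolution: int = 25,
):
    """Evaluate the right-hand side on a lattice.

    Returns ``(A_mesh, B_mesh, dA, dB)`` arrays of shape
    ``(resolution, resolution)``.
    """
    if window is None:
        window = default_window(p)
    a_lo, a_hi, b_lo, b_hi = window
    A, B = np.meshgrid(
        np.linspace(a_lo, a_hi, resolution), np.linspace(b_lo, b_hi, resolution)
    )
    dA, dB = rhs_xy(A, B, p)
    return A, B, dA, dB


def basin_map(
    p: ModelParameters,
    window: Optional[tuple[float, float, float, float]] = None,
    resolution: int = 20,
    horizon: float = 400.0,
    *,
    attractors: Optional[Sequence] = None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> BasinMap:
    """Label each lattice initial state by the attractor it reaches.

    Attractors are the stable equilibria plus any limit cycle detected
    around an unstable (non-saddle) equilibrium.  A point is labeled when
    its trajectory ends within tolerance of an equilibrium (dwelling
    there over the final 10% of the horizon) or tracks a cycle orbit;
    otherwise it is unresolved (-1).
    """
    from .dynamics import simulate

    if window is None:
        window = default_window(p)
    a_lo, a_hi, b_lo, b_hi = window
    if attractors is None:
        eqs = find_equilibria(p, window)
        attractors = [e for e in eqs if e.is_stable]
        for e in eqs:
            if not e.is_stable and e.stability != "saddle":
                cyc = detect_limit_cycle(p, e)
                if cyc is not None:
                    attractors.append(cyc)
    if not attractors:
        raise ValueError("basin_map requires at least one attractor")

    A_values = np.linspace(a_lo, a_hi, resolution)
    B_values = np.linspace(b_lo, b_hi, resolution)
    labels = np.full((resolution, resolution), -1, dtype=int)
    eq_tol = 10 * SETTLE_TOL_BASIN
    for i, b0 in enumerate(B_values):
        for j, a0 in enumerate(A_values):
            traj = simulate(
                p, CytokineState(a0, b0), horizon, rtol=rtol, atol=atol, n_out=400
            )
            tail = traj.states[traj.times >= 0.9 * horizon]
            final = traj.states[-1]
            for k, att in enumerate(attractors):
                if isinstance(att, Equilibrium):
                    tgt = att.state.as_array()
                    if np.all(np.hypot(tail[:, 0] - tgt[0], tail[:, 1] - tgt[1]) < eq_tol):
                        labels[i, j] = k
                        break
                else:  # LimitCycle: final state close to the orbit
                    d = np.min(np.hypot(att.orbit[:, 0] - final[0],
                                        att.orbit[:, 1] - final[1]))
                    orbit_scale = max(att.amplitude_A, att.amplitude_B)
                    if d < 0.05 * orbit_scale:
                        labels[i, j] = k
                        break
    return BasinMap(
        A_values=A_values,
        B_values=B_values,
        labels=labels,
        attractors=tuple(attractors),
    )
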