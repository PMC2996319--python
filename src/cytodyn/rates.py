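"""Rate laws of the two-cytokine model and the assembled ODE right-hand side.

Three building blocks:

* dose-dependent production — basal rate plus a maximal rate modulated by
  Michaelis-Menten activation factors ``c/(K+c)`` and inhibition factors
  ``K/(K+c)``, one per regulating cytokine;
* receptor-mediated uptake — the flux of cytokine internalized with its
  receptor, proportional to occupied surface receptors, where the surface
  receptor pool itself equilibrates between internalization and recycling
  and therefore shrinks at high ligand concentration (this is what can
  make uptake non-monotone in concentration);
* clearance — first-order removal (capillary exchange plus linearized
  protease degradation), optionally augmented by a saturating protease
  term.

All functions accept scalars or numpy arrays for the concentration
arguments and broadcast elementwise.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

from .params import (
    CytokineState,
    ModelParameters,
    ProductionParams,
    ReceptorParams,
    SaturatingClearance,
)

__all__ = [
    "production_rate",
    "surface_receptor_fraction",
    "uptake_rate",
    "rhs",
    "rhs_xy",
    "jacobian",
    "dissipative_box",
]

ArrayLike = Union[float, np.ndarray]


def production_rate(
    activators: Sequence[ArrayLike],
    inhibitors: Sequence[ArrayLike],
    p: ProductionParams,
) -> ArrayLike:
    """Cytokine production rate under activatory and inhibitory inputs.

    Returns ``basal + max_rate * prod_i [a_i/(K_i+a_i)]^h *
    prod_j [K_j/(K_j+c_j)]^h``.  The value is bounded between
    ``basal_rate`` and ``basal_rate + max_rate`` for any nonnegative
    inputs.

    Raises
    ------
    ValueError
        If the number of supplied concentrations does not match the
        parameter structure, or any concentration is negative.
    """
    if len(activators) != p.activator_count:
        raise ValueError(
            f"expected {p.activator_count} activator concentration(s), "
            f"got {len(activators)}"
        )
    if len(inhibitors) != p.inhibitor_count:
        raise ValueError(
            f"expected {p.inhibitor_count} inhibitor concentration(s), "
            f"got {len(inhibitors)}"
        )
    factor = 1.0
    for c, K in zip(activators, p.activator_dissociation):
        c = np.asarray(c, dtype=float)
        if np.any(c < 0):
            raise ValueError("activator concentrations must be >= 0")
        f = c / (K + c)
        factor = factor * (f if p.hill == 1.0 else f**p.hill)
    for c, K in zip(inhibitors, p.inhibitor_dissociation):
        c = np.asarray(c, dtype=float)
        if np.any(c < 0):
            raise ValueError("inhibitor concentrations must be >= 0")
        f = K / (K + c)
        factor = factor * (f if p.hill == 1.0 else f**p.hill)
    return p.basal_rate + p.max_rate * factor


def surface_receptor_fraction(conc: ArrayLike, r: ReceptorParams) -> ArrayLike:
    """Steady-state fraction of receptors on the cell surface.

    With bound fraction ``b = c/(Kd+c)``, surface receptors internalize
    at the occupancy-weighted rate ``ki_eff = ki_free*(1-b) + ki_bound*b``
    and recover from the internal pool at ``recovery_rate``.  Setting the
    surface-pool balance to zero under receptor conservation gives

        fraction = recovery_rate / (recovery_rate + ki_eff(c))

    which interpolates from ``kr/(kr+ki_free)`` at zero concentration to
    ``kr/(kr+ki_bound)`` at saturation.  Always in [0, 1].
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    b = conc / (r.ligand_dissociation + conc)
    ki_eff = r.internalization_rate_free * (1.0 - b) + r.internalization_rate_bound * b
    denom = r.recovery_rate + ki_eff
    # denom can only vanish if recovery and both internalization rates are
    # zero, which ReceptorParams rejects at construction; guard anyway for
    # the pathological all-zero-at-this-conc case (kr=0, ki_eff(c)=0).
    out = np.where(denom > 0, r.recovery_rate / np.where(denom > 0, denom, 1.0), np.nan)
    if np.any(np.isnan(out)):
        raise ValueError(
            "surface receptor steady state undefined: recovery and effective "
            "internalization both vanish at this concentration"
        )
    return out if out.ndim else float(out)


def uptake_rate(conc: ArrayLike, r: ReceptorParams) -> ArrayLike:
    """Receptor-mediated cytokine uptake flux at concentration ``conc``.

    The flux is proportional to the bound surface receptors (occupancy
    ``c/(Kd+c)`` times the steady-state surface pool) multiplied once
    more by the surface pool — uptake requires an encounter between a
    bound receptor and the internalization machinery of the surface pool
    — with one receptor-count factor folded into the normalization:

        uptake = uptake_normalization * total_receptors
                 * occupancy * surface_fraction**2

    Zero at zero concentration and bounded by ``uptake_normalization *
    total_receptors``.  Because the surface fraction shrinks with
    concentration when bound receptors internalize faster than they
    recover (``ki_bound > kr + 2*ki_free``), the flux is then
    non-monotone: it rises, peaks at bound fraction ``(kr+ki_free) /
    (ki_bound-ki_free)``, and declines toward ``u*R*(kr/(kr+ki_bound))**2``.
    This is the nonlinearity that enables multistability and
    oscillations in the coupled system.
    """
    conc = np.asarray(conc, dtype=float)
    occupancy = conc / (r.ligand_dissociation + conc)
    s = surface_receptor_fraction(conc, r)
    out = r.uptake_normalization * r.total_receptors * occupancy * s * s
    return out if np.ndim(out) else float(out)


def _removal(conc: ArrayLike, rec: ReceptorParams, lam: float,
             prot: Optional[SaturatingClearance]) -> ArrayLike:
    out = uptake_rate(conc, rec) + lam * np.asarray(conc, dtype=float)
    if prot is not None:
        c = np.asarray(conc, dtype=float)
        out = out + prot.vmax * c / (prot.km + c)
    return out


def rhs_xy(A: ArrayLike, B: ArrayLike, p: ModelParameters):
    """Vectorized right-hand side: time derivatives ``(dA/dt, dB/dt)``.

    dA/dt = production_A(inhibited by B[, self-activated by A])
            - uptake_A(A) - clearance_A * A
    dB/dt = production_B(activated by A) - uptake_B(B) - clearance_B * B
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValueError("non-finite cytokine state")
    acts_A = [A] if p.self_activation_A else []
    prod_A = production_rate(acts_A, [B], p.production_A)
    prod_B = production_rate([A], [], p.production_B)
    dA = prod_A - _removal(A, p.receptor_A, p.linear_clearance_A, p.protease_A)
    dB = prod_B - _removal(B, p.receptor_B, p.linear_clearance_B, p.protease_B)
    return dA, dB


def rhs(state: CytokineState, p: ModelParameters) -> tuple[float, float]:
    """Time derivatives of the two cytokine concentrations at ``state``."""
    dA, dB = rhs_xy(state.conc_A, state.conc_B, p)
    return float(dA), float(dB)


def jacobian(state, p: ModelParameters, rel_step: float = 1e-6) -> np.ndarray:
    """Jacobian of the right-hand side by central finite differences.

    The step for each coordinate is ``rel_step * (1 + |value|)``, so the
    stencil stays inside the nonnegative quadrant for states at least one
    step away from the axes; on the axes a forward-shifted stencil is
    used for that coordinate.
    """
    x = state.as_array() if isinstance(state, CytokineState) else np.asarray(state, float)
    J = np.empty((2, 2))
    for j in range(2):
        h = rel_step * (1.0 + abs(x[j]))
        lo, hi = x.copy(), x.copy()
        hi[j] += h
        lo[j] -= h
        if lo[j] < 0:  # keep the stencil in the admissible quadrant
            lo[j] = x[j]
            hi[j] = x[j] + 2 * h
        fhi = rhs_xy(hi[0], hi[1], p)
        flo = rhs_xy(lo[0], lo[1], p)
        J[0, j] = (fhi[0] - flo[0]) / (hi[j] - lo[j])
        J[1, j] = (fhi[1] - flo[1]) / (hi[j] - lo[j])
    return J


def dissipative_box(p: ModelParameters, margin: float = 1.0) -> tuple[float, float]:
    """Upper bounds ``(A_max, B_max)`` of the forward-invariant box.

    Above ``(basal + max_rate) / linear_clearance`` the corresponding
    derivative is strictly negative regardless of the other cytokine, so
    trajectories enter and remain in ``[0, A_max] x [0, B_max]``.
    ``margin`` scales the box outward.  Requires strictly positive linear
    clearances (the uptake flux saturates and cannot bound production by
    itself).
    """
    if p.linear_clearance_A <= 0 or p.linear_clearance_B <= 0:
        raise ValueError(
            "dissipative box requires strictly positive linear clearances"
        )
    pa, pb = p.production_A, p.production_B
    A_max = (pa.basal_rate + pa.max_rate) / p.linear_clearance_A
    B_max = (pb.basal_rate + pb.max_rate) / p.linear_clearance_B
    return margin * A_max, margin * B_max
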