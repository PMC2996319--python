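"""Calibration of production laws to tabulated dose-response data.

Experimentally, a cell population's cytokine output is measured at a
series of input-cytokine doses (e.g. IL-17 output as a function of
extracellular IL-23).  The composite steady-state curve modeled here is
the production law driven by the input as activator and, optionally,
inhibited by the input's own receptor-uptake flux: as the dose rises the
bound-receptor signal first grows (suppressing output) and then shrinks
again as receptors internalize, which reproduces the experimentally
observed plateau-dip-rise shape.  Without the receptor module the curve
is plain monotone-saturating.

Output is reported on the concentration scale of the measurements: the
production law's ``max_rate``/``basal_rate`` here absorb the first-order
clearance that converts a production rate into a steady-state
concentration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .params import ProductionParams, ReceptorParams
from .rates import production_rate, uptake_rate

__all__ = ["composite_response", "fit_dose_response", "DoseResponseFit"]

PRODUCTION_FREE = (
    "max_rate",
    "basal_rate",
    "activator_dissociation",
    "inhibitor_dissociation",
)
RECEPTOR_FREE = (
    "ligand_dissociation",
    "internalization_rate_bound",
    "internalization_rate_free",
    "recovery_rate",
    "uptake_normalization",
)


def composite_response(
    conc,
    production: ProductionParams,
    receptor: Optional[ReceptorParams] = None,
):
    """Steady-state output concentration at input concentration ``conc``.

    ``production`` must have exactly one activator (the input).  With a
    ``receptor``, it must also have exactly one inhibitor, whose
    concentration-equivalent signal is the receptor uptake flux of the
    input; without one, it must have no inhibitors.
    """
    conc = np.asarray(conc, dtype=float)
    if production.activator_count != 1:
        raise ValueError("composite curve needs exactly one activator (the input)")
    if receptor is None:
        if production.inhibitor_count != 0:
            raise ValueError("no receptor given but production expects an inhibitor")
        return production_rate([conc], [], production)
    if production.inhibitor_count != 1:
        raise ValueError("receptor given: production needs exactly one inhibitor")
    signal = uptake_rate(conc, receptor)
    return production_rate([conc], [signal], production)


@dataclass(frozen=True)
class DoseResponseFit:
    """Result of a dose-response calibration."""

    production: ProductionParams
    receptor: Optional[ReceptorParams]
    free_names: tuple[str, ...]
    values: dict[str, float]
    residuals: np.ndarray
    cost: float
    success: bool
    message: str
    n_starts_converged: int

    def predict(self, conc):
        return composite_response(conc, self.production, self.receptor)


def _get(params, rec, name):
    if name in PRODUCTION_FREE:
        v = getattr(params, name)
        return v[0] if isinstance(v, tuple) else v
    return getattr(rec, name)


def _with(params: ProductionParams, rec: Optional[ReceptorParams], values: dict):
    pkw, rkw = {}, {}
    for name, v in values.items():
        if name in ("activator_dissociation", "inhibitor_dissociation"):
            pkw[name] = (v,)
        elif name in PRODUCTION_FREE:
            pkw[name] = v
        else:
            rkw[name] = v
    p = dataclasses.replace(params, **pkw) if pkw else params
    r = dataclasses.replace(rec, **rkw) if (rkw and rec is not None) else rec
    return p, r


def fit_dose_response(
    table: Union[Sequence, "np.ndarray"],
    free: Sequence[str],
    *,
    production: ProductionParams,
    receptor: Optional[ReceptorParams] = None,
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    n_starts: int = 8,
    seed: int = 0,
) -> DoseResponseFit:
    """Box-constrained least-squares fit of the composite response curve.

    Parameters
    ----------
    table
        Sequence of ``(input_conc, output_conc)`` pairs (or a DataFrame
        with columns ``input_conc, output_conc``).
    free
        Names of the free parameters, drawn from the production fields
        (``max_rate``, ``basal_rate``, ``activator_dissociation``,
        ``inhibitor_dissociation``) and, when a receptor is supplied,
        the receptor fields.
    production, receptor
        Baseline parameter objects supplying the fixed values and the
        structure of the composite curve.
    bounds
        Per-parameter ``(lo, hi)`` boxes; defaults to wide positive
        ranges scaled to the data.
    n_starts
        Number of seeded multi-start optimizations (log-spaced starting
        points); the lowest-cost converged fit wins, ties broken by the
        smaller parameter norm.

    Raises
    ------
    ValueError
        If there are fewer data points than free parameters.  A fit in
        which no start converges is returned with ``success=False`` and
        an explanatory message, never silently.
    """
    if hasattr(table, "columns"):
        data = np.column_stack(
            [np.asarray(table["input_conc"]), np.asarray(table["output_conc"])]
        )
    else:
        data = np.asarray(table, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("table must be pairs of (input_conc, output_conc)")
    if np.any(data < 0):
        raise ValueError("concentrations must be nonnegative")
    x, y = data[:, 0], data[:, 1]
    free = tuple(free)
    if len(free) == 0:
        raise ValueError("no free parameters requested")
    if data.shape[0] < len(free):
        raise ValueError(
            f"{data.shape[0]} data points cannot constrain {len(free)} parameters"
        )
    for name in free:
        if name in RECEPTOR_FREE and receptor is None:
            raise ValueError(f"free parameter {name!r} requires a receptor")
        if name not in PRODUCTION_FREE + RECEPTOR_FREE:
            raise ValueError(f"unknown free parameter {name!r}")

    yscale = max(float(np.max(y)), 1e-12)
    xscale = max(float(np.max(x[x > 0], initial=1.0)), 1e-12)
    default_bounds = {
        "max_rate": (1e-4 * yscale, 1e3 * yscale),
        "basal_rate": (1e-9 * yscale, 1e2 * yscale),
        "activator_dissociation": (1e-4 * xscale, 1e3 * xscale),
        "inhibitor_dissociation": (1e-6, 1e6),
        "ligand_dissociation": (1e-4 * xscale, 1e3 * xscale),
        "internalization_rate_bound": (1e-4, 1e4),
        "internalization_rate_free": (1e-6, 1e4),
        "recovery_rate": (1e-4, 1e4),
        "uptake_normalization": (1e-6, 1e6),
    }
    if bounds:
        default_bounds.update(bounds)
    lo = np.log10([default_bounds[n][0] for n in free])
    hi = np.log10([default_bounds[n][1] for n in free])

    def residual(logv):
        values = dict(zip(free, 10.0 ** logv))
        prod, rec = _with(production, receptor, values)
        return composite_response(x, prod, rec) - y

    rng = np.random.default_rng(seed)
    starts = [lo + rng.random(len(free)) * (hi - lo) for _ in range(max(n_starts, 1))]
    # also start from the baseline values when they are inside the box
    base = np.log10(
        [max(_get(production, receptor, n), 10.0 ** l) for n, l in zip(free, lo)]
    )
    starts.insert(0, np.clip(base, lo, hi))

    best = None
    n_ok = 0
    for s in starts:
        try:
            res = least_squares(
                residual, s, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
        except Exception:  # pragma: no cover - solver blow-up on a bad start
            continue
        if not res.success:
            continue
        n_ok += 1
        key = (res.cost, float(np.linalg.norm(res.x)))
        if best is None or key < best[0]:
            best = (key, res)

    if best is None:
        return DoseResponseFit(
            production=production,
            receptor=receptor,
            free_names=free,
            values={},
            residuals=np.full_like(y, np.nan),
            cost=float("inf"),
            success=False,
            message=f"no start converged out of {len(starts)}",
            n_starts_converged=0,
        )
    res = best[1]
    values = dict(zip(free, 10.0 ** res.x))
    prod, rec = _with(production, receptor, values)
    return DoseResponseFit(
        production=prod,
        receptor=rec,
        free_names=free,
        values=values,
        residuals=res.fun,
        cost=float(res.cost),
        success=True,
        message="converged",
        n_starts_converged=n_ok,
    )
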