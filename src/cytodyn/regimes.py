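"""Dynamical-regime classification and seeded parameter-space search.

The model supports three qualitatively distinct behaviors depending on
parameters: a single stable homeostatic point, a bistable trigger (two
stable levels separated by a saddle), and oscillations (a limit cycle,
either coexisting with a stable point or as the only attractor).  This
module classifies a parameter set into these regimes from its equilibria,
their stability and cycle detection, and searches parameter space by
seeded log-scale Latin-hypercube sampling to produce exemplar sets deep
inside each regime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import qmc

from .params import ModelParameters, ProductionParams, ReceptorParams
from .phase import (
    Equilibrium,
    LimitCycle,
    detect_limit_cycle,
    find_equilibria,
)

__all__ = [
    "RegimeReport",
    "classify_regime",
    "stability_margin",
    "search_regimes",
    "SweepRecord",
    "DEFAULT_BOUNDS",
    "parameters_from_sample",
]

log = logging.getLogger(__name__)

MONOSTABLE = "monostable-homeostasis"
TRIGGER = "bistable-trigger"
OSC_COEXISTING = "oscillatory-coexisting"
OSC_PURE = "oscillatory-pure"
NEAR_BIFURCATION = "unclassified-near-bifurcation"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class RegimeReport:
    """Classification of a parameter set with its supporting evidence."""

    regime: str
    equilibria: tuple[Equilibrium, ...]
    cycles: tuple[LimitCycle, ...]
    parameters: ModelParameters

    @property
    def n_stable(self) -> int:
        return sum(e.is_stable for e in self.equilibria)

    @property
    def n_unstable(self) -> int:
        return len(self.equilibria) - self.n_stable


def classify_regime(
    p: ModelParameters,
    *,
    detect_cycles: bool = True,
    cycle_horizon: float = 600.0,
) -> RegimeReport:
    """Classify a parameter set into a dynamical regime.

    Finds all equilibria, classifies their stability, and runs cycle
    detection around each unstable non-saddle equilibrium (a cycle in the
    plane must enclose net index +1, which a lone saddle cannot supply).
    Labels:

    * ``monostable-homeostasis`` — exactly one stable equilibrium, no cycle
    * ``bistable-trigger`` — exactly two stable plus at least one unstable
      equilibrium, no cycle
    * ``oscillatory-coexisting`` — a stable equilibrium and a limit cycle
    * ``oscillatory-pure`` — a limit cycle with no stable equilibrium
    * ``unclassified-near-bifurcation`` — a marginal eigenvalue makes the
      call unreliable; never a forced guess
    """
    equilibria = find_equilibria(p)
    if any(e.stability == "center-marginal" for e in equilibria):
        return RegimeReport(NEAR_BIFURCATION, tuple(equilibria), (), p)
    cycles: list[LimitCycle] = []
    if detect_cycles:
        for e in equilibria:
            if not e.is_stable and e.stability != "saddle":
                cyc = detect_limit_cycle(p, e, horizon=cycle_horizon)
                if cyc is not None:
                    cycles.append(cyc)
    n_stable = sum(e.is_stable for e in equilibria)
    n_unstable = len(equilibria) - n_stable
    if cycles:
        regime = OSC_COEXISTING if n_stable >= 1 else OSC_PURE
    elif n_stable == 1:
        regime = MONOSTABLE
    elif n_stable == 2 and n_unstable >= 1:
        regime = TRIGGER
    else:
        regime = UNCLASSIFIED
    return RegimeReport(regime, tuple(equilibria), tuple(cycles), p)


def stability_margin(p_or_report) -> float:
    """Distance from neutrality: min over equilibria of |Re(leading eigenvalue)|.

    The leading eigenvalue is the one with the largest real part.  Larger
    margin means deeper inside the regime (farther from a local
    bifurcation); a set tuned to a bifurcation has margin near zero.
    """
    report = (
        p_or_report
        if isinstance(p_or_report, RegimeReport)
        else classify_regime(p_or_report, detect_cycles=False)
    )
    if not report.equilibria:
        return 0.0
    return min(abs(e.leading_real_part) for e in report.equilibria)


# ---------------------------------------------------------------------------
# parameter-space sweep
# ---------------------------------------------------------------------------

#: Sampled parameters (log10-uniform within bounds).  Receptor pools enter
#: the dynamics only through the product uptake_normalization *
#: total_receptors, so a single uptake-capacity scale is sampled with
#: total_receptors fixed at 1.  Free-receptor internalization is kept slow
#: (0.01) and basal secretion at 1e-4 of the maximal rate, so sampling
#: concentrates on the axes that move the system between regimes: the
#: production scales and affinities, the uptake capacity and its binding
#: scale, the bound-receptor internalization vs recovery competition, and
#: the linear clearances.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "qmax_A": (10 ** -1.5, 10 ** 1.5),
    "qmax_B": (10 ** -1.5, 10 ** 1.5),
    "K_inh_B": (10 ** -1.5, 10 ** 1.5),   # inhibition of A-production by B
    "K_act_A": (10 ** -1.5, 10 ** 1.5),   # activation of B-production by A
    "uptake_A": (10 ** -1.5, 10 ** 1.5),
    "uptake_B": (10 ** -1.5, 10 ** 1.5),
    "Kd_A": (10 ** -1.5, 10 ** 1.5),
    "Kd_B": (10 ** -1.5, 10 ** 1.5),
    "ki_bound_A": (10 ** -1.5, 10 ** 1.5),
    "ki_bound_B": (10 ** -1.5, 10 ** 1.5),
    "kr_A": (10 ** -1.5, 10 ** 1.5),
    "kr_B": (10 ** -1.5, 10 ** 1.5),
    "clearance_A": (10 ** -2.0, 10 ** 0.5),
    "clearance_B": (10 ** -2.0, 10 ** 0.5),
}

KI_FREE = 0.01          # fixed free-receptor internalization rate
BASAL_FRACTION = 1e-4   # basal secretion as a fraction of max_rate


def parameters_from_sample(sample: dict[str, float]) -> ModelParameters:
    """Assemble a ModelParameters from a named sample of sweep axes."""

    def receptor(which: str) -> ReceptorParams:
        return ReceptorParams(
            total_receptors=1.0,
            ligand_dissociation=sample[f"Kd_{which}"],
            internalization_rate_bound=sample[f"ki_bound_{which}"],
            internalization_rate_free=sample.get(f"ki_free_{which}", KI_FREE),
            recovery_rate=sample[f"kr_{which}"],
            uptake_normalization=sample[f"uptake_{which}"],
        )

    return ModelParameters(
        production_A=ProductionParams(
            max_rate=sample["qmax_A"],
            inhibitor_dissociation=(sample["K_inh_B"],),
            basal_rate=BASAL_FRACTION * sample["qmax_A"],
        ),
        production_B=ProductionParams(
            max_rate=sample["qmax_B"],
            activator_dissociation=(sample["K_act_A"],),
            basal_rate=BASAL_FRACTION * sample["qmax_B"],
        ),
        receptor_A=receptor("A"),
        receptor_B=receptor("B"),
        linear_clearance_A=sample["clearance_A"],
        linear_clearance_B=sample["clearance_B"],
    )


@dataclass(frozen=True)
class SweepRecord:
    """One classified sample of a parameter sweep."""

    index: int
    sample: dict[str, float]
    regime: str
    n_equilibria: int
    n_stable: int
    margin: float


def search_regimes(
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    n_samples: int = 1000,
    seed: int = 0,
    *,
    k_exemplars: int = 3,
    cycle_horizon: float = 400.0,
    progress: bool = False,
):
    """Seeded log-scale Latin-hypercube sweep over parameter space.

    Every sample is classified; for each regime up to ``k_exemplars``
    parameter sets are returned, preferring those deepest inside the
    regime (largest stability margin).  A regime with no hits is reported
    as an empty list, never fabricated.  Reproducible given
    ``(bounds, n_samples, seed)``.

    Returns
    -------
    exemplars : dict[str, list[ModelParameters]]
    records : list[SweepRecord]
        The full sweep ledger, one record per sample.
    """
    if bounds is None:
        bounds = DEFAULT_BOUNDS
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    names = list(bounds)
    lo = np.log10([bounds[n][0] for n in names])
    hi = np.log10([bounds[n][1] for n in names])
    if np.any(hi < lo):
        raise ValueError("bounds must be ordered (lo <= hi)")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n=n_samples)
    values = 10 ** (lo + unit * (hi - lo))

    records: list[SweepRecord] = []
    best: dict[str, list[tuple[float, ModelParameters]]] = {}
    iterator = range(n_samples)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc="sweep")
        except ImportError:
            pass
    for i in iterator:
        sample = dict(zip(names, values[i]))
        p = parameters_from_sample(sample)
        try:
            report = classify_regime(p, cycle_horizon=cycle_horizon)
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("sample %d failed classification: %s", i, exc)
            records.append(SweepRecord(i, sample, "failed", 0, 0, float("nan")))
            continue
        margin = stability_margin(report)
        records.append(
            SweepRecord(
                index=i,
                sample=sample,
                regime=report.regime,
                n_equilibria=len(report.equilibria),
                n_stable=report.n_stable,
                margin=margin,
            )
        )
        best.setdefault(report.regime, []).append((margin, p))
    exemplars = {
        regime: [p for _, p in sorted(hits, key=lambda t: -t[0])[:k_exemplars]]
        for regime, hits in best.items()
    }
    return exemplars, records
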