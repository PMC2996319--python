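"""Parameter containers for the two-cytokine interaction model.

The model couples two immune cell populations through the extracellular
concentrations of two cytokines, A and B.  Population 1 secretes A and is
inhibited by B; population 2 secretes B and is activated by A.  Each
cytokine is removed by receptor-mediated uptake (endocytosis of
ligand-bound receptors) and by a lumped first-order clearance that
aggregates capillary exchange and protease degradation.

All default parameter sets are expressed in normalized (dimensionless)
units: concentrations and rates are scaled so that typical values are of
order 0.01-100.  :func:`normalize_parameters` maps a dimensional,
tissue-level description (cell counts, surface areas, capillary
permeability, protease kinetics) onto this normalized vector.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "ProductionParams",
    "ReceptorParams",
    "SaturatingClearance",
    "RawTissueParameters",
    "ModelParameters",
    "CytokineState",
    "normalize_parameters",
]


def _as_tuple(x) -> tuple[float, ...]:
    if x is None:
        return ()
    if isinstance(x, (int, float)):
        return (float(x),)
    return tuple(float(v) for v in x)


@dataclass(frozen=True)
class ProductionParams:
    """Dose-dependent cytokine production law.

    Production is a basal rate plus a maximal rate modulated by a product
    of Michaelis-Menten occupancy factors, one per regulating cytokine:
    activators contribute ``c/(K+c)`` and inhibitors ``K/(K+c)``.  The
    ``hill`` exponent applies to every factor and defaults to 1 (simple
    hyperbolic binding); it exists for forward-compatibility only.

    Parameters
    ----------
    max_rate : float
        Maximal regulated production rate (concentration/time). The
        normalization coefficient of the production law.
    activator_dissociation, inhibitor_dissociation : tuple of float
        Dissociation constants (concentration) of each activatory /
        inhibitory input, in input order.  Their lengths define the
        number of activators / inhibitors.
    basal_rate : float
        Constitutive secretion rate, independent of any input.
    hill : float
        Cooperativity exponent applied to each occupancy factor.
    """

    max_rate: float
    activator_dissociation: tuple[float, ...] = ()
    inhibitor_dissociation: tuple[float, ...] = ()
    basal_rate: float = 0.0
    hill: float = 1.0

    def __post_init__(self):
        object.__setattr__(
            self, "activator_dissociation", _as_tuple(self.activator_dissociation)
        )
        object.__setattr__(
            self, "inhibitor_dissociation", _as_tuple(self.inhibitor_dissociation)
        )
        if self.max_rate < 0:
            raise ValueError(f"max_rate must be >= 0, got {self.max_rate}")
        if self.basal_rate < 0:
            raise ValueError(f"basal_rate must be >= 0, got {self.basal_rate}")
        for k in self.activator_dissociation + self.inhibitor_dissociation:
            if not k > 0:
                raise ValueError(f"dissociation constants must be > 0, got {k}")
        if not self.hill > 0:
            raise ValueError("hill exponent must be > 0")

    @property
    def activator_count(self) -> int:
        return len(self.activator_dissociation)

    @property
    def inhibitor_count(self) -> int:
        return len(self.inhibitor_dissociation)


@dataclass(frozen=True)
class ReceptorParams:
    """Receptor binding / internalization / recycling parameters.

    The total receptor pool per cell is conserved between a surface and an
    internalized fraction.  Ligand-bound receptors internalize at
    ``internalization_rate_bound``, free ones at
    ``internalization_rate_free``, and internalized receptors return to
    the surface at ``recovery_rate``.  The steady state of this exchange
    sets the surface receptor fraction as a function of extracellular
    cytokine concentration; uptake flux is proportional to occupied
    surface receptors.
    """

    total_receptors: float
    ligand_dissociation: float
    internalization_rate_bound: float
    internalization_rate_free: float
    recovery_rate: float
    uptake_normalization: float

    def __post_init__(self):
        if self.total_receptors < 0:
            raise ValueError("total_receptors must be >= 0")
        if not self.ligand_dissociation > 0:
            raise ValueError("ligand_dissociation must be > 0")
        for name in (
            "internalization_rate_bound",
            "internalization_rate_free",
            "recovery_rate",
            "uptake_normalization",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if (
            self.recovery_rate
            + self.internalization_rate_bound
            + self.internalization_rate_free
        ) <= 0:
            raise ValueError(
                "receptor exchange degenerate: recovery and internalization "
                "rates are all zero, surface steady state undefined"
            )


@dataclass(frozen=True)
class SaturatingClearance:
    """Michaelis-Menten protease degradation term ``vmax*c/(km+c)``.

    Optional alternative to the linearized protease contribution folded
    into the linear clearance.
    """

    vmax: float
    km: float

    def __post_init__(self):
        if self.vmax < 0:
            raise ValueError("vmax must be >= 0")
        if not self.km > 0:
            raise ValueError("km must be > 0")


@dataclass(frozen=True)
class RawTissueParameters:
    """Dimensional tissue-level balance parameters for one cytokine.

    Describes the elementary tissue volume: how many producing and
    receptor-bearing cells it contains, their surface areas, the
    capillary exchange surface, and protease kinetics.  Used only as the
    source side of :func:`normalize_parameters`; the dynamical code runs
    on the normalized :class:`ModelParameters`.
    """

    producing_cell_surface_area: float
    producing_cell_count: float
    tissue_volume: float
    uptake_cell_surface_area: float
    uptake_cell_count: float
    capillary_surface_area: float
    capillary_permeability: float
    blood_cytokine_concentration: float
    protease_vmax: float
    protease_concentration: float
    protease_km: float
    basal_secretion_rate: float

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")
        if not self.tissue_volume > 0:
            raise ValueError("tissue_volume must be > 0")


@dataclass(frozen=True)
class CytokineState:
    """Nonnegative extracellular concentrations of the two cytokines."""

    conc_A: float
    conc_B: float

    def __post_init__(self):
        import math

        if not (math.isfinite(self.conc_A) and math.isfinite(self.conc_B)):
            raise ValueError("cytokine concentrations must be finite")
        if self.conc_A < 0 or self.conc_B < 0:
            raise ValueError(
                f"cytokine concentrations must be >= 0, "
                f"got ({self.conc_A}, {self.conc_B})"
            )

    def as_array(self):
        import numpy as np

        return np.array([self.conc_A, self.conc_B], dtype=float)


@dataclass(frozen=True)
class ModelParameters:
    """Normalized parameter vector of the final two-ODE system.

    ``production_A`` must have zero activators and exactly one inhibitor
    (B inhibits A production) unless ``self_activation_A`` is set, in
    which case it has one activator (A itself) and one inhibitor.
    ``production_B`` must have exactly one activator (A) and none
    inhibitory.

    At least one removal mechanism per cytokine must be strictly
    positive so trajectories stay bounded.
    """

    production_A: ProductionParams
    production_B: ProductionParams
    receptor_A: ReceptorParams
    receptor_B: ReceptorParams
    linear_clearance_A: float
    linear_clearance_B: float
    protease_A: Optional[SaturatingClearance] = None
    protease_B: Optional[SaturatingClearance] = None
    self_activation_A: bool = False
    raw: Optional[RawTissueParameters] = None

    def __post_init__(self):
        if self.linear_clearance_A < 0 or self.linear_clearance_B < 0:
            raise ValueError("linear clearances must be >= 0")
        n_act_A = 1 if self.self_activation_A else 0
        if self.production_A.activator_count != n_act_A:
            raise ValueError(
                f"production_A must have {n_act_A} activator(s) "
                f"(self_activation_A={self.self_activation_A})"
            )
        if self.production_A.inhibitor_count != 1:
            raise ValueError("production_A must have exactly 1 inhibitor (B)")
        if self.production_B.activator_count != 1:
            raise ValueError("production_B must have exactly 1 activator (A)")
        if self.production_B.inhibitor_count != 0:
            raise ValueError("production_B must have no inhibitors")
        for cyt in ("A", "B"):
            lam = getattr(self, f"linear_clearance_{cyt}")
            rec: ReceptorParams = getattr(self, f"receptor_{cyt}")
            prot = getattr(self, f"protease_{cyt}")
            uptake_capacity = rec.uptake_normalization * rec.total_receptors
            prot_cap = prot.vmax if prot is not None else 0.0
            if lam <= 0 and uptake_capacity <= 0 and prot_cap <= 0:
                raise ValueError(
                    f"cytokine {cyt} has no removal mechanism; trajectories "
                    "would be unbounded"
                )

    def replace(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given top-level fields replaced."""
        return dataclasses.replace(self, **kwargs)


def normalize_parameters(
    raw: RawTissueParameters,
    prod: ProductionParams,
    rec: ReceptorParams,
    *,
    raw_B: Optional[RawTissueParameters] = None,
    prod_B: Optional[ProductionParams] = None,
    rec_B: Optional[ReceptorParams] = None,
) -> ModelParameters:
    """Fold a dimensional tissue balance into normalized model parameters.

    The tissue-level balance for one cytokine reads::

        dc/dt = (S_p N_p / V) * [q(c_in) + q_basal]        (production)
              - (S_u N_u / V) * u(c)                       (uptake)
              - (S_cap P_cap / V) * (c - c_blood)          (capillary)
              - Vmax E c / (Km + c)                        (protease)

    Geometric factors are folded into the production and uptake
    normalization coefficients.  The capillary term and the protease term
    linearized for ``c << Km`` are folded into a single linear clearance;
    the back-flux from blood, ``(S_cap P_cap / V) c_blood``, joins the
    basal production rate.  The raw parameters are retained on the
    returned object as provenance.

    By default the B channel reuses the A-channel inputs (a symmetric
    tissue); pass ``raw_B``/``prod_B``/``rec_B`` to break the symmetry.
    """
    if raw_B is None:
        raw_B = raw
    if prod_B is None:
        # mirror the A-channel law into the structurally correct B role:
        # B production is activated by A with the same affinity scale
        prod_B = dataclasses.replace(
            prod,
            activator_dissociation=prod.inhibitor_dissociation,
            inhibitor_dissociation=(),
        )
    if rec_B is None:
        rec_B = rec

    def channel(rw: RawTissueParameters, pr: ProductionParams, rc: ReceptorParams):
        g_prod = rw.producing_cell_surface_area * rw.producing_cell_count / rw.tissue_volume
        g_upt = rw.uptake_cell_surface_area * rw.uptake_cell_count / rw.tissue_volume
        cap = rw.capillary_surface_area * rw.capillary_permeability / rw.tissue_volume
        prot_lin = (
            rw.protease_vmax * rw.protease_concentration / rw.protease_km
            if rw.protease_km > 0
            else 0.0
        )
        prod_n = dataclasses.replace(
            pr,
            max_rate=g_prod * pr.max_rate,
            basal_rate=g_prod * (pr.basal_rate + rw.basal_secretion_rate)
            + cap * rw.blood_cytokine_concentration,
        )
        rec_n = dataclasses.replace(
            rc, uptake_normalization=g_upt * rc.uptake_normalization
        )
        clearance = cap + prot_lin
        return prod_n, rec_n, clearance

    prod_A_n, rec_A_n, lam_A = channel(raw, prod, rec)
    prod_B_n, rec_B_n, lam_B = channel(raw_B, prod_B, rec_B)
    return ModelParameters(
        production_A=prod_A_n,
        production_B=prod_B_n,
        receptor_A=rec_A_n,
        receptor_B=rec_B_n,
        linear_clearance_A=lam_A,
        linear_clearance_B=lam_B,
        raw=raw,
    )
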