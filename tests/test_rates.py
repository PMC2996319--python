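"""Rate-law unit and property tests: production, receptor uptake, rhs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytodyn import (
    CytokineState,
    ModelParameters,
    ProductionParams,
    RawTissueParameters,
    ReceptorParams,
    dissipative_box,
    find_equilibria,
    normalize_parameters,
    production_rate,
    rhs,
    rhs_xy,
    surface_receptor_fraction,
    uptake_rate,
)

from conftest import make_model

pos = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)
conc = st.floats(min_value=0.0, max_value=1e3, allow_nan=False)


def _endocytic():
    return ReceptorParams(
        total_receptors=1.0,
        ligand_dissociation=1.0,
        internalization_rate_bound=20.0,
        internalization_rate_free=0.01,
        recovery_rate=1.0,
        uptake_normalization=1.0,
    )


class TestProductionRate:
    def test_zero_inhibitor_gives_max(self):
        p = ProductionParams(max_rate=3.0, inhibitor_dissociation=(2.0,))
        assert production_rate([], [0.0], p) == pytest.approx(3.0)

    def test_half_saturation_identity(self):
        p = ProductionParams(max_rate=2.0, activator_dissociation=(0.7,))
        assert production_rate([0.7], [], p) == pytest.approx(1.0)

    def test_product_of_half_factors(self):
        # activator at its K and inhibitor at its K each contribute 1/2
        p = ProductionParams(
            max_rate=8.0,
            activator_dissociation=(1.5,),
            inhibitor_dissociation=(0.3,),
        )
        expected = 8.0 * (1.5 / (1.5 + 1.5)) * (0.3 / (0.3 + 0.3))
        assert production_rate([1.5], [0.3], p) == pytest.approx(expected)
        assert expected == pytest.approx(0.25 * 8.0)

    def test_mismatched_lengths_rejected(self):
        p = ProductionParams(max_rate=1.0, activator_dissociation=(1.0,))
        with pytest.raises(ValueError, match="activator"):
            production_rate([], [], p)

    def test_negative_concentration_rejected(self):
        p = ProductionParams(max_rate=1.0, inhibitor_dissociation=(1.0,))
        with pytest.raises(ValueError):
            production_rate([], [-0.1], p)

    @given(a=conc, i=conc, Ka=pos, Ki=pos, q=pos, basal=conc)
    @settings(max_examples=200, deadline=None)
    def test_bounded_between_basal_and_basal_plus_max(self, a, i, Ka, Ki, q, basal):
        p = ProductionParams(
            max_rate=q,
            activator_dissociation=(Ka,),
            inhibitor_dissociation=(Ki,),
            basal_rate=basal,
        )
        v = production_rate([a], [i], p)
        assert basal - 1e-12 <= v <= basal + q + 1e-12

    @given(i1=conc, i2=conc, a=conc)
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_each_input(self, i1, i2, a):
        p = ProductionParams(
            max_rate=1.0,
            activator_dissociation=(1.0,),
            inhibitor_dissociation=(1.0,),
        )
        lo, hi = sorted((i1, i2))
        assert production_rate([a], [hi], p) <= production_rate([a], [lo], p) + 1e-12
        assert production_rate([lo], [i1], p) <= production_rate([hi], [i1], p) + 1e-12


class TestSurfaceReceptorFraction:
    def test_nothing_internalizes_at_zero_conc(self):
        r = ReceptorParams(
            total_receptors=1.0,
            ligand_dissociation=1.0,
            internalization_rate_bound=5.0,
            internalization_rate_free=0.0,
            recovery_rate=2.0,
            uptake_normalization=1.0,
        )
        assert surface_receptor_fraction(0.0, r) == pytest.approx(1.0)

    def test_saturation_limit(self, endocytic_receptor):
        r = endocytic_receptor
        limit = r.recovery_rate / (r.recovery_rate + r.internalization_rate_bound)
        assert surface_receptor_fraction(1e9, r) == pytest.approx(limit, rel=1e-6)

    def test_degenerate_receptor_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ReceptorParams(
                total_receptors=1.0,
                ligand_dissociation=1.0,
                internalization_rate_bound=0.0,
                internalization_rate_free=0.0,
                recovery_rate=0.0,
                uptake_normalization=1.0,
            )

    @pytest.mark.parametrize("c", np.geomspace(1e-3, 1e3, 7).tolist())
    def test_agrees_with_ode_relaxation(self, endocytic_receptor, c):
        # independent oracle: integrate the surface-pool ODE to steady state
        from scipy.integrate import solve_ivp

        r = endocytic_receptor
        b = c / (r.ligand_dissociation + c)
        ki = r.internalization_rate_free * (1 - b) + r.internalization_rate_bound * b

        sol = solve_ivp(
            lambda t, s: [r.recovery_rate * (1 - s[0]) - ki * s[0]],
            (0, 200.0),
            [0.5],
            rtol=1e-12,
            atol=1e-14,
        )
        assert surface_receptor_fraction(c, r) == pytest.approx(
            sol.y[0, -1], abs=1e-8
        )

    @given(c=conc)
    @settings(max_examples=100, deadline=None)
    def test_fraction_in_unit_interval(self, c):
        assert 0.0 <= surface_receptor_fraction(c, _endocytic()) <= 1.0


class TestUptakeRate:
    def test_zero_at_zero(self, endocytic_receptor):
        assert uptake_rate(0.0, endocytic_receptor) == 0.0

    def test_closed_form_at_kd_with_equal_internalization(self, simple_receptor):
        # equal bound/free internalization: surface fraction independent of conc
        r = simple_receptor
        s = r.recovery_rate / (r.recovery_rate + r.internalization_rate_bound)
        expected = r.uptake_normalization * r.total_receptors * 0.5 * s * s
        assert uptake_rate(r.ligand_dissociation, r) == pytest.approx(expected)

    def test_non_monotone_when_bound_internalization_dominates(
        self, endocytic_receptor
    ):
        c = np.geomspace(1e-4, 1e4, 400)
        u = uptake_rate(c, endocytic_receptor)
        peak = int(np.argmax(u))
        assert 0 < peak < len(c) - 1  # interior maximum: rises then declines
        assert u[-1] < 0.5 * u[peak]

    def test_monotone_when_recovery_dominates(self, simple_receptor):
        c = np.geomspace(1e-4, 1e4, 400)
        u = uptake_rate(c, simple_receptor)
        assert np.all(np.diff(u) >= -1e-15)

    @given(c=conc)
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_normalization_times_pool(self, c):
        r = _endocytic()
        assert 0 <= uptake_rate(c, r) <= r.uptake_normalization * r.total_receptors


class TestRhs:
    def test_equilibrium_has_zero_derivative(self, plain_model):
        eqs = find_equilibria(plain_model)
        assert eqs
        for e in eqs:
            dA, dB = rhs(e.state, plain_model)
            assert abs(dA) < 1e-9 and abs(dB) < 1e-9

    def test_origin_with_zero_basal(self):
        p = make_model(basal_frac=0.0)
        dA, dB = rhs(CytokineState(0.0, 0.0), p)
        # B has no input activator: production 0.  A faces no inhibitor.
        assert dB == pytest.approx(0.0)
        assert dA == pytest.approx(p.production_A.max_rate)

    def test_pure_decay_has_negative_derivatives(self, decay_model):
        dA, dB = rhs(CytokineState(0.5, 2.0), decay_model)
        assert dA < 0 and dB < 0

    def test_nonnegative_quadrant_forward_invariant(self, plain_model):
        dA, _ = rhs(CytokineState(0.0, 3.0), plain_model)
        _, dB = rhs(CytokineState(3.0, 0.0), plain_model)
        assert dA >= 0 and dB >= 0

    def test_dissipative_above_bounding_box(self, plain_model):
        a_max, b_max = dissipative_box(plain_model)
        dA, dB = rhs(CytokineState(a_max * 1.01, b_max * 1.01), plain_model)
        assert dA < 0 and dB < 0

    def test_nonfinite_state_rejected(self, plain_model):
        with pytest.raises(ValueError):
            rhs_xy(np.inf, 1.0, plain_model)


class TestNormalizeParameters:
    def _raw(self, **over):
        base = dict(
            producing_cell_surface_area=2.0,
            producing_cell_count=50.0,
            tissue_volume=10.0,
            uptake_cell_surface_area=1.5,
            uptake_cell_count=40.0,
            capillary_surface_area=4.0,
            capillary_permeability=0.25,
            blood_cytokine_concentration=0.1,
            protease_vmax=0.3,
            protease_concentration=2.0,
            protease_km=5.0,
            basal_secretion_rate=1e-4,
        )
        base.update(over)
        return RawTissueParameters(**base)

    def _prod(self):
        return ProductionParams(max_rate=0.2, inhibitor_dissociation=(1.0,))

    def _rec(self):
        return ReceptorParams(
            total_receptors=1.0,
            ligand_dissociation=1.0,
            internalization_rate_bound=2.0,
            internalization_rate_free=0.1,
            recovery_rate=1.0,
            uptake_normalization=0.05,
        )

    def test_production_linear_in_cell_count(self):
        p1 = normalize_parameters(self._raw(), self._prod(), self._rec())
        p2 = normalize_parameters(
            self._raw(producing_cell_count=100.0), self._prod(), self._rec()
        )
        assert p2.production_A.max_rate == pytest.approx(
            2 * p1.production_A.max_rate
        )

    def test_no_capillary_no_protease_means_zero_clearance(self):
        raw = self._raw(capillary_permeability=0.0, protease_vmax=0.0)
        p = normalize_parameters(raw, self._prod(), self._rec())
        assert p.linear_clearance_A == 0.0

    def test_provenance_retained(self):
        raw = self._raw()
        p = normalize_parameters(raw, self._prod(), self._rec())
        assert p.raw is raw

    def test_matches_tissue_balance_term_by_term(self):
        # independent assembly of the tissue balance on a state grid
        raw, prod, rec = self._raw(), self._prod(), self._rec()
        p = normalize_parameters(raw, prod, rec)
        g_prod = (
            raw.producing_cell_surface_area
            * raw.producing_cell_count
            / raw.tissue_volume
        )
        g_upt = (
            raw.uptake_cell_surface_area * raw.uptake_cell_count / raw.tissue_volume
        )
        cap = raw.capillary_surface_area * raw.capillary_permeability / raw.tissue_volume
        prot = raw.protease_vmax * raw.protease_concentration / raw.protease_km
        for a in (0.0, 0.3, 2.0):
            for b in (0.0, 0.7, 4.0):
                direct = (
                    g_prod * (production_rate([], [b], prod) + raw.basal_secretion_rate)
                    - g_upt * uptake_rate(a, rec)
                    - cap * (a - raw.blood_cytokine_concentration)
                    - prot * a
                )
                dA, _ = rhs_xy(a, b, p)
                assert dA == pytest.approx(direct, abs=1e-10)
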