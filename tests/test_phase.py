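"""Nullclines, equilibria, stability, limit cycles and basin maps."""

import numpy as np
import pytest

import cytodyn as cd
from cytodyn import (
    CytokineState,
    ModelParameters,
    ProductionParams,
    ReceptorParams,
    basin_map,
    classify_stability,
    compute_nullclines,
    detect_limit_cycle,
    find_equilibria,
    load_exemplar,
    rhs_xy,
    simulate,
    vector_field,
)
from cytodyn.phase import default_window


@pytest.fixture(scope="module")
def exemplars():
    return {name: load_exemplar(name) for name in cd.list_exemplars()}


@pytest.fixture(scope="module")
def exemplar_equilibria(exemplars):
    return {name: find_equilibria(p) for name, p in exemplars.items()}


def decoupled(basal_A=0.2, basal_B=0.3, lam_A=0.5, lam_B=0.25):
    no_rec = ReceptorParams(
        total_receptors=0.0,
        ligand_dissociation=1.0,
        internalization_rate_bound=0.0,
        internalization_rate_free=0.0,
        recovery_rate=1.0,
        uptake_normalization=0.0,
    )
    return ModelParameters(
        production_A=ProductionParams(
            max_rate=0.0, inhibitor_dissociation=(1.0,), basal_rate=basal_A
        ),
        production_B=ProductionParams(
            max_rate=0.0, activator_dissociation=(1.0,), basal_rate=basal_B
        ),
        receptor_A=no_rec,
        receptor_B=no_rec,
        linear_clearance_A=lam_A,
        linear_clearance_B=lam_B,
    )


class TestNullclines:
    def test_pure_decay_nullclines_are_axes(self, decay_model):
        null_A, null_B = compute_nullclines(
            decay_model, window=(0.0, 2.0, 0.0, 2.0), resolution=60
        )
        # dA/dt = 0 only at A=0 (the B axis); dB/dt = 0 only at B=0
        assert null_A.points.size > 0 and null_B.points.size > 0
        assert np.allclose(null_A.points[:, 0], 0.0, atol=1e-8)
        assert np.allclose(null_B.points[:, 1], 0.0, atol=1e-8)

    def test_points_satisfy_defining_equation(self, exemplars):
        p = exemplars["trigger"]
        null_A, null_B = compute_nullclines(p, resolution=80)
        for nc, comp in ((null_A, 0), (null_B, 1)):
            pts = nc.points
            dA, dB = rhs_xy(pts[:, 0], pts[:, 1], p)
            resid = np.abs(dA if comp == 0 else dB)
            assert np.max(resid) < 1e-8

    def test_activation_nullcline_monotone_in_a(self):
        # linear-clearance B channel: B-nullcline is production_B(A)/lam
        p = decoupled()
        p = p.replace(
            production_B=ProductionParams(
                max_rate=1.0, activator_dissociation=(0.5,), basal_rate=0.01
            )
        )
        _, null_B = compute_nullclines(p, window=(0, 3, 0, 6), resolution=80)
        assert len(null_B.branches) == 1
        br = null_B.branches[0]
        order = np.argsort(br[:, 0])
        assert np.all(np.diff(br[order, 1]) >= -1e-10)

    def test_trigger_nullclines_cross_three_times(self, exemplars):
        # count crossings as sign changes of dA/dt along the B-nullcline
        p = exemplars["trigger"]
        _, null_B = compute_nullclines(p, resolution=400)
        crossings = 0
        for br in null_B.branches:
            dA, _ = rhs_xy(br[:, 0], br[:, 1], p)
            dA = np.asarray(dA)
            crossings += int(np.sum(np.diff(np.sign(dA)) != 0))
        assert crossings == 3

    def test_every_intersection_is_an_equilibrium(self, exemplars,
                                                  exemplar_equilibria):
        p = exemplars["trigger"]
        eqs = exemplar_equilibria["trigger"]
        _, null_B = compute_nullclines(p, resolution=400)
        hits = []
        for br in null_B.branches:
            dA, _ = rhs_xy(br[:, 0], br[:, 1], p)
            dA = np.asarray(dA)
            for i in np.where(np.diff(np.sign(dA)) != 0)[0]:
                hits.append(0.5 * (br[i] + br[i + 1]))
        assert len(hits) == len(eqs)
        for h in hits:
            d = min(
                np.hypot(*(h - e.state.as_array())) for e in eqs
            )
            assert d < 0.05


class TestFindEquilibria:
    @pytest.mark.parametrize(
        "name,n_eq,n_stable",
        [
            ("healthy", 1, 1),
            ("healthy_excitable", 1, 1),
            ("trigger", 3, 2),
            ("oscillatory_pure", 1, 0),
            ("oscillatory_coexisting", 3, 1),
        ],
    )
    def test_exemplar_counts(self, exemplar_equilibria, name, n_eq, n_stable):
        eqs = exemplar_equilibria[name]
        assert len(eqs) == n_eq
        assert sum(e.is_stable for e in eqs) == n_stable

    def test_residual_below_tolerance(self, exemplar_equilibria):
        for name, eqs in exemplar_equilibria.items():
            p = load_exemplar(name)
            for e in eqs:
                dA, dB = cd.rhs(e.state, p)
                assert max(abs(dA), abs(dB)) < 1e-9

    def test_sorted_by_conc_a(self, exemplar_equilibria):
        for eqs in exemplar_equilibria.values():
            a = [e.state.conc_A for e in eqs]
            assert a == sorted(a)

    def test_matches_grid_scan_oracle(self, exemplars, exemplar_equilibria):
        from conftest import grid_sign_scan_oracle

        p = exemplars["trigger"]
        eqs = exemplar_equilibria["trigger"]
        points, sizes = grid_sign_scan_oracle(p, n=300)
        assert len(points) == len(eqs)
        for e in eqs:
            x = e.state.as_array()
            d = np.abs(points - x) / (sizes + 1e-30)
            assert np.min(np.max(d, axis=1)) < 4  # within a few local cells


class TestClassifyStability:
    def test_decoupled_linear_closed_form(self):
        p = decoupled(lam_A=0.5, lam_B=0.25)
        eq = classify_stability(CytokineState(0.4, 1.2), p)
        assert eq.stability == "stable-node"
        assert sorted(eq.eigenvalues.real) == pytest.approx([-0.5, -0.25])
        assert np.allclose(eq.eigenvalues.imag, 0.0, atol=1e-9)

    def test_trigger_has_saddle_between_stable_states(self, exemplar_equilibria):
        eqs = exemplar_equilibria["trigger"]
        assert [e.stability.startswith("stable") for e in eqs] == [True, False, True]
        assert eqs[1].stability == "saddle"

    def test_oscillatory_equilibrium_is_unstable_spiral(self, exemplar_equilibria):
        (eq,) = exemplar_equilibria["oscillatory_pure"]
        assert not eq.is_stable
        assert np.max(eq.eigenvalues.real) > 0

    @pytest.mark.parametrize("name", ["healthy", "trigger", "oscillatory_pure"])
    def test_labels_agree_with_perturbation_integration(
        self, exemplars, exemplar_equilibria, name
    ):
        p = exemplars[name]
        for e in exemplar_equilibria[name]:
            x0 = e.state.as_array()
            scale = 1e-3 * (1.0 + np.abs(x0))
            rate = max(abs(e.leading_real_part), 0.05)
            horizon = min(60.0 / rate, 2000.0)
            if e.is_stable:
                for d in ([1, 1], [-1, 1], [1, -1], [-1, -1]):
                    start = np.clip(x0 + scale * np.asarray(d), 0, None)
                    traj = simulate(p, CytokineState(*start), horizon,
                                    rtol=1e-8, atol=1e-10)
                    assert np.hypot(*(traj.states[-1] - x0)) < 1e-4
            else:
                # leave along the unstable direction
                idx = int(np.argmax(e.eigenvalues.real))
                vec = np.linalg.eig(e.jacobian).eigenvectors[:, idx].real
                vec = vec / np.linalg.norm(vec)
                start = np.clip(x0 + scale * vec, 0, None)
                traj = simulate(p, CytokineState(*start), horizon,
                                rtol=1e-8, atol=1e-10)
                dist = np.hypot(traj.states[:, 0] - x0[0], traj.states[:, 1] - x0[1])
                assert dist.max() > 10 * np.linalg.norm(scale)


@pytest.fixture(scope="module")
def osc_cycle(exemplars, exemplar_equilibria):
    p = exemplars["oscillatory_pure"]
    (eq,) = exemplar_equilibria["oscillatory_pure"]
    cycle = detect_limit_cycle(p, eq)
    assert cycle is not None
    return p, eq, cycle


class TestDetectLimitCycle:
    def test_requires_unstable_seed(self, exemplar_equilibria):
        eqs = exemplar_equilibria["healthy"]
        p = load_exemplar("healthy")
        with pytest.raises(ValueError):
            detect_limit_cycle(p, eqs[0])

    def test_cycle_properties(self, osc_cycle):
        p, eq, cycle = osc_cycle
        assert cycle.period > 0
        assert cycle.amplitude_A > 0 and cycle.amplitude_B > 0
        # orbit closes on itself
        gap = np.hypot(*(cycle.orbit[0] - cycle.orbit[-1]))
        assert gap < 0.05 * max(cycle.amplitude_A, cycle.amplitude_B)

    def test_cycle_encloses_unstable_equilibrium(self, osc_cycle):
        _, eq, cycle = osc_cycle
        assert cycle.encloses(eq.state)

    def test_period_stable_under_longer_horizon(self, osc_cycle):
        p, eq, cycle = osc_cycle
        cycle2 = detect_limit_cycle(p, eq, horizon=1200.0)
        assert cycle2 is not None
        assert abs(cycle2.period - cycle.period) < 1e-3 * cycle.period


class TestVectorField:
    def test_is_pointwise_rhs(self, exemplars):
        p = exemplars["healthy"]
        A, B, dA, dB = vector_field(p, resolution=7)
        fa, fb = rhs_xy(A[3, 4], B[3, 4], p)
        assert dA[3, 4] == pytest.approx(fa)
        assert dB[3, 4] == pytest.approx(fb)

    def test_negative_at_large_concentrations(self, exemplars):
        p = exemplars["healthy"]
        A, B, dA, dB = vector_field(p, resolution=5)
        assert dA[-1, -1] < 0 and dB[-1, -1] < 0

    def test_zero_component_on_nullcline(self, exemplars):
        p = exemplars["healthy"]
        null_A, _ = compute_nullclines(p, resolution=50)
        a, b = null_A.points[len(null_A.points) // 2]
        dA, _ = rhs_xy(a, b, p)
        assert abs(dA) < 1e-8


class TestBasinMap:
    def test_monostable_single_label(self, exemplars):
        p = exemplars["healthy"]
        bm = basin_map(p, resolution=8, horizon=600.0)
        labels = bm.labels[bm.labels >= 0]
        assert labels.size > 0
        assert np.all(labels == labels[0])

    def test_trigger_two_basins(self, exemplars, exemplar_equilibria):
        p = exemplars["trigger"]
        stables = [e for e in exemplar_equilibria["trigger"] if e.is_stable]
        bm = basin_map(p, resolution=10, horizon=600.0, attractors=stables)
        present = set(bm.labels[bm.labels >= 0].ravel())
        assert present == {0, 1}

    def test_labels_match_direct_settlement(self, exemplars, exemplar_equilibria):
        p = exemplars["trigger"]
        stables = [e for e in exemplar_equilibria["trigger"] if e.is_stable]
        bm = basin_map(p, resolution=8, horizon=600.0, attractors=stables)
        rng = np.random.default_rng(0)
        resolved = np.argwhere(bm.labels >= 0)
        for i, j in resolved[rng.choice(len(resolved), size=3, replace=False)]:
            a0, b0 = bm.A_values[j], bm.B_values[i]
            traj = simulate(p, CytokineState(a0, b0), 600.0, rtol=1e-7, atol=1e-9)
            d = [np.hypot(*(traj.states[-1] - e.state.as_array())) for e in stables]
            assert int(np.argmin(d)) == bm.labels[i, j]
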