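import numpy as np
import pytest

from cytodyn.phase import default_window
from cytodyn.rates import rhs_xy


def grid_sign_scan_oracle(p, n=400):
    """Brute-force equilibrium locator: sign-change scan on a log grid.

    Independent of the root-finder: marks every grid cell in which both
    time derivatives change sign, clusters adjacent cells in index
    space, and returns one representative cell corner per cluster plus
    the local cell sizes.  Returns (points, cell_sizes) arrays.
    """
    a_lo, a_hi, b_lo, b_hi = default_window(p)
    av = np.geomspace(a_hi * 1e-5, a_hi, n)
    bv = np.geomspace(b_hi * 1e-5, b_hi, n)
    A, B = np.meshgrid(av, bv)
    f, g = rhs_xy(A, B, p)
    sf, sg = np.sign(f), np.sign(g)
    cf = (np.abs(np.diff(sf, axis=0))[:, :-1] + np.abs(np.diff(sf, axis=1))[:-1, :]) > 0
    cg = (np.abs(np.diff(sg, axis=0))[:, :-1] + np.abs(np.diff(sg, axis=1))[:-1, :]) > 0
    idx = np.argwhere(cf & cg)
    clusters: list[list[np.ndarray]] = []
    for ij in idx:
        placed = None
        for cl in clusters:
            if any(np.max(np.abs(ij - member)) <= 2 for member in cl):
                if placed is None:
                    cl.append(ij)
                    placed = cl
                else:  # merge chains that this cell bridges
                    placed.extend(cl)
                    cl.clear()
        if placed is None:
            clusters.append([ij])
    clusters = [cl for cl in clusters if cl]
    points, sizes = [], []
    for cl in clusters:
        arr = np.array(cl)
        i, j = arr.mean(axis=0).round().astype(int)
        i, j = min(i, n - 2), min(j, n - 2)
        points.append([A[i, j], B[i, j]])
        sizes.append([av[j + 1] - av[j], bv[i + 1] - bv[i]])
    return np.array(points), np.array(sizes)

from cytodyn import (
    CytokineState,
    ModelParameters,
    ProductionParams,
    ReceptorParams,
)


@pytest.fixture
def simple_receptor():
    """Receptor pool with equal bound/free internalization (monotone uptake)."""
    return ReceptorParams(
        total_receptors=1.0,
        ligand_dissociation=1.0,
        internalization_rate_bound=0.5,
        internalization_rate_free=0.5,
        recovery_rate=1.0,
        uptake_normalization=1.0,
    )


@pytest.fixture
def endocytic_receptor():
    """Fast bound-receptor internalization: non-monotone uptake."""
    return ReceptorParams(
        total_receptors=1.0,
        ligand_dissociation=1.0,
        internalization_rate_bound=20.0,
        internalization_rate_free=0.01,
        recovery_rate=1.0,
        uptake_normalization=1.0,
    )


def make_model(
    qmax_A=1.0,
    qmax_B=1.0,
    K_inh=1.0,
    K_act=1.0,
    clearance=0.5,
    receptor=None,
    basal_frac=1e-4,
):
    """Small helper: symmetric-ish model with optional shared receptor."""
    rec = receptor or ReceptorParams(
        total_receptors=1.0,
        ligand_dissociation=1.0,
        internalization_rate_bound=0.5,
        internalization_rate_free=0.5,
        recovery_rate=1.0,
        uptake_normalization=0.2,
    )
    return ModelParameters(
        production_A=ProductionParams(
            max_rate=qmax_A,
            inhibitor_dissociation=(K_inh,),
            basal_rate=basal_frac * qmax_A,
        ),
        production_B=ProductionParams(
            max_rate=qmax_B,
            activator_dissociation=(K_act,),
            basal_rate=basal_frac * qmax_B,
        ),
        receptor_A=rec,
        receptor_B=rec,
        linear_clearance_A=clearance,
        linear_clearance_B=clearance,
    )


@pytest.fixture
def plain_model():
    return make_model()


@pytest.fixture
def decay_model():
    """No production at all: pure decay toward the origin."""
    rec = ReceptorParams(
        total_receptors=1.0,
        ligand_dissociation=1.0,
        internalization_rate_bound=0.5,
        internalization_rate_free=0.5,
        recovery_rate=1.0,
        uptake_normalization=0.2,
    )
    return ModelParameters(
        production_A=ProductionParams(
            max_rate=0.0, inhibitor_dissociation=(1.0,), basal_rate=0.0
        ),
        production_B=ProductionParams(
            max_rate=0.0, activator_dissociation=(1.0,), basal_rate=0.0
        ),
        receptor_A=rec,
        receptor_B=rec,
        linear_clearance_A=0.5,
        linear_clearance_B=0.5,
    )
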