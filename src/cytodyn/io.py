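"""Serialization, schema-validated configs and synthetic fixture tables.

Parameter sets round-trip through YAML (keys mirror the dataclass field
names verbatim; unknown keys are rejected).  Dose-response tables are
two-column CSV with header ``input_conc,output_conc``.  Trajectories
write as CSV with a sidecar JSON echoing the protocol, parameters and
seed for full reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .calibration import composite_response
from .dynamics import Trajectory
from .params import (
    ModelParameters,
    ProductionParams,
    RawTissueParameters,
    ReceptorParams,
    SaturatingClearance,
)
from .phase import BasinMap, Equilibrium, LimitCycle, Nullcline

__all__ = [
    "parameters_to_dict",
    "parameters_from_dict",
    "save_parameters",
    "load_parameters",
    "read_dose_response",
    "write_dose_response",
    "generate_dose_response_fixture",
    "write_trajectory",
    "equilibrium_to_dict",
    "cycle_to_dict",
    "regime_report_to_dict",
    "write_manifest",
]


def _clean(obj):
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_clean(v) for v in obj.tolist()]
    return obj


def parameters_to_dict(p: ModelParameters) -> dict:
    d = dataclasses.asdict(p)
    if d.get("raw") is None:
        d.pop("raw", None)
    for k in ("protease_A", "protease_B"):
        if d.get(k) is None:
            d.pop(k, None)
    return _clean(d)


def _from_dict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(
            f"unknown key(s) for {cls.__name__}: {sorted(unknown)}; "
            f"allowed: {sorted(names)}"
        )
    return cls(**d)


def parameters_from_dict(d: dict) -> ModelParameters:
    """Build ModelParameters from a plain dict, rejecting unknown keys."""
    d = dict(d)
    nested = {
        "production_A": ProductionParams,
        "production_B": ProductionParams,
        "receptor_A": ReceptorParams,
        "receptor_B": ReceptorParams,
        "protease_A": SaturatingClearance,
        "protease_B": SaturatingClearance,
        "raw": RawTissueParameters,
    }
    for key, cls in nested.items():
        if key in d and isinstance(d[key], dict):
            d[key] = _from_dict(cls, d[key])
    return _from_dict(ModelParameters, d)


def save_parameters(p: ModelParameters, path: Union[str, Path]) -> None:
    path = Path(path)
    doc = parameters_to_dict(p)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def load_parameters(path: Union[str, Path]) -> ModelParameters:
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return parameters_from_dict(doc)


# ---------------------------------------------------------------------------
# dose-response tables
# ---------------------------------------------------------------------------

def write_dose_response(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table[["input_conc", "output_conc"]].to_csv(path, index=False)


def read_dose_response(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"input_conc", "output_conc"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


#: ground-truth parameters behind the two fixture shapes (normalized units)
FIXTURE_TRUTH = {
    "monotone-saturating": {
        "production": ProductionParams(
            max_rate=200.0, activator_dissociation=(1.0,), basal_rate=10.0
        ),
        "receptor": None,
    },
    # tuned so the curve shows the plateau-dip-rise shape of measured
    # IL-17-vs-IL-23 style dose responses, reading ~120 at dose 0.25 and
    # ~180 at dose 10 (output units pg/ml-like, input ng/ml-like)
    "non-monotone": {
        "production": ProductionParams(
            max_rate=252.44,
            activator_dissociation=(0.002,),
            inhibitor_dissociation=(0.008518,),
            basal_rate=10.0,
        ),
        "receptor": ReceptorParams(
            total_receptors=1.0,
            ligand_dissociation=10.0,
            internalization_rate_bound=20.0,
            internalization_rate_free=0.01,
            recovery_rate=1.0,
            uptake_normalization=1.0,
        ),
    },
}


def generate_dose_response_fixture(
    shape: str,
    n_points: int = 12,
    noise_cv: float = 0.0,
    seed: int = 0,
    *,
    dose_range: tuple[float, float] = (0.01, 30.0),
    path: Optional[Union[str, Path]] = None,
):
    """Synthetic dose-response table from known ground-truth parameters.

    Samples the composite steady-state output curve at log-spaced doses
    with multiplicative lognormal noise of coefficient of variation
    ``noise_cv``; deterministic per seed.  With ``path``, writes the CSV
    table and a ``<path>.truth.json`` sidecar holding the ground truth.

    Returns ``(table, production, receptor)``.
    """
    if shape not in FIXTURE_TRUTH:
        raise ValueError(f"shape must be one of {sorted(FIXTURE_TRUTH)}")
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    truth = FIXTURE_TRUTH[shape]
    prod, rec = truth["production"], truth["receptor"]
    doses = np.geomspace(dose_range[0], dose_range[1], n_points)
    out = np.asarray(composite_response(doses, prod, rec), dtype=float)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        out = out * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=out.shape)
    table = pd.DataFrame({"input_conc": doses, "output_conc": out})
    if path is not None:
        path = Path(path)
        write_dose_response(table, path)
        sidecar = {
            "shape": shape,
            "seed": seed,
            "noise_cv": noise_cv,
            "production": _clean(dataclasses.asdict(prod)),
            "receptor": _clean(dataclasses.asdict(rec)) if rec else None,
        }
        path.with_suffix(path.suffix + ".truth.json").write_text(
            json.dumps(sidecar, indent=2)
        )
    return table, prod, rec


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    """CSV (time,conc_A,conc_B) plus a sidecar JSON with the full context."""
    path = Path(path)
    traj.to_dataframe().to_csv(path, index=False)
    sidecar = {
        "parameters": parameters_to_dict(traj.parameters),
        "protocol": dataclasses.asdict(traj.protocol) if traj.protocol else None,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(_clean(sidecar), indent=2)
    )


def equilibrium_to_dict(eq: Equilibrium) -> dict:
    return {
        "conc_A": float(eq.state.conc_A),
        "conc_B": float(eq.state.conc_B),
        "eigenvalues": [[float(z.real), float(z.imag)] for z in eq.eigenvalues],
        "stability": eq.stability,
    }


def cycle_to_dict(cycle: LimitCycle) -> dict:
    return {
        "period": float(cycle.period),
        "amplitude_A": float(cycle.amplitude_A),
        "amplitude_B": float(cycle.amplitude_B),
        "n_orbit_samples": int(len(cycle.orbit)),
    }


def regime_report_to_dict(report) -> dict:
    return {
        "regime": report.regime,
        "n_equilibria": len(report.equilibria),
        "n_stable": report.n_stable,
        "equilibria": [equilibrium_to_dict(e) for e in report.equilibria],
        "cycles": [cycle_to_dict(c) for c in report.cycles],
    }


def write_nullclines(null_A: Nullcline, null_B: Nullcline,
                     path: Union[str, Path]) -> None:
    rows = []
    for nc in (null_A, null_B):
        for bi, br in enumerate(nc.branches):
            for a, b in br:
                rows.append((nc.which, bi, a, b))
    pd.DataFrame(rows, columns=["nullcline", "branch", "conc_A", "conc_B"]).to_csv(
        path, index=False
    )


def write_basin_map(bm: BasinMap, path: Union[str, Path]) -> None:
    A, B = np.meshgrid(bm.A_values, bm.B_values)
    pd.DataFrame(
        {"conc_A": A.ravel(), "conc_B": B.ravel(), "label": bm.labels.ravel()}
    ).to_csv(path, index=False)


def write_manifest(path: Union[str, Path], *, inputs: dict, seed=None) -> None:
    """Write a reproducibility manifest next to an output artifact."""
    import cytodyn

    blob = json.dumps(_clean(inputs), sort_keys=True).encode()
    manifest = {
        "inputs": _clean(inputs),
        "inputs_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {
            "cytodyn": cytodyn.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
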