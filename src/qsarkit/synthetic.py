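"""Synthetic datasets with the statistical structure each modelling stage
assumes, plus the packaged 50-compound activity fixture.

Three generators: a descriptor matrix with a planted sparse linear signal
among correlated nuisance columns, a symbolic-regression target over the
package function set, and a toy aligned molecule series whose activities come
from a known steric+electrostatic field model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import gep
from .chem_io import ActivityRecord, Molecule, transform_activity
from .comsia import ProbeParams

__all__ = [
    "PlantedLinearSpec",
    "SymbolicSpec",
    "ToyMoleculeSpec",
    "gen_planted_linear",
    "gen_symbolic",
    "gen_toy_molecules",
    "table1_fixture",
    "activity_records",
]


@dataclass
class PlantedLinearSpec:
    n: int = 40
    p: int = 100
    n_true: int = 5
    true_indices: list[int] | None = None
    true_coef: list[float] | None = None
    intercept: float = 1.0
    nuisance_correlation: float = 0.3
    noise_sd: float = 0.1
    noise_relative: bool = True  # noise sd scales with sd of the clean signal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.nuisance_correlation < 1):
            raise ValueError("nuisance_correlation must be in [0, 1)")


def gen_planted_linear(spec: PlantedLinearSpec) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Descriptor matrix with a sparse planted linear signal.

    Nuisance columns share a single latent factor giving pairwise correlation
    ``nuisance_correlation``; true columns are independent.  Returns
    ``(matrix, y, truth)`` where truth records indices, coefficients and the
    clean signal.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.true_indices is None:
        true_idx = sorted(rng.choice(spec.p, size=spec.n_true, replace=False).tolist())
    else:
        true_idx = sorted(spec.true_indices)
        if any(i >= spec.p for i in true_idx):
            raise ValueError("true index outside column range")
    if spec.true_coef is None:
        coef = rng.uniform(1.0, 3.0, size=len(true_idx)) * rng.choice(
            [-1.0, 1.0], size=len(true_idx)
        )
    else:
        coef = np.asarray(spec.true_coef, dtype=float)
        if len(coef) != len(true_idx):
            raise ValueError("true_coef length must match true indices")
    rho = spec.nuisance_correlation
    latent = rng.standard_normal(spec.n)
    X = np.sqrt(rho) * latent[:, None] + np.sqrt(1 - rho) * rng.standard_normal(
        (spec.n, spec.p)
    )
    X[:, true_idx] = rng.standard_normal((spec.n, len(true_idx)))
    signal = X[:, true_idx] @ coef + spec.intercept
    sd = spec.noise_sd * (signal.std() if spec.noise_relative else 1.0)
    y = signal + rng.normal(0.0, sd, size=spec.n) if sd > 0 else signal.copy()
    matrix = pd.DataFrame(X, columns=[f"x{i}" for i in range(spec.p)])
    truth = {
        "true_columns": [f"x{i}" for i in true_idx],
        "true_indices": true_idx,
        "coef": coef.tolist(),
        "intercept": spec.intercept,
        "signal": signal,
        "noise_sd": float(sd),
    }
    return matrix, y, truth


@dataclass
class SymbolicSpec:
    expression: str = "d0*d1+Cos(d2)"
    n: int = 50
    n_terminals: int = 5
    ranges: dict[str, tuple[float, float]] | None = None
    default_range: tuple[float, float] = (-2.0, 2.0)
    noise_sd: float = 0.0
    seed: int = 0


def gen_symbolic(spec: SymbolicSpec) -> tuple[pd.DataFrame, np.ndarray, gep.Node]:
    """Sample terminals uniformly and evaluate a symbolic target expression.

    Raises if the sampled region hits the guarded singularities (saturated
    values), suggesting a range change.
    """
    tree = gep.parse_model_expression(spec.expression)
    rng = np.random.default_rng(spec.seed)
    cols = {}
    for i in range(spec.n_terminals):
        name = f"d{i}"
        lo, hi = (spec.ranges or {}).get(name, spec.default_range)
        cols[name] = rng.uniform(lo, hi, size=spec.n)
    X = pd.DataFrame(cols)
    values = gep.evaluate_tree(tree, {k: v for k, v in cols.items()})
    values = np.broadcast_to(np.asarray(values, dtype=float), (spec.n,)).copy()
    if np.any(np.abs(values) >= gep.SATURATION):
        raise ValueError(
            "expression hits a guarded singularity in the sampled region; "
            "change the terminal ranges"
        )
    y = values + (rng.normal(0.0, spec.noise_sd, size=spec.n) if spec.noise_sd > 0 else 0.0)
    return X, y, tree


@dataclass
class ToyMoleculeSpec:
    """Aligned toy molecule series: a shared rigid scaffold plus one
    substituent atom whose radius and charge vary per molecule."""

    n: int = 20
    scaffold_coords: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.0, 0.0, 0.0],
                [1.5, 0.0, 0.0],
                [2.2, 1.3, 0.0],
                [1.5, 2.6, 0.3],
                [0.0, 2.6, 0.0],
            ]
        )
    )
    scaffold_elements: tuple[str, ...] = ("C", "C", "N", "C", "O")
    scaffold_charges: tuple[float, ...] = (0.05, -0.05, -0.3, 0.1, -0.4)
    substituent_site: np.ndarray = field(default_factory=lambda: np.array([3.7, 1.3, 0.0]))
    substituent_element: str = "C"
    radius_range: tuple[float, float] = (1.2, 2.2)
    charge_range: tuple[float, float] = (-0.5, 0.5)
    steric_weight: float = 1.0
    electrostatic_weight: float = 1.0
    noise_sd: float = 0.0
    probe: ProbeParams = field(default_factory=ProbeParams)
    n_probe_points: int = 8
    seed: int = 0


def gen_toy_molecules(spec: ToyMoleculeSpec) -> tuple[list[Molecule], np.ndarray, dict]:
    """Generate aligned toy molecules and field-model activities.

    Activity = ``w_S * sum_q S(q) + w_E * sum_q E(q) + noise`` where the sums
    run over a fixed set of probe points near the substituent site, so the
    generating model is exactly linear in the molecules' true steric and
    electrostatic field values.
    """
    rng = np.random.default_rng(spec.seed)
    scaffold_r = np.array([1.7 if e != "H" else 1.2 for e in spec.scaffold_elements])
    mols: list[Molecule] = []
    for i in range(spec.n):
        rad = rng.uniform(*spec.radius_range)
        chg = rng.uniform(*spec.charge_range)
        coords = np.vstack([spec.scaffold_coords, spec.substituent_site])
        mols.append(
            Molecule(
                id=f"toy{i + 1}",
                elements=list(spec.scaffold_elements) + [spec.substituent_element],
                coords=coords,
                radii=np.append(scaffold_r, rad),
                charges=np.append(np.asarray(spec.scaffold_charges, dtype=float), chg),
            )
        )
    # fixed probe points around the substituent site
    offs = rng.uniform(-2.0, 2.0, size=(spec.n_probe_points, 3))
    pts = spec.substituent_site + offs

    def fields_at_points(mol: Molecule) -> tuple[float, float]:
        d2 = np.sum((pts[:, None, :] - mol.coords[None, :, :]) ** 2, axis=2)
        g = np.exp(-spec.probe.alpha * d2)
        s = float(np.sum(-spec.probe.weights["S"] * (g @ (mol.radii**3))))
        e = float(np.sum(-spec.probe.weights["E"] * (g @ mol.charges)))
        return s, e

    y = np.empty(spec.n)
    for i, mol in enumerate(mols):
        s, e = fields_at_points(mol)
        y[i] = spec.steric_weight * s + spec.electrostatic_weight * e
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n)
    truth = {
        "probe_points": pts,
        "steric_weight": spec.steric_weight,
        "electrostatic_weight": spec.electrostatic_weight,
        "noise_sd": spec.noise_sd,
    }
    return mols, y, truth


def table1_fixture() -> pd.DataFrame:
    """The packaged 50-compound activity table.

    Columns: ``compound_id`` (str), ``ic50_uM``, ``activity`` (the
    ``6 - log10`` transform), ``test_2d`` and ``test_3d`` hold-out flags.
    """
    ref = resources.files("qsarkit.data").joinpath("activity_table.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#", dtype={"compound_id": str})
    df["test_2d"] = df["test_2d"].astype(bool)
    df["test_3d"] = df["test_3d"].astype(bool)
    df["activity"] = transform_activity(df["ic50_uM"].to_numpy())
    return df


def activity_records(df: pd.DataFrame | None = None) -> list[ActivityRecord]:
    if df is None:
        df = table1_fixture()
    return [
        ActivityRecord(compound_id=str(r.compound_id), ic50=float(r.ic50_uM))
        for r in df.itertuples()
    ]
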