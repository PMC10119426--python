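"""Molecular descriptors: atom counts, equalized partial charges, shadow
ratios, and resonance-energy reductions over supplied matrices.

Quantum descriptors (MREB, MSEC) need a semi-empirical wavefunction and are
therefore accepted as *provided* columns; the resonance-energy reduction that
defines MREB is still implemented here as a standalone operation on supplied
density/resonance-integral matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_io import Molecule
from .elements import SANDERSON_EN

__all__ = [
    "PartialChargeSet",
    "ShadowResult",
    "ResonanceInput",
    "count_nitrogens",
    "ee_charges",
    "min_o_charge",
    "principal_frame",
    "shadow",
    "resonance_energy",
    "max_ch_resonance",
    "assemble_matrix",
    "read_resonance_input",
]

COMPUTED_COLUMNS = ("NN", "MPCO(ZPC)", "YZS/YZR")


@dataclass
class PartialChargeSet:
    """Per-atom partial charges (elementary charge) and the oxygen minimum."""

    charges: np.ndarray
    q_min_o: float | None = None


@dataclass
class ShadowResult:
    plane: str
    shadow_area: float  # A^2
    rectangle_area: float  # A^2

    @property
    def ratio(self) -> float:
        return self.shadow_area / self.rectangle_area


@dataclass
class ResonanceInput:
    """Density matrix, resonance integrals and the basis->atom assignment."""

    density: np.ndarray
    beta: np.ndarray
    basis_to_atom: dict[int, tuple[int, str]]

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.density.shape != self.beta.shape or self.density.ndim != 2:
            raise ValueError("density and beta must be square matrices of equal shape")
        if self.density.shape[0] != self.density.shape[1]:
            raise ValueError("density matrix must be square")
        nb = self.density.shape[0]
        missing = [i for i in range(nb) if i not in self.basis_to_atom]
        if missing:
            raise ValueError(f"basis indices without atom assignment: {missing}")

    def basis_of_atom(self, atom: int) -> list[int]:
        return [b for b, (a, _e) in self.basis_to_atom.items() if a == atom]

    def atoms_of_element(self, element: str) -> list[int]:
        return sorted({a for (a, e) in self.basis_to_atom.values() if e == element})


def count_nitrogens(molecule: Molecule) -> int:
    """Number of nitrogen atoms (descriptor NN)."""
    return sum(1 for e in molecule.elements if e == "N")


def ee_charges(
    molecule: Molecule, table: dict[str, float] | None = None
) -> PartialChargeSet:
    """One-shot Sanderson electronegativity-equalization partial charges.

    ``q_A = (S_mol - S_A) / (2.08 * sqrt(S_A))`` with ``S_mol`` the geometric
    mean of the atomic electronegativities, followed by a uniform shift so the
    charges sum exactly to the molecule's net charge.
    """
    en = dict(SANDERSON_EN)
    if table:
        en.update(table)
    missing = sorted({e for e in molecule.elements if e not in en})
    if missing:
        raise ValueError(f"no Sanderson electronegativity for element(s): {missing}")
    s = np.array([en[e] for e in molecule.elements])
    s_mol = float(np.exp(np.mean(np.log(s))))
    q = (s_mol - s) / (2.08 * np.sqrt(s))
    q = q + (molecule.net_charge - q.sum()) / len(q)
    o_idx = [i for i, e in enumerate(molecule.elements) if e == "O"]
    q_min_o = float(q[o_idx].min()) if o_idx else None
    return PartialChargeSet(charges=q, q_min_o=q_min_o)


def min_o_charge(charges: PartialChargeSet, molecule: Molecule) -> float:
    """Minimum partial charge over oxygen atoms (descriptor MPCO)."""
    o_idx = [i for i, e in enumerate(molecule.elements) if e == "O"]
    if not o_idx:
        raise ValueError(f"molecule {molecule.id!r} has no oxygen: MPCO undefined")
    return float(charges.charges[o_idx].min())


def principal_frame(molecule: Molecule) -> Molecule:
    """Rotate into the principal-axis frame (centroid at origin).

    Axes are ordered by descending spatial extent.  Sign convention: each axis
    is flipped, if necessary, so that the atom farthest from the centroid
    (ties broken by atom index) has non-negative coordinates along it; a zero
    component falls through to the next-farthest atom.
    """
    coords = molecule.coords - molecule.coords.mean(axis=0)
    if molecule.n_atoms < 2:
        warnings.warn(f"molecule {molecule.id!r}: <2 atoms, identity frame")
        return molecule.with_coords(coords)
    cov = coords.T @ coords
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    if evals[order[1]] < 1e-12:
        warnings.warn(f"molecule {molecule.id!r}: collinear atoms, identity frame")
        return molecule.with_coords(coords)
    axes = evecs[:, order]
    rotated = coords @ axes
    dist = np.linalg.norm(coords, axis=1)
    # quantize distances so exact ties are not broken by rounding noise
    by_far = np.lexsort((np.arange(len(dist)), -np.round(dist, 6)))
    for ax in range(3):
        for i in by_far:
            if abs(rotated[i, ax]) > 1e-9:
                if rotated[i, ax] < 0:
                    rotated[:, ax] = -rotated[:, ax]
                break
    return molecule.with_coords(rotated)


_PLANES = {"XY": (0, 1), "XZ": (0, 2), "YZ": (1, 2)}


def shadow(molecule: Molecule, plane: str = "YZ", resolution: float = 0.05) -> ShadowResult:
    """Projected van der Waals shadow on a principal plane.

    ``shadow_area`` is the rasterized area of the union of atom discs (centres
    projected onto the plane, radii = vdW radii); ``rectangle_area`` is the
    product of the projected extents including radii.  The molecule should
    already be in its principal frame (see :func:`principal_frame`).
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if plane not in _PLANES:
        raise ValueError(f"plane must be one of {sorted(_PLANES)}, got {plane!r}")
    i, j = _PLANES[plane]
    u = molecule.coords[:, i]
    v = molecule.coords[:, j]
    r = molecule.radii
    umin, umax = float(np.min(u - r)), float(np.max(u + r))
    vmin, vmax = float(np.min(v - r)), float(np.max(v + r))
    rectangle = (umax - umin) * (vmax - vmin)
    nu = max(1, int(np.ceil((umax - umin) / resolution)))
    nv = max(1, int(np.ceil((vmax - vmin) / resolution)))
    uc = umin + (np.arange(nu) + 0.5) * resolution
    vc = vmin + (np.arange(nv) + 0.5) * resolution
    covered = np.zeros((nu, nv), dtype=bool)
    for k in range(molecule.n_atoms):
        du2 = (uc - u[k]) ** 2
        dv2 = (vc - v[k]) ** 2
        covered |= du2[:, None] + dv2[None, :] <= r[k] ** 2
    area = float(covered.sum()) * resolution**2
    return ShadowResult(plane=plane, shadow_area=area, rectangle_area=rectangle)


def resonance_energy(inp: ResonanceInput, atom_a: int, atom_b: int) -> float:
    """Sum of ``P[mu,nu] * beta[mu,nu]`` over basis functions of two atoms."""
    if atom_a == atom_b:
        raise ValueError("atoms must be distinct")
    mus = inp.basis_of_atom(atom_a)
    nus = inp.basis_of_atom(atom_b)
    if not mus or not nus:
        raise ValueError(f"atom without basis functions: {atom_a if not mus else atom_b}")
    mus = np.asarray(mus)
    nus = np.asarray(nus)
    return float(np.sum(inp.density[np.ix_(mus, nus)] * inp.beta[np.ix_(mus, nus)]))


def max_ch_resonance(inp: ResonanceInput) -> float:
    """Maximum resonance energy over all C-H atom pairs (descriptor MREB)."""
    carbons = inp.atoms_of_element("C")
    hydrogens = inp.atoms_of_element("H")
    if not carbons or not hydrogens:
        raise ValueError("no C-H atom pair in resonance input")
    return max(resonance_energy(inp, c, h) for c in carbons for h in hydrogens)


def read_resonance_input(matrix_path, basis_map_path) -> tuple[np.ndarray, dict]:
    """Read a whitespace-delimited matrix and a ``basis_index,atom_index,element``
    CSV basis map.  Returns ``(matrix, basis_to_atom)``."""
    matrix = np.loadtxt(matrix_path)
    if matrix.ndim == 0:
        matrix = matrix.reshape(1, 1)
    bm = pd.read_csv(basis_map_path)
    need = {"basis_index", "atom_index", "element"}
    if need - set(bm.columns):
        raise ValueError(f"basis map missing columns {sorted(need - set(bm.columns))}")
    basis_to_atom = {
        int(r.basis_index): (int(r.atom_index), str(r.element)) for r in bm.itertuples()
    }
    return matrix, basis_to_atom


def assemble_matrix(
    molecules: list[Molecule],
    provided: pd.DataFrame | None = None,
    shadow_plane: str = "YZ",
    shadow_resolution: float = 0.05,
) -> pd.DataFrame:
    """Assemble the descriptor matrix for a molecule list.

    Computed columns: NN (nitrogen count), MPCO(ZPC) (minimum equalized oxygen
    charge; NaN when the compound has no oxygen), YZS/YZR (shadow ratio on the
    requested principal plane).  ``provided`` columns (e.g. MREB, MSEC) are
    joined on ``compound_id``.  Column provenance is recorded in
    ``df.attrs["provenance"]``.
    """
    rows = {}
    for mol in molecules:
        framed = principal_frame(mol)
        sh = shadow(framed, plane=shadow_plane, resolution=shadow_resolution)
        q = ee_charges(mol)
        rows[mol.id] = {
            "NN": float(count_nitrogens(mol)),
            "MPCO(ZPC)": q.q_min_o if q.q_min_o is not None else np.nan,
            "YZS/YZR": sh.ratio,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "compound_id"
    provenance = {c: "computed" for c in df.columns}
    if provided is not None:
        prov = provided.copy()
        if "compound_id" in prov.columns:
            prov["compound_id"] = prov["compound_id"].astype(str)
            prov = prov.set_index("compound_id")
        dup = set(prov.columns) & set(df.columns)
        if dup:
            raise ValueError(f"provided columns clash with computed ones: {sorted(dup)}")
        orphans = sorted(set(df.index) - set(prov.index))
        if orphans:
            raise ValueError(f"compounds missing from provided descriptors: {orphans}")
        df = df.join(prov.loc[df.index])
        provenance.update({c: "provided" for c in prov.columns})
    df.attrs["provenance"] = provenance
    return df


def write_matrix_csv(df: pd.DataFrame, path) -> None:
    """Write a descriptor matrix with provenance recorded in ``#`` header lines."""
    provenance = df.attrs.get("provenance", {})
    with open(path, "w") as fh:
        for col, src in provenance.items():
            fh.write(f"# provenance: {col} = {src}\n")
        df.to_csv(fh)


def read_matrix_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", index_col=0)
    df.index = df.index.astype(str)
    provenance = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "provenance:" in line:
                body = line.split("provenance:", 1)[1]
                col, src = body.split("=")
                provenance[col.strip()] = src.strip()
    df.attrs["provenance"] = provenance
    return df
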