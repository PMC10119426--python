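"""Structure and activity I/O, the activity transform, and dataset splitting.

Molecules are lightweight containers (no bond perception): every downstream
descriptor or field operation needs only elements, coordinates, van der Waals
radii and (optionally) partial charges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .elements import VDW_RADII

__all__ = [
    "Molecule",
    "ActivityRecord",
    "DatasetSplit",
    "read_structures",
    "read_activity_csv",
    "write_activity_csv",
    "transform_activity",
    "inverse_transform_activity",
    "split_dataset",
]


@dataclass
class Molecule:
    """A rigid 3D molecule: elements, coordinates, vdW radii, optional charges.

    Parameters
    ----------
    id : str
        Compound identifier.
    elements : list of str
        Element symbol per atom.
    coords : (n_atoms, 3) float array
        Cartesian coordinates in Angstrom.
    radii : (n_atoms,) float array
        Van der Waals radii in Angstrom, strictly positive.
    charges : (n_atoms,) float array, optional
        Partial charges in elementary-charge units.
    net_charge : int
        Net molecular charge.
    """

    id: str
    elements: list[str]
    coords: np.ndarray
    radii: np.ndarray
    charges: np.ndarray | None = None
    net_charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
        n = len(self.elements)
        if n < 1:
            raise ValueError(f"molecule {self.id!r}: needs at least one atom")
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"molecule {self.id!r}: coords shape {self.coords.shape} != ({n}, 3)"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"molecule {self.id!r}: non-finite coordinates")
        if self.radii.shape != (n,) or not np.all(self.radii > 0):
            raise ValueError(f"molecule {self.id!r}: radii must be positive, one per atom")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        return Molecule(
            id=self.id,
            elements=list(self.elements),
            coords=np.asarray(coords, dtype=float),
            radii=self.radii.copy(),
            charges=None if self.charges is None else self.charges.copy(),
            net_charge=self.net_charge,
        )


@dataclass
class ActivityRecord:
    """One compound's measured IC50 (micromolar) and transformed activity."""

    compound_id: str
    ic50: float
    activity: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not (self.ic50 > 0):
            raise ValueError(f"{self.compound_id}: ic50 must be > 0, got {self.ic50}")
        if math.isnan(self.activity):
            self.activity = transform_activity(self.ic50)


@dataclass
class DatasetSplit:
    train_ids: list[str]
    test_ids: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


def _lookup_radius(element: str, radii: dict[str, float]) -> float:
    try:
        return radii[element]
    except KeyError:
        raise ValueError(f"unknown element {element!r}: no van der Waals radius") from None


def transform_activity(ic50):
    """Map micromolar IC50 to the modelling response ``6 - log10(IC50)``."""
    ic50 = np.asarray(ic50, dtype=float)
    if np.any(ic50 <= 0):
        raise ValueError("ic50 must be strictly positive")
    out = 6.0 - np.log10(ic50)
    return float(out) if out.ndim == 0 else out


def inverse_transform_activity(activity):
    """Inverse of :func:`transform_activity`: ``10**(6 - activity)``."""
    activity = np.asarray(activity, dtype=float)
    out = np.power(10.0, 6.0 - activity)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# structure readers


def read_structures(path, fmt: str | None = None, radii: dict[str, float] | None = None):
    """Read molecules from an SDF (V2000), MOL2 or XYZ file.

    Radii absent from the file (always, for these formats) are assigned from
    the packaged Bondi-style table, overridable via ``radii``.

    Returns a list of :class:`Molecule`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    if fmt is None:
        fmt = path.suffix.lstrip(".").upper()
    fmt = fmt.upper()
    table = dict(VDW_RADII)
    if radii:
        table.update(radii)
    if fmt == "XYZ":
        return _read_xyz(path, table)
    if fmt == "MOL2":
        return _read_mol2(path, table)
    if fmt == "SDF":
        return _read_sdf(path, table)
    raise ValueError(f"unsupported structure format: {fmt!r} (expected SDF, MOL2 or XYZ)")


def _read_xyz(path: Path, radii: dict[str, float]) -> list[Molecule]:
    lines = path.read_text().splitlines()
    mols: list[Molecule] = []
    i = 0
    record = 0
    # Tolerate both the standard counted format and bare "El x y z" blocks.
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        record += 1
        try:
            n = int(lines[i].split()[0])
            name = lines[i + 1].strip() or f"{path.stem}_{record}"
            body = lines[i + 2 : i + 2 + n]
            i += 2 + n
        except (ValueError, IndexError):
            # headerless: consume contiguous atom lines
            body = []
            while i < len(lines) and lines[i].strip():
                body.append(lines[i])
                i += 1
            name = f"{path.stem}_{record}"
            n = len(body)
        if len(body) != n or n == 0:
            raise ValueError(f"{path}: XYZ record {record} is truncated")
        elements, coords = [], []
        for ln in body:
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed XYZ atom line: {ln!r}")
            elements.append(parts[0].capitalize() if len(parts[0]) > 1 else parts[0])
            coords.append([float(x) for x in parts[1:4]])
        r = np.array([_lookup_radius(e, radii) for e in elements])
        mols.append(Molecule(id=name, elements=elements, coords=np.array(coords), radii=r))
    return mols


def _read_mol2(path: Path, radii: dict[str, float]) -> list[Molecule]:
    mols: list[Molecule] = []
    name = None
    in_atoms = False
    await_name = 0
    elements: list[str] = []
    coords: list[list[float]] = []
    charges: list[float] = []
    have_charge = False

    def flush():
        nonlocal elements, coords, charges, have_charge
        if elements:
            r = np.array([_lookup_radius(e, radii) for e in elements])
            mols.append(
                Molecule(
                    id=name or f"{path.stem}_{len(mols) + 1}",
                    elements=list(elements),
                    coords=np.array(coords),
                    radii=r,
                    charges=np.array(charges) if have_charge else None,
                )
            )
        elements, coords, charges, have_charge = [], [], [], False

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            tag = line[len("@<TRIPOS>") :]
            in_atoms = tag == "ATOM"
            if tag == "MOLECULE":
                flush()
                await_name = 1
            continue
        if await_name and line:
            name = line
            await_name = 0
            continue
        if in_atoms and line:
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}: malformed MOL2 atom line {lineno}: {raw!r}")
            try:
                x, y, z = (float(v) for v in parts[2:5])
            except ValueError:
                raise ValueError(
                    f"{path}: malformed MOL2 atom line {lineno}: {raw!r}"
                ) from None
            elem = parts[5].split(".")[0]
            elements.append(elem)
            coords.append([x, y, z])
            if len(parts) >= 9:
                charges.append(float(parts[8]))
                have_charge = True
            else:
                charges.append(0.0)
    flush()
    if not mols:
        raise ValueError(f"{path}: no MOL2 records found")
    return mols


def _read_sdf(path: Path, radii: dict[str, float]) -> list[Molecule]:
    from rdkit import Chem  # deferred: only SDF needs a chemistry toolkit

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    mols: list[Molecule] = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{path}: unparseable SDF record {idx}")
        if mol.GetNumConformers() == 0:
            raise ValueError(f"{path}: SDF record {idx} has no coordinates")
        conf = mol.GetConformer()
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        coords = np.array(
            [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
             for i in range(mol.GetNumAtoms())]
        )
        r = np.array([_lookup_radius(e, radii) for e in elements])
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"{path.stem}_{idx + 1}"
        net = sum(a.GetFormalCharge() for a in mol.GetAtoms())
        mols.append(
            Molecule(id=name, elements=elements, coords=coords, radii=r, net_charge=net)
        )
    if not mols:
        raise ValueError(f"{path}: no SDF records found")
    return mols


# ---------------------------------------------------------------------------
# activity tables


def read_activity_csv(path) -> list[ActivityRecord]:
    """Read ``compound_id,ic50_uM`` CSV into activity records (transform applied)."""
    df = pd.read_csv(path, comment="#", dtype={"compound_id": str})
    missing = {"compound_id", "ic50_uM"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: activity CSV missing columns {sorted(missing)}")
    return [
        ActivityRecord(compound_id=str(row.compound_id), ic50=float(row.ic50_uM))
        for row in df.itertuples()
    ]


def write_activity_csv(records: list[ActivityRecord], path) -> None:
    df = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "ic50_uM": [r.ic50 for r in records],
            "activity": [r.activity for r in records],
        }
    )
    df.to_csv(path, index=False)


def split_dataset(
    records: list[ActivityRecord], n_train: int, n_test: int, seed: int
) -> DatasetSplit:
    """Uniform random partition into ``n_train``/``n_test``, reproducible by seed."""
    n = len(records)
    if n_train + n_test != n:
        raise ValueError(f"n_train + n_test = {n_train + n_test} != {n} records")
    if n_train < 1 or n_test < 0:
        raise ValueError("n_train must be >= 1 and n_test >= 0")
    ids = [r.compound_id for r in records]
    if len(set(ids)) != n:
        raise ValueError("duplicate compound ids")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_ids = [ids[i] for i in sorted(perm[:n_train])]
    test_ids = [ids[i] for i in sorted(perm[n_train:])]
    return DatasetSplit(train_ids=train_ids, test_ids=test_ids, seed=seed)
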