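"""CoMSIA-style 3D-QSAR: rigid template alignment, Gaussian similarity-index
fields on a lattice, PLS with leave-one-out q^2, field contributions and
contour masks.

Field value at grid point q for field k:
``A_k(q) = -sum_i w_probe,k * w_ik * exp(-alpha * r_iq^2)``
with steric atom weight ``r_vdw^3``, electrostatic weight the partial charge,
and hydrophobic/donor/acceptor weights from the packaged atom-type table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_io import Molecule
from .elements import ACCEPTOR_W, DONOR_W, HYDROPHOBIC_W

__all__ = [
    "FIELD_NAMES",
    "AlignmentSpec",
    "ProbeParams",
    "FieldGrid",
    "PLSModel",
    "ComsiaModel",
    "align_to_template",
    "kabsch",
    "build_grid",
    "similarity_fields",
    "field_block",
    "pls_fit",
    "loo_q2",
    "select_onc",
    "field_contributions",
    "column_filter",
    "contour_masks",
    "fit_comsia",
    "predict_comsia",
]

FIELD_NAMES = ("S", "E", "H", "D", "A")


@dataclass
class AlignmentSpec:
    """Template id plus, per molecule, (molecule_atom_index, template_atom_index)
    correspondences over the common substructure."""

    template_id: str
    atom_maps: dict[str, list[tuple[int, int]]]


@dataclass
class ProbeParams:
    alpha: float = 0.3  # A^-2 attenuation
    charge: float = 1.0
    radius: float = 1.0
    hydrophobic: float = 1.0
    donor: float = 1.0
    acceptor: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    @property
    def weights(self) -> dict[str, float]:
        return {
            "S": self.radius**3,
            "E": self.charge,
            "H": self.hydrophobic,
            "D": self.donor,
            "A": self.acceptor,
        }


@dataclass
class FieldGrid:
    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All grid points as an (n_points, 3) array, z fastest."""
        ax = [self.origin[d] + self.spacing * np.arange(self.shape[d]) for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def upper_corner(self) -> np.ndarray:
        return self.origin + self.spacing * (np.asarray(self.shape) - 1)


# ---------------------------------------------------------------------------
# alignment


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing ||P @ R + t - Q||."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = qc - pc @ R
    return R, t


def align_to_template(
    molecules: list[Molecule], spec: AlignmentSpec
) -> tuple[list[Molecule], dict[str, float]]:
    """Rigidly superpose each molecule onto the template over mapped atoms.

    Returns the aligned molecules (template unchanged) and per-molecule RMSD
    over the mapped atoms, in Angstrom.
    """
    by_id = {m.id: m for m in molecules}
    if spec.template_id not in by_id:
        raise ValueError(f"template {spec.template_id!r} not among molecules")
    template = by_id[spec.template_id]
    aligned: list[Molecule] = []
    rmsds: dict[str, float] = {}
    for mol in molecules:
        if mol.id == spec.template_id:
            aligned.append(mol.with_coords(mol.coords))
            rmsds[mol.id] = 0.0
            continue
        if mol.id not in spec.atom_maps:
            raise ValueError(f"no atom map for molecule {mol.id!r}")
        pairs = spec.atom_maps[mol.id]
        if len(pairs) < 3:
            raise ValueError(f"molecule {mol.id!r}: need >= 3 mapped atoms")
        P = mol.coords[[p[0] for p in pairs]]
        Q = template.coords[[p[1] for p in pairs]]
        centered = P - P.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise ValueError(f"molecule {mol.id!r}: mapped atoms are collinear")
        R, t = kabsch(P, Q)
        new_coords = mol.coords @ R + t
        aligned.append(mol.with_coords(new_coords))
        diff = P @ R + t - Q
        rmsds[mol.id] = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return aligned, rmsds


# ---------------------------------------------------------------------------
# grid and fields


def build_grid(molecules: list[Molecule], spacing: float = 2.0, margin: float = 4.0) -> FieldGrid:
    """Axis-aligned lattice covering the union atom-centre bounding box plus margin."""
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if not molecules:
        raise ValueError("need at least one molecule")
    coords = np.vstack([m.coords for m in molecules])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing - 1e-9)) + 1 for d in range(3))
    return FieldGrid(origin=lo, spacing=spacing, shape=shape)


def _atom_weights(mol: Molecule, probe: ProbeParams) -> dict[str, np.ndarray]:
    if mol.charges is None:
        raise ValueError(f"molecule {mol.id!r}: partial charges required for the E field")
    w = {"S": mol.radii**3, "E": mol.charges}
    for fname, table in (("H", HYDROPHOBIC_W), ("D", DONOR_W), ("A", ACCEPTOR_W)):
        vals = []
        for i, e in enumerate(mol.elements):
            if e not in table:
                raise ValueError(
                    f"molecule {mol.id!r} atom {i} ({e}): no {fname}-field weight"
                )
            vals.append(table[e])
        w[fname] = np.asarray(vals)
    return w


def similarity_fields(
    mol: Molecule, grid: FieldGrid, probe: ProbeParams | None = None
) -> dict[str, np.ndarray]:
    """Gaussian similarity indices of one molecule at every grid point.

    Returns ``{field: (n_points,) array}`` for S, E, H, D, A.
    """
    probe = probe or ProbeParams()
    weights = _atom_weights(mol, probe)
    pts = grid.points()
    d2 = np.sum((pts[:, None, :] - mol.coords[None, :, :]) ** 2, axis=2)
    g = np.exp(-probe.alpha * d2)  # (n_points, n_atoms)
    pw = probe.weights
    return {k: -pw[k] * (g @ weights[k]) for k in FIELD_NAMES}


def field_block(
    molecules: list[Molecule], grid: FieldGrid, probe: ProbeParams | None = None
) -> pd.DataFrame:
    """Stack per-molecule fields into a modelling block.

    Columns are ordered field-major: ``S:0 ... S:N-1, E:0, ...``.
    """
    probe = probe or ProbeParams()
    rows = []
    ids = []
    for mol in molecules:
        f = similarity_fields(mol, grid, probe)
        rows.append(np.concatenate([f[k] for k in FIELD_NAMES]))
        ids.append(mol.id)
    cols = [f"{k}:{i}" for k in FIELD_NAMES for i in range(grid.n_points)]
    return pd.DataFrame(np.vstack(rows), index=ids, columns=cols)


# ---------------------------------------------------------------------------
# PLS


@dataclass
class PLSModel:
    """PLS1 regression model on (centered) field columns."""

    ncomp: int
    coef: np.ndarray
    intercept: float
    x_mean: np.ndarray
    r2: float
    see: float
    f: float
    q2: float | None = None
    onc: int | None = None
    contributions: dict[str, float] | None = None
    column_names: list[str] = field(default_factory=list)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.coef + self.intercept


def _nipals(X: np.ndarray, y: np.ndarray, ncomp: int) -> tuple[np.ndarray, float, np.ndarray]:
    """PLS1 via NIPALS with deflation; returns (coef, intercept, x_mean)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    q = np.zeros(ncomp)
    Xd, yd = Xc.copy(), yc.copy()
    used = 0
    for a in range(ncomp):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-14:
            break
        p_a = Xd.T @ t / tt
        q_a = float(yd @ t / tt)
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        Xd = Xd - np.outer(t, p_a)
        yd = yd - t * q_a
        used += 1
    if used == 0:
        coef = np.zeros(p)
    else:
        Wu, Pu, qu = W[:, :used], P[:, :used], q[:used]
        coef = Wu @ np.linalg.solve(Pu.T @ Wu, qu)
    intercept = y_mean
    return coef, intercept, x_mean


def pls_fit(X, y, ncomp: int, column_names: list[str] | None = None) -> PLSModel:
    """Fit PLS1 with ``ncomp`` latent components.

    ``SEE = sqrt(RSS / (n - ncomp - 1))``; ``F = (r2/ncomp)/((1-r2)/(n-ncomp-1))``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if ncomp < 1:
        raise ValueError("ncomp must be >= 1")
    if ncomp > min(n - 1, p):
        raise ValueError(f"ncomp={ncomp} too large for n={n}, p={p}")
    coef, intercept, x_mean = _nipals(X, y, ncomp)
    yhat = (X - x_mean) @ coef + intercept
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    dof = n - ncomp - 1
    see = float(np.sqrt(rss / dof)) if dof > 0 else np.nan
    with np.errstate(divide="ignore"):
        f = (r2 / ncomp) / ((1.0 - r2) / dof) if dof > 0 and r2 < 1.0 else np.inf
    return PLSModel(
        ncomp=ncomp,
        coef=coef,
        intercept=intercept,
        x_mean=x_mean,
        r2=r2,
        see=see,
        f=f,
        column_names=list(column_names) if column_names is not None else [],
    )


def loo_q2(X, y, ncomp: int) -> float:
    """Leave-one-out q^2 at fixed component count.

    ``q2 = 1 - PRESS / sum_i (y_i - mean(y_{-i}))^2``: each held-out compound
    is referenced to its training fold's mean, so a mean-only predictor scores
    exactly 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need n >= 4 for leave-one-out q^2")
    press = 0.0
    denom = 0.0
    for i in range(n):
        mask = np.arange(n) != i
        ncomp_i = min(ncomp, n - 2)
        model = pls_fit(X[mask], y[mask], ncomp_i)
        pred = float(model.predict(X[i : i + 1])[0])
        press += (y[i] - pred) ** 2
        denom += (y[i] - y[mask].mean()) ** 2
    if denom <= 0:
        raise ValueError("zero-variance response")
    return 1.0 - press / denom


def select_onc(X, y, max_comp: int) -> tuple[int, list[float]]:
    """Optimal component count: argmax of q^2, smaller count on ties."""
    if max_comp < 1:
        raise ValueError("max_comp must be >= 1")
    n, p = np.asarray(X).shape
    max_comp = min(max_comp, n - 2, p)
    q2s = [loo_q2(X, y, a) for a in range(1, max_comp + 1)]
    onc = int(np.argmax(q2s)) + 1  # argmax returns first maximum -> smallest count
    return onc, q2s


def field_contributions(model: PLSModel, X: pd.DataFrame) -> dict[str, float]:
    """Per-field percentage of total ``sum_j |coef_j| * sd_j``."""
    sds = X.to_numpy(dtype=float).std(axis=0, ddof=1)
    scores = np.abs(model.coef) * sds
    total = scores.sum()
    if total <= 0:
        raise ValueError("all-zero coefficients: contributions undefined")
    names = model.column_names or list(X.columns)
    out = {k: 0.0 for k in FIELD_NAMES}
    for name, sc in zip(names, scores):
        fkey = name.split(":")[0]
        out[fkey] = out.get(fkey, 0.0) + float(sc)
    return {k: 100.0 * v / total for k, v in out.items()}


def column_filter(X: pd.DataFrame, sigma_threshold: float = 0.0) -> np.ndarray:
    """Boolean mask of columns with sample sd >= threshold."""
    sds = X.to_numpy(dtype=float).std(axis=0, ddof=1)
    mask = sds >= sigma_threshold
    if not mask.any():
        raise ValueError("column filter removed every column")
    return mask


def contour_masks(
    model: PLSModel,
    X: pd.DataFrame,
    favored_pct: float = 80.0,
    disfavored_pct: float = 20.0,
) -> dict[str, dict[str, np.ndarray]]:
    """Favored/disfavored point masks per field from coef*sd values.

    Strict percentile inequalities, so a uniform field yields empty masks.
    """
    sds = X.to_numpy(dtype=float).std(axis=0, ddof=1)
    values = model.coef * sds
    names = model.column_names or list(X.columns)
    out: dict[str, dict[str, np.ndarray]] = {}
    for k in FIELD_NAMES:
        idx = [i for i, nm in enumerate(names) if nm.split(":")[0] == k]
        if not idx:
            raise ValueError(f"field {k} has no columns")
        v = values[idx]
        hi = np.percentile(v, favored_pct)
        lo = np.percentile(v, disfavored_pct)
        out[k] = {"favored": v > hi, "disfavored": v < lo, "values": v}
    return out


# ---------------------------------------------------------------------------
# end-to-end CoMSIA model


@dataclass
class ComsiaModel:
    pls: PLSModel
    grid: FieldGrid
    probe: ProbeParams
    column_mask: np.ndarray
    column_names: list[str]
    q2s: list[float]

    def to_dict(self) -> dict:
        return {
            "onc": self.pls.onc,
            "q2": self.pls.q2,
            "r2": self.pls.r2,
            "see": self.pls.see,
            "f": self.pls.f,
            "contributions": self.pls.contributions,
            "q2_by_ncomp": [float(v) for v in self.q2s],
            "grid": {
                "origin": [float(v) for v in self.grid.origin],
                "spacing": self.grid.spacing,
                "shape": list(self.grid.shape),
            },
            "probe": vars(self.probe).copy(),
        }


def fit_comsia(
    molecules: list[Molecule],
    activities,
    spacing: float = 2.0,
    margin: float = 4.0,
    probe: ProbeParams | None = None,
    max_comp: int = 10,
    sigma_threshold: float = 0.0,
    ncomp: int | None = None,
) -> ComsiaModel:
    """Build grid + fields for pre-aligned molecules and fit PLS at the ONC."""
    probe = probe or ProbeParams()
    y = np.asarray(activities, dtype=float)
    grid = build_grid(molecules, spacing=spacing, margin=margin)
    block = field_block(molecules, grid, probe)
    mask = column_filter(block, sigma_threshold) if sigma_threshold > 0 else np.ones(
        block.shape[1], dtype=bool
    )
    sub = block.loc[:, mask]
    if ncomp is None:
        onc, q2s = select_onc(sub.to_numpy(), y, max_comp)
    else:
        onc = ncomp
        q2s = [loo_q2(sub.to_numpy(), y, a) for a in range(1, min(ncomp, len(y) - 2) + 1)]
    model = pls_fit(sub.to_numpy(), y, onc, column_names=list(sub.columns))
    model.onc = onc
    model.q2 = q2s[onc - 1] if onc - 1 < len(q2s) else loo_q2(sub.to_numpy(), y, onc)
    model.contributions = field_contributions(model, sub)
    return ComsiaModel(
        pls=model,
        grid=grid,
        probe=probe,
        column_mask=mask,
        column_names=list(block.columns),
        q2s=q2s,
    )


def predict_comsia(model: ComsiaModel, mol: Molecule) -> float:
    """Predict activity for a molecule already in the model's alignment frame."""
    lo = model.grid.origin
    hi = model.grid.upper_corner()
    if np.any(mol.coords < lo) or np.any(mol.coords > hi):
        warnings.warn(f"molecule {mol.id!r} extends outside the field grid (extrapolation)")
    f = similarity_fields(mol, model.grid, model.probe)
    row = np.concatenate([f[k] for k in FIELD_NAMES])[model.column_mask]
    return float(model.pls.predict(row[None, :])[0])


def export_grid_csv(model: ComsiaModel, molecules: list[Molecule], path) -> None:
    """Flat CSV ``point_index,x,y,z,S,E,H,D,A`` of mean fields over molecules."""
    pts = model.grid.points()
    acc = {k: np.zeros(model.grid.n_points) for k in FIELD_NAMES}
    for mol in molecules:
        f = similarity_fields(mol, model.grid, model.probe)
        for k in FIELD_NAMES:
            acc[k] += f[k]
    nm = len(molecules)
    df = pd.DataFrame(
        {
            "point_index": np.arange(model.grid.n_points),
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
            **{k: acc[k] / nm for k in FIELD_NAMES},
        }
    )
    df.to_csv(path, index=False)


def export_grid_dx(values: np.ndarray, grid: FieldGrid, path) -> None:
    """Write one scalar field as an OpenDX-style regular grid file."""
    nx, ny, nz = grid.shape
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing:.6f} 0 0\n")
        fh.write(f"delta 0 {grid.spacing:.6f} 0\n")
        fh.write(f"delta 0 0 {grid.spacing:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {values.size} data follows\n"
        )
        for i in range(0, values.size, 3):
            fh.write(" ".join(f"{v:.8e}" for v in values[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
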