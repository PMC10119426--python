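"""Per-element data tables used across the package.

All tables are plain dicts keyed by element symbol so callers can copy and
override entries (e.g. ``radii = {**VDW_RADII, "C": 1.75}``).
"""

from __future__ import annotations

# Bondi-style van der Waals radii in Angstrom. Elements without a measured
# Bondi value use common force-field estimates.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "He": 1.40,
    "Li": 1.82,
    "Be": 1.53,
    "B": 1.92,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Ne": 1.54,
    "Na": 2.27,
    "Mg": 1.73,
    "Al": 1.84,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Ar": 1.88,
    "K": 2.75,
    "Ca": 2.31,
    "Zn": 1.39,
    "Br": 1.85,
    "I": 1.98,
}

# Sanderson electronegativities (dimensionless, Sanderson's SR scale).
SANDERSON_EN: dict[str, float] = {
    "H": 2.592,
    "Li": 0.670,
    "Be": 1.810,
    "B": 2.275,
    "C": 2.746,
    "N": 3.194,
    "O": 3.654,
    "F": 4.000,
    "Na": 0.560,
    "Mg": 1.318,
    "Al": 1.714,
    "Si": 2.138,
    "P": 2.515,
    "S": 2.957,
    "Cl": 3.475,
    "K": 0.445,
    "Ca": 0.946,
    "Br": 3.219,
    "I": 2.778,
}

# Simple per-element atom weights for the hydrophobic (H), hydrogen-bond
# donor (D) and acceptor (A) similarity fields.  These are package
# conventions (documented, user-overridable), not literature parameters:
# carbon and halogens carry hydrophobic weight, N/O carry donor/acceptor
# weight.  Connectivity-aware typing is deliberately out of scope.
HYDROPHOBIC_W: dict[str, float] = {
    "H": 0.1,
    "C": 1.0,
    "N": -0.3,
    "O": -0.4,
    "F": 0.4,
    "P": 0.2,
    "S": 0.6,
    "Cl": 0.5,
    "Br": 0.5,
    "I": 0.5,
}

DONOR_W: dict[str, float] = {
    "H": 0.0,
    "C": 0.0,
    "N": 1.0,
    "O": 0.5,
    "F": 0.0,
    "P": 0.0,
    "S": 0.1,
    "Cl": 0.0,
    "Br": 0.0,
    "I": 0.0,
}

ACCEPTOR_W: dict[str, float] = {
    "H": 0.0,
    "C": 0.0,
    "N": 0.5,
    "O": 1.0,
    "F": 0.3,
    "P": 0.1,
    "S": 0.2,
    "Cl": 0.0,
    "Br": 0.0,
    "I": 0.0,
}
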