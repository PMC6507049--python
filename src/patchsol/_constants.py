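"""Physical constants, unit conversions, and built-in parameter tables.

All internal energies are kJ/mol, potentials mV, distances Å, charges in
elementary charge units.  Every conversion constant used anywhere in the
package is pinned here.
"""

from __future__ import annotations

import math

# CODATA 2018
ELEMENTARY_CHARGE = 1.602176634e-19  # C
AVOGADRO = 6.02214076e23  # 1/mol
BOLTZMANN = 1.380649e-23  # J/K
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
GAS_CONSTANT_KJ = 8.31446261815324e-3  # kJ/(mol K)

# e / (4 pi eps0), in mV * Angstrom: potential of a unit charge at distance
# d Angstrom in vacuum is COULOMB_MV_A / d millivolts.
COULOMB_MV_A = (
    ELEMENTARY_CHARGE / (4.0 * math.pi * VACUUM_PERMITTIVITY) * 1e10 * 1e3
)  # ~14399.645 mV Å

# N_A e^2 / (4 pi eps0), in kJ Å / mol: pair energy of two unit charges at
# distance d Angstrom in vacuum is COULOMB_KJ_A / d kJ/mol.
COULOMB_KJ_A = (
    AVOGADRO * ELEMENTARY_CHARGE**2 / (4.0 * math.pi * VACUUM_PERMITTIVITY) * 1e10 / 1e3
)  # ~1389.35 kJ Å / mol

LN10 = math.log(10.0)

# Fixed united-atom radius table (Å); hydrogens are normally absent from the
# structures we read, so the heavy-atom radii absorb them.
ELEMENT_RADII = {
    "C": 1.9,
    "N": 1.7,
    "O": 1.5,
    "S": 1.85,
    "H": 1.0,
    "P": 1.9,
}
DEFAULT_RADIUS = 1.8  # anything exotic

# Formal charges at pH 7 for the fixed-charge (patch) map.  Each entry maps a
# residue name to {atom_name: charge}.  Charges of a carboxylate / guanidinium
# are split over the two equivalent atoms to avoid orientation artifacts.
# His is neutral here (model pKa 6.3 < 7); it titrates in the titration module.
SIDECHAIN_CHARGES = {
    "ASP": {"OD1": -0.5, "OD2": -0.5},
    "GLU": {"OE1": -0.5, "OE2": -0.5},
    "LYS": {"NZ": +1.0},
    "ARG": {"NH1": +0.5, "NH2": +0.5},
}

# Terminal charges: the free amino terminus carries +1 on N, the carboxylate
# -1 split over the two terminal oxygens (or all of it on O if OXT is absent).
NTERM_CHARGE = +1.0
CTERM_CHARGE = -1.0

# Model (intrinsic / unfolded-state) pKa values for titratable groups.
MODEL_PKA = {
    "ASP": 4.0,
    "GLU": 4.4,
    "HIS": 6.3,
    "LYS": 10.4,
    "ARG": 12.0,
    "TYR": 9.6,
    "CYS": 8.3,
    "NTERM": 7.5,
    "CTERM": 3.8,
}

# Acid sites are neutral when protonated and -1 when deprotonated;
# base sites are +1 when protonated and neutral when deprotonated.
ACID_SITES = {"ASP", "GLU", "TYR", "CYS", "CTERM"}
BASE_SITES = {"HIS", "LYS", "ARG", "NTERM"}

# Atoms whose centroid carries the titratable charge of each site type.
SITE_CENTER_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2"),
    "TYR": ("OH",),
    "CYS": ("SG",),
    "NTERM": ("N",),
    "CTERM": ("O", "OXT"),
}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# Net sidechain formal charge at pH 7 per 1-letter code (His neutral).
AA_FORMAL_CHARGE = {a: 0.0 for a in AA1_TO_3}
AA_FORMAL_CHARGE.update({"D": -1.0, "E": -1.0, "K": +1.0, "R": +1.0})

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")

DISULFIDE_SG_CUTOFF = 2.5  # Å, SG-SG distance below which cysteines are bonded
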