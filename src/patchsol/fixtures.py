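"""Deterministic toy structures with analytically known expectations.

Every generator returns ``(pdb_text, expected)`` where ``expected`` is a
machine-readable record of closed-form values (total solvent-accessible
area, potentials at probe points, patch topology) computed *at generation
time* from geometry — not by running the pipeline — so the test corpus is
self-validating.  Toy "residues" are emitted as ordinary ALA/LYS/ASP
residues: nothing downstream special-cases fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._constants import COULOMB_MV_A, ELEMENT_RADII
from .builders import build_polymer, ideal_helix_backbone
from .structure_io import Atom, Structure, structure_to_pdb

PROBE = 1.4
_CARBON_R = ELEMENT_RADII["C"]


@dataclass
class ToySpec:
    """Declarative description of a toy structure.

    ``charges`` lists explicit (atom_index, charge_e) overrides for the
    electrostatics stages; geometric parameters live in ``params``.
    """

    kind: str  # single_sphere | dumbbell | helix | charge_lattice
    params: dict[str, Any] = field(default_factory=dict)
    charges: list[tuple[int, float]] = field(default_factory=list)
    seed: int | None = None


def _sphere_area(radius: float, probe: float = PROBE) -> float:
    return 4.0 * math.pi * (radius + probe) ** 2


def _coulomb_mv(q: float, d: float, eps_r: float = 78.4) -> float:
    return COULOMB_MV_A * q / (eps_r * d)


def _ca_atom(serial: int, seq: int, pos, resname: str = "ALA") -> Atom:
    return Atom(serial, "CA", "C", resname, "A", seq,
                np.asarray(pos, dtype=float), _CARBON_R)


def make_toy(spec: ToySpec) -> tuple[str, dict[str, Any]]:
    """Build the PDB text and the expected-values record for a spec."""
    if spec.kind == "single_sphere":
        return _make_single_sphere(spec)
    if spec.kind == "dumbbell":
        return _make_dumbbell(spec)
    if spec.kind == "helix":
        return _make_helix(spec)
    if spec.kind == "charge_lattice":
        return _make_charge_lattice(spec)
    raise ValueError(f"unknown toy kind {spec.kind!r}")


def _make_single_sphere(spec: ToySpec) -> tuple[str, dict]:
    charges = spec.charges or [(0, +1.0)]
    s = Structure([_ca_atom(1, 1, [0.0, 0.0, 0.0])])
    probe_points = np.array(spec.params.get("probe_points", [[10.0, 0.0, 0.0]]), float)
    expected = {
        "total_area": _sphere_area(_CARBON_R),
        "n_atoms": 1,
        "charges": charges,
        "probe_points": probe_points,
        # unscreened Coulomb values at the probe points (eps_r 78.4)
        "probe_potentials_mV": [
            sum(_coulomb_mv(q, float(np.linalg.norm(p - s.atoms[i].position)))
                for i, q in charges)
            for p in probe_points
        ],
        "patch_counts_uncharged": {"POS": 0, "NEG": 0, "HYD": 1},
    }
    return structure_to_pdb(s), expected


def _make_dumbbell(spec: ToySpec) -> tuple[str, dict]:
    d = float(spec.params.get("separation", 4.0))
    if d <= 0:
        raise ValueError("dumbbell separation must be positive")
    s = Structure([
        _ca_atom(1, 1, [0.0, 0.0, 0.0]),
        _ca_atom(2, 2, [d, 0.0, 0.0]),
    ])
    R = _CARBON_R + PROBE
    if d >= 2 * R:
        area = 2 * _sphere_area(_CARBON_R)
        n_components = 2
    else:
        # two equal intersecting spheres: each loses a cap of height R - d/2
        h = R - d / 2.0
        area = 2 * (4 * math.pi * R**2 - 2 * math.pi * R * h)
        n_components = 1
    expected = {
        "total_area": area,
        "n_atoms": 2,
        "charges": spec.charges,
        "n_connected_components": n_components,
        "patch_counts_uncharged": {"POS": 0, "NEG": 0, "HYD": n_components},
    }
    return structure_to_pdb(s), expected


def _make_helix(spec: ToySpec) -> tuple[str, dict]:
    n = int(spec.params.get("n_res", 20))
    subs: dict[int, str] = {int(k): v for k, v in spec.params.get("substitutions", {}).items()}
    seq = "".join(subs.get(i + 1, "A") for i in range(n))
    s = build_polymer(ideal_helix_backbone(n), seq)
    formal = {"K": 1, "R": 1, "D": -1, "E": -1}
    net = sum(formal.get(a, 0) for a in seq)  # termini add +1 and -1
    expected = {
        "n_res": n,
        "sequence": seq,
        "net_formal_charge": float(net),
        "n_chains": 1,
    }
    return structure_to_pdb(s), expected


def _make_charge_lattice(spec: ToySpec) -> tuple[str, dict]:
    n = int(spec.params.get("n_side", 3))
    spacing = float(spec.params.get("spacing", 8.0))
    atoms = []
    charges = []
    k = 0
    for i in range(n):
        for j in range(n):
            atoms.append(_ca_atom(k + 1, k + 1, [i * spacing, j * spacing, 0.0]))
            charges.append((k, 1.0 if (i + j) % 2 == 0 else -1.0))
            k += 1
    s = Structure(atoms)
    expected = {
        "n_atoms": n * n,
        "charges": charges,
        "net_charge": float(sum(q for _, q in charges)),
    }
    return structure_to_pdb(s), expected


def set_explicit_charges(s: Structure, charges: list[tuple[int, float]]) -> Structure:
    """Copy of a structure with charges set directly by atom index (used by
    the electrostatics fixtures; real structures use ``assign_charges``)."""
    out = s.copy()
    for a in out.atoms:
        a.charge = 0.0
    for i, q in charges:
        out.atoms[i].charge = float(q)
    return out
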