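"""In-silico sidechain replacement and systematic patch-mutation screening.

Mutations keep the backbone (N, CA, C, O — and CB where both residues have
one) fixed and rebuild the sidechain from the ideal residue geometry shipped
with biotite's chemical-component tables.  A small built-in rotamer set
(chi1/chi2 staggered plus perpendicular ring orientations) is scanned and
the rotamer with the fewest heavy-atom clashes against the rest of the
structure wins; ties break to library order, so results are deterministic.
No energy minimisation or backbone relaxation is attempted — formal charge
positions dominate the downstream electrostatics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import biotite.structure.info as bstinfo

from ._constants import AA1_TO_3, AA3_TO_1, DEFAULT_RADIUS, ELEMENT_RADII
from .geometry import dihedral, kabsch, rotation_about_axis
from .structure_io import Atom, Structure

CLASH_FACTOR = 0.7  # pair clash when d < 0.7 * (r_i + r_j)

BACKBONE_KEEP = ("N", "CA", "C", "O", "OXT")

# chi dihedral definitions: (quad atom names, atoms moved by this chi)
_CHI: dict[str, list[tuple[tuple[str, str, str, str], tuple[str, ...]]]] = {
    "ARG": [
        (("N", "CA", "CB", "CG"), ("CG", "CD", "NE", "CZ", "NH1", "NH2")),
        (("CA", "CB", "CG", "CD"), ("CD", "NE", "CZ", "NH1", "NH2")),
    ],
    "LYS": [
        (("N", "CA", "CB", "CG"), ("CG", "CD", "CE", "NZ")),
        (("CA", "CB", "CG", "CD"), ("CD", "CE", "NZ")),
    ],
    "GLU": [
        (("N", "CA", "CB", "CG"), ("CG", "CD", "OE1", "OE2")),
        (("CA", "CB", "CG", "CD"), ("CD", "OE1", "OE2")),
    ],
    "GLN": [
        (("N", "CA", "CB", "CG"), ("CG", "CD", "OE1", "NE2")),
        (("CA", "CB", "CG", "CD"), ("CD", "OE1", "NE2")),
    ],
    "MET": [
        (("N", "CA", "CB", "CG"), ("CG", "SD", "CE")),
        (("CA", "CB", "CG", "SD"), ("SD", "CE")),
    ],
    "ASP": [(("N", "CA", "CB", "CG"), ("CG", "OD1", "OD2"))],
    "ASN": [(("N", "CA", "CB", "CG"), ("CG", "OD1", "ND2"))],
    "LEU": [
        (("N", "CA", "CB", "CG"), ("CG", "CD1", "CD2")),
        (("CA", "CB", "CG", "CD1"), ("CD1", "CD2")),
    ],
    "ILE": [
        (("N", "CA", "CB", "CG1"), ("CG1", "CG2", "CD1")),
        (("CA", "CB", "CG1", "CD1"), ("CD1",)),
    ],
    "PHE": [
        (("N", "CA", "CB", "CG"), ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
        (("CA", "CB", "CG", "CD1"), ("CD1", "CD2", "CE1", "CE2", "CZ")),
    ],
    "TYR": [
        (("N", "CA", "CB", "CG"), ("CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH")),
        (("CA", "CB", "CG", "CD1"), ("CD1", "CD2", "CE1", "CE2", "CZ", "OH")),
    ],
    "TRP": [
        (
            ("N", "CA", "CB", "CG"),
            ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
        ),
        (
            ("CA", "CB", "CG", "CD1"),
            ("CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
        ),
    ],
    "HIS": [
        (("N", "CA", "CB", "CG"), ("CG", "ND1", "CD2", "CE1", "NE2")),
        (("CA", "CB", "CG", "ND1"), ("ND1", "CD2", "CE1", "NE2")),
    ],
    "SER": [(("N", "CA", "CB", "OG"), ("OG",))],
    "THR": [(("N", "CA", "CB", "OG1"), ("OG1", "CG2"))],
    "CYS": [(("N", "CA", "CB", "SG"), ("SG",))],
    "VAL": [(("N", "CA", "CB", "CG1"), ("CG1", "CG2"))],
}

_CHI1_ANGLES = (-60.0, 180.0, 60.0)
_CHI2_ANGLES = (-60.0, 180.0, 60.0, 90.0, -90.0)


@dataclass(frozen=True)
class MutationSpec:
    chain_id: str
    residue_seq: int
    wt_aa: str
    new_aa: str

    @classmethod
    def parse(cls, token: str, chain_id: str = "A") -> "MutationSpec":
        from .structure_io import SequenceEdit

        e = SequenceEdit.parse(token, chain_id)
        return cls(e.chain_id, e.residue_seq, e.wt_aa, e.new_aa)

    def __str__(self) -> str:  # e.g. "R150D"
        return f"{self.wt_aa}{self.residue_seq}{self.new_aa}"


@lru_cache(maxsize=32)
def residue_template(resname: str) -> tuple[tuple[str, ...], np.ndarray, tuple[str, ...]]:
    """Heavy-atom ideal geometry of a residue: (names, coords, elements)."""
    tmpl = bstinfo.residue(resname)
    if tmpl is None:
        raise KeyError(f"no ideal template for residue {resname}")
    mask = (tmpl.element != "H") & (tmpl.atom_name != "OXT")
    names = tuple(tmpl.atom_name[mask])
    coords = np.array(tmpl.coord[mask], dtype=float)
    elements = tuple(tmpl.element[mask])
    return names, coords, elements


def _set_chi(
    coords: dict[str, np.ndarray],
    quad: tuple[str, str, str, str],
    moving: tuple[str, ...],
    target_deg: float,
) -> None:
    a, b, c, d = (coords[n] for n in quad)
    current = dihedral(a, b, c, d)
    delta = np.deg2rad(target_deg) - current
    R = rotation_about_axis(c - b, delta)
    for name in moving:
        if name in coords:
            coords[name] = b + R @ (coords[name] - b)


def _clash_count(
    side: dict[str, np.ndarray],
    side_elements: dict[str, str],
    other_coords: np.ndarray,
    other_radii: np.ndarray,
) -> int:
    if len(other_coords) == 0:
        return 0
    n = 0
    for name, pos in side.items():
        r = ELEMENT_RADII.get(side_elements[name], DEFAULT_RADIUS)
        d = np.linalg.norm(other_coords - pos, axis=1)
        n += int(np.sum(d < CLASH_FACTOR * (r + other_radii)))
    return n


def mutate_sidechain(s: Structure, m: MutationSpec) -> Structure:
    """Replace one residue's sidechain, preserving the backbone exactly.

    Raises if the residue is absent, the wild-type letter does not match, or
    backbone atoms (N, CA, C) are missing.  Mutating a residue to itself is
    a no-op returning an identical copy.  If the input structure carried
    formal charges, charges are re-assigned (default charge model) on the
    result.
    """
    idxs = s.residue_atoms(m.chain_id, m.residue_seq)
    if not idxs:
        raise KeyError(f"no residue {m.chain_id}{m.residue_seq}")
    found = s.atoms[idxs[0]].residue_name
    found1 = AA3_TO_1.get(found, "X")
    if found1 != m.wt_aa:
        raise ValueError(
            f"wild-type mismatch at {m.chain_id}{m.residue_seq}: "
            f"expected {m.wt_aa}, structure has {found1} ({found})"
        )
    if m.new_aa == m.wt_aa:
        return s.copy()
    new3 = AA1_TO_3[m.new_aa]

    res_atoms = {s.atoms[i].name: i for i in idxs}
    for bb in ("N", "CA", "C"):
        if bb not in res_atoms:
            raise ValueError(
                f"residue {m.chain_id}{m.residue_seq} lacks backbone atom {bb}"
            )

    t_names, t_coords, t_elem = residue_template(new3)
    t_index = {n: i for i, n in enumerate(t_names)}
    bb_target = np.array([s.atoms[res_atoms[n]].position for n in ("N", "CA", "C")])
    bb_mobile = np.array([t_coords[t_index[n]] for n in ("N", "CA", "C")])
    R, t = kabsch(bb_mobile, bb_target)

    side_names = [n for n in t_names if n not in BACKBONE_KEEP]
    side = {n: R @ t_coords[t_index[n]] + t for n in side_names}
    side_elem = {n: t_elem[t_index[n]] for n in side_names}

    # keep the existing CB exactly when both residues have one
    ca = s.atoms[res_atoms["CA"]].position
    if "CB" in res_atoms and "CB" in side:
        v_new = side["CB"] - ca
        v_old = s.atoms[res_atoms["CB"]].position - ca
        axis = np.cross(v_new, v_old)
        if np.linalg.norm(axis) > 1e-8:
            ang = np.arccos(
                np.clip(
                    v_new @ v_old / (np.linalg.norm(v_new) * np.linalg.norm(v_old)),
                    -1.0,
                    1.0,
                )
            )
            Rc = rotation_about_axis(axis, ang)
            for n in side:
                side[n] = ca + Rc @ (side[n] - ca)
        side["CB"] = s.atoms[res_atoms["CB"]].position.copy()

    # rotamer scan against the rest of the structure
    chis = _CHI.get(new3, [])
    if chis:
        other = [a for i, a in enumerate(s.atoms) if i not in set(idxs)]
        other_coords = np.array([a.position for a in other]) if other else np.empty((0, 3))
        other_radii = np.array(
            [ELEMENT_RADII.get(a.element.upper(), DEFAULT_RADIUS) for a in other]
        )
        combos = (
            [(c1,) for c1 in _CHI1_ANGLES]
            if len(chis) == 1
            else [(c1, c2) for c1 in _CHI1_ANGLES for c2 in _CHI2_ANGLES]
        )
        coords_n = s.atoms[res_atoms["N"]].position
        best = None
        for combo in combos:
            trial = {n: p.copy() for n, p in side.items()}
            trial["N"] = coords_n
            trial["CA"] = ca
            for (quad, moving), ang in zip(chis, combo):
                if all(q in trial for q in quad):
                    _set_chi(trial, quad, moving, ang)
            trial_side = {n: trial[n] for n in side_names if n in trial}
            clashes = _clash_count(trial_side, side_elem, other_coords, other_radii)
            if best is None or clashes < best[0]:
                best = (clashes, trial_side)
            if best[0] == 0:
                break
        side = best[1]

    # assemble: original backbone atoms, then the new sidechain
    new_atoms: list[Atom] = []
    pos_in_res = set(idxs)
    insert_at = idxs[0]
    for i, a in enumerate(s.atoms):
        if i not in pos_in_res:
            new_atoms.append(a.copy())
            continue
        if i == insert_at:
            for bb in BACKBONE_KEEP:
                if bb in res_atoms:
                    old = s.atoms[res_atoms[bb]].copy()
                    old.residue_name = new3
                    new_atoms.append(old)
            for n in side_names:
                el = side_elem[n]
                new_atoms.append(
                    Atom(
                        serial=0,
                        name=n,
                        element=el,
                        residue_name=new3,
                        chain_id=m.chain_id,
                        residue_seq=m.residue_seq,
                        position=np.asarray(side[n], dtype=float).copy(),
                        radius=ELEMENT_RADII.get(el, DEFAULT_RADIUS),
                    )
                )
    for k, a in enumerate(new_atoms, start=1):
        a.serial = k
    out = Structure(new_atoms)

    if any(a.charge != 0.0 for a in s.atoms):
        from .structure_io import assign_charges

        out = assign_charges(out)
    return out


# ---------------------------------------------------------------------------
# systematic screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenRow:
    mutation: MutationSpec
    posQmax: float
    ratio: float
    prediction: str


@dataclass
class ScreenResult:
    baseline_ratio: float
    baseline_posQmax: float
    rows: list[ScreenRow] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "mutation": str(r.mutation),
                    "posQmax_A2": r.posQmax,
                    "ratio": r.ratio,
                    "prediction": r.prediction,
                }
                for r in self.rows
            ]
        )


_BASIC = {"K", "R"}
_ACIDIC = {"D", "E"}


def screen_candidates(structure: Structure, patch, mode: str) -> list[MutationSpec]:
    """Enumerate the single mutations a screening mode implies for a patch."""
    specs: list[MutationSpec] = []
    members = sorted(patch.member_residues)
    for cid, seq in members:
        idxs = structure.residue_atoms(cid, seq)
        if not idxs:
            continue
        aa = AA3_TO_1.get(structure.atoms[idxs[0]].residue_name, "X")
        if aa == "X":
            continue
        if mode == "basic_to_D" and aa in _BASIC:
            specs.append(MutationSpec(cid, seq, aa, "D"))
        elif mode == "any_to_D" and aa != "D":
            specs.append(MutationSpec(cid, seq, aa, "D"))
        elif mode == "acidic_to_basic" and aa in _ACIDIC:
            specs.append(MutationSpec(cid, seq, aa, "K"))
            specs.append(MutationSpec(cid, seq, aa, "R"))
    return specs


def screen_patch_mutations(
    structure: Structure, patch, mode: str, profile_fn
) -> ScreenResult:
    """Mutate every candidate in the patch and re-run the full pipeline.

    ``profile_fn`` maps a Structure to a SolubilityProfile (surface →
    potential → patches → ratio); the screen never shortcuts it, so even
    non-charge mutations that reshape the surface are handled correctly.
    Rows come back sorted by ratio, most solubilising first.
    """
    if mode not in ("basic_to_D", "any_to_D", "acidic_to_basic"):
        raise ValueError(f"unknown screening mode {mode!r}")
    specs = screen_candidates(structure, patch, mode)
    base = profile_fn(structure)
    result = ScreenResult(
        baseline_ratio=base.ratio, baseline_posQmax=base.posQmax
    )
    if not specs:
        warnings.warn(f"no candidates in patch for mode {mode}")
        return result
    for spec in specs:
        mutant = mutate_sidechain(structure, spec)
        prof = profile_fn(mutant)
        result.rows.append(
            ScreenRow(spec, prof.posQmax, prof.ratio, prof.prediction)
        )
    result.rows.sort(key=lambda r: (r.ratio, str(r.mutation)))
    return result
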