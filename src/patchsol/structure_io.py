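"""PDB structure reading/writing, sequence edits, and formal-charge assignment.

The in-memory model is intentionally small: an ordered list of heavy atoms
with coordinates, united-atom radii and formal charges on designated
charge-center atoms.  Parsing goes through gemmi; only ATOM records of
standard polymer residues are kept by default (waters, ligands and other
HETATM records are dropped), and alternate locations are resolved
deterministically to the highest-occupancy conformer (ties break to the
alphabetically first altloc).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from ._constants import (
    AA1_TO_3,
    AA3_TO_1,
    BACKBONE_ATOMS,
    CTERM_CHARGE,
    DEFAULT_RADIUS,
    DISULFIDE_SG_CUTOFF,
    ELEMENT_RADII,
    NTERM_CHARGE,
    SIDECHAIN_CHARGES,
)


class PDBParseError(ValueError):
    """Raised when a PDB text cannot be turned into a usable structure."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    position: np.ndarray  # (3,) Å
    radius: float = 0.0
    charge: float = 0.0

    def copy(self) -> "Atom":
        return replace(self, position=self.position.copy())


@dataclass
class Structure:
    """An ordered collection of atoms grouped into chains and residues."""

    atoms: list[Atom] = field(default_factory=list)

    # -- basic accessors ---------------------------------------------------
    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def net_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    def copy(self) -> "Structure":
        return Structure([a.copy() for a in self.atoms])

    # -- residue bookkeeping ----------------------------------------------
    def residues(self) -> list[tuple[str, int, str, list[int]]]:
        """Residues in atom order as (chain_id, residue_seq, residue_name,
        atom indices)."""
        out: list[tuple[str, int, str, list[int]]] = []
        key = None
        for i, a in enumerate(self.atoms):
            k = (a.chain_id, a.residue_seq)
            if k != key:
                out.append((a.chain_id, a.residue_seq, a.residue_name, [i]))
                key = k
            else:
                out[-1][3].append(i)
        return out

    def residue_atoms(self, chain_id: str, residue_seq: int) -> list[int]:
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.chain_id == chain_id and a.residue_seq == residue_seq
        ]

    def sequence(self, chain_id: str) -> str:
        """1-letter sequence of a chain (unknown residues become 'X')."""
        return "".join(
            AA3_TO_1.get(name, "X")
            for cid, _seq, name, _idx in self.residues()
            if cid == chain_id
        )

    def chain_termini(self, chain_id: str) -> tuple[tuple[int, str], tuple[int, str]]:
        """((first_seq, first_resname), (last_seq, last_resname)) of a chain."""
        rs = [(seq, name) for cid, seq, name, _ in self.residues() if cid == chain_id]
        if not rs:
            raise KeyError(f"no such chain: {chain_id!r}")
        return rs[0], rs[-1]


@dataclass(frozen=True)
class SequenceEdit:
    """A single point substitution, e.g. K24N on chain A."""

    chain_id: str
    residue_seq: int
    wt_aa: str
    new_aa: str

    @classmethod
    def parse(cls, token: str, chain_id: str = "A") -> "SequenceEdit":
        """Parse a token like ``K24N`` (1-letter codes, PDB numbering)."""
        token = token.strip()
        if len(token) < 3 or token[0] not in AA1_TO_3 or token[-1] not in AA1_TO_3:
            raise ValueError(f"cannot parse edit token {token!r}")
        try:
            seq = int(token[1:-1])
        except ValueError as exc:
            raise ValueError(f"cannot parse edit token {token!r}") from exc
        return cls(chain_id, seq, token[0], token[-1])

    @classmethod
    def parse_list(cls, tokens: str, chain_id: str = "A") -> list["SequenceEdit"]:
        """Parse a comma-separated list like ``K24N,K38N,K83N``."""
        return [cls.parse(t, chain_id) for t in tokens.split(",") if t.strip()]


@dataclass
class ChargeModel:
    """Formal charges at pH 7 placed on canonical charge-center atoms.

    ``sidechain`` maps residue name -> {atom name: charge}; free termini add
    +1 on the backbone N and -1 split over the carboxylate oxygens.
    """

    sidechain: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in SIDECHAIN_CHARGES.items()}
    )
    nterm: float = NTERM_CHARGE
    cterm: float = CTERM_CHARGE
    include_termini: bool = True


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

def load_structure(pdb_text: str, chain_filter: set[str] | None = None) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Waters and non-polymer HETATM records are excluded; alternate locations
    are resolved to the highest-occupancy conformer (ties -> first altloc in
    alphabetical order).  Unknown residue types are retained with a warning;
    they simply never receive charges.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise PDBParseError("no models in PDB text")
    model = st[0]

    atoms: list[Atom] = []
    unknown: set[str] = set()
    for chain in model:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for res in chain:
            if res.is_water():
                continue
            if res.het_flag == "H" and res.name not in AA3_TO_1:
                continue  # ligands / glycans are out of scope
            if res.name not in AA3_TO_1:
                unknown.add(res.name)
            # resolve altlocs: highest occupancy, ties to first altloc
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if (
                    prev is None
                    or at.occ > prev.occ + 1e-9
                    or (abs(at.occ - prev.occ) <= 1e-9 and (at.altloc or "~") < (prev.altloc or "~"))
                ):
                    best[at.name] = at
            for at in best.values():
                el = at.element.name.upper() if at.element else ""
                if el == "H":
                    continue  # united-atom model
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=el or at.name[:1],
                        residue_name=res.name,
                        chain_id=chain.name,
                        residue_seq=res.seqid.num,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    )
                )
    if not atoms:
        raise PDBParseError("no ATOM records (after filtering)")
    if unknown:
        warnings.warn(f"unknown residue types retained without charges: {sorted(unknown)}")
    s = Structure(atoms)
    assign_radii(s)
    return s


def structure_to_pdb(s: Structure) -> str:
    """Serialise a structure back to PDB-format text (ATOM/TER/END)."""
    lines = []
    serial = 0
    residues = s.residues()
    last_chain = None
    for chain_id, seq, name, idxs in residues:
        if last_chain is not None and chain_id != last_chain:
            lines.append("TER")
        last_chain = chain_id
        for i in idxs:
            a = s.atoms[i]
            serial += 1
            nm = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            x, y, z = a.position
            lines.append(
                f"ATOM  {serial:5d} {nm}{'':1s}{name:>3s} {chain_id:1s}{seq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def assign_radii(s: Structure) -> Structure:
    """Assign united-atom radii in place from the built-in element table."""
    for a in s.atoms:
        a.radius = ELEMENT_RADII.get(a.element.upper(), DEFAULT_RADIUS)
    return s


# ---------------------------------------------------------------------------
# sequence edits
# ---------------------------------------------------------------------------

def apply_sequence_edits(s: Structure, edits: list[SequenceEdit]) -> Structure:
    """Apply point substitutions by sidechain replacement.

    Each edit's ``wt_aa`` must match the residue actually present; a mismatch
    raises rather than silently re-applying.  Backbone atoms are untouched.
    """
    from .mutagenesis import MutationSpec, mutate_sidechain  # local: avoids cycle

    out = s
    for e in edits:
        out = mutate_sidechain(
            out, MutationSpec(e.chain_id, e.residue_seq, e.wt_aa, e.new_aa)
        )
    return out


# ---------------------------------------------------------------------------
# charges
# ---------------------------------------------------------------------------

def assign_charges(s: Structure, model: ChargeModel | None = None) -> Structure:
    """Return a copy with formal charges on designated charge-center atoms.

    All other atoms carry zero.  If a charged residue lacks its designated
    atoms (e.g. a truncated sidechain in a crystal structure) the full charge
    is placed on the sidechain atom closest to the sidechain centroid, with a
    warning.
    """
    model = model or ChargeModel()
    out = s.copy()
    for a in out.atoms:
        a.charge = 0.0

    index = {}
    for cid, seq, name, idxs in out.residues():
        index[(cid, seq)] = (name, idxs)
        spec = model.sidechain.get(name)
        if not spec:
            continue
        names = {out.atoms[i].name: i for i in idxs}
        missing = [an for an in spec if an not in names]
        if not missing:
            for an, q in spec.items():
                out.atoms[names[an]].charge += q
        else:
            side = [
                i for i in idxs
                if out.atoms[i].name not in BACKBONE_ATOMS
            ]
            total = sum(spec.values())
            if side:
                centroid = np.mean([out.atoms[i].position for i in side], axis=0)
                nearest = min(side, key=lambda i: np.linalg.norm(out.atoms[i].position - centroid))
                out.atoms[nearest].charge += total
                warnings.warn(
                    f"{name} {cid}{seq}: charge-center atom(s) {missing} missing; "
                    "charge placed on sidechain centroid"
                )
            else:
                warnings.warn(
                    f"{name} {cid}{seq}: no sidechain atoms; charge dropped"
                )

    if model.include_termini:
        for cid in out.chains:
            (first_seq, _), (last_seq, _) = out.chain_termini(cid)
            first_idx = out.residue_atoms(cid, first_seq)
            names = {out.atoms[i].name: i for i in first_idx}
            if "N" in names:
                out.atoms[names["N"]].charge += model.nterm
            last_idx = out.residue_atoms(cid, last_seq)
            names = {out.atoms[i].name: i for i in last_idx}
            oxys = [names[n] for n in ("O", "OXT") if n in names]
            if oxys:
                for i in oxys:
                    out.atoms[i].charge += model.cterm / len(oxys)
    return out


def find_disulfides(s: Structure) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Cysteine pairs whose SG atoms are closer than the disulfide cutoff."""
    sg = [
        (a.chain_id, a.residue_seq, a.position)
        for a in s.atoms
        if a.residue_name == "CYS" and a.name == "SG"
    ]
    pairs = []
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            if np.linalg.norm(sg[i][2] - sg[j][2]) < DISULFIDE_SG_CUTOFF:
                pairs.append(((sg[i][0], sg[i][1]), (sg[j][0], sg[j][1])))
    return pairs
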