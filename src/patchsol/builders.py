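"""Programmatic backbone construction for synthetic test structures.

Two builders are provided:

* :func:`ideal_helix_backbone` — a straight ideal alpha helix grown residue
  by residue with NeRF internal-coordinate placement (phi = -57, psi = -47).
* :func:`tube_backbone` — residues wound helically around an arbitrary
  smooth guide curve.  The per-residue cylindrical offsets of N/CA/C are
  measured once from the NeRF helix, so a straight guide reproduces an ideal
  helix and a curved guide yields a locally helical, self-avoiding tube.
  This is the workhorse for the synthetic four-helix-bundle models.

Sidechains are attached separately (see :func:`build_polymer`), reusing the
template + rotamer machinery of the mutagenesis module so the fixtures
exercise exactly the code paths real structures do.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from ._constants import AA1_TO_3, ELEMENT_RADII
from .geometry import fit_line, kabsch, place_atom
from .mutagenesis import MutationSpec, mutate_sidechain, residue_template
from .structure_io import Atom, Structure, assign_radii

# ideal backbone internal coordinates
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = np.deg2rad([111.2, 116.2, 121.7])
_A_CA_C_O = np.deg2rad(120.5)
HELIX_PHI, HELIX_PSI = -57.0, -47.0
HELIX_RISE, HELIX_TWIST = 1.5, np.deg2rad(100.0)


def ideal_helix_backbone(
    n_res: int, phi: float = HELIX_PHI, psi: float = HELIX_PSI
) -> list[dict[str, np.ndarray]]:
    """Backbone coordinates (N, CA, C, O; OXT on the last residue) of an
    ideal polypeptide with uniform phi/psi, grown by NeRF placement."""
    if n_res < 1:
        raise ValueError("need at least one residue")
    phi_r, psi_r = np.deg2rad(phi), np.deg2rad(psi)
    omega = np.pi

    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    c0 = ca0 + _B_CA_C * np.array(
        [np.cos(np.pi - _A_N_CA_C), np.sin(np.pi - _A_N_CA_C), 0.0]
    )
    res.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_res):
        prev = res[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi_r)
        ca = place_atom(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, omega)
        c = place_atom(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi_r)
        res.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens: trans to the next N (psi + pi)
    for i, r in enumerate(res):
        psi_eff = psi_r
        r["O"] = place_atom(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, psi_eff + np.pi)
        if i == n_res - 1:
            r["OXT"] = place_atom(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, psi_eff)
    return res


@lru_cache(maxsize=1)
def _helix_frame_offsets() -> dict[str, tuple[float, float, float]]:
    """Cylindrical offsets (d_phase rad, radius Å, d_z Å) of N, CA and C
    relative to the per-residue helical phase, measured from a NeRF helix."""
    bb = ideal_helix_backbone(15)
    cas = np.array([r["CA"] for r in bb])
    centroid, axis = fit_line(cas)
    # orthonormal frame about the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ axis) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    def cyl(p: np.ndarray) -> tuple[float, float, float]:
        v = p - centroid
        z = v @ axis
        x, y = v @ e1, v @ e2
        return float(np.arctan2(y, x)), float(np.hypot(x, y)), float(z)

    i = 7  # a middle residue, away from end effects
    base_phase, _, base_z = cyl(bb[i]["CA"])
    out = {}
    for name in ("N", "CA", "C"):
        ph, r, z = cyl(bb[i][name])
        dph = np.arctan2(np.sin(ph - base_phase), np.cos(ph - base_phase))
        out[name] = (float(dph), r, z - base_z)
    return out


def resample_polyline(points: np.ndarray, n: int) -> tuple[np.ndarray, float]:
    """n points evenly spaced by arclength along a polyline; returns
    (points, spacing)."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    t = np.linspace(0.0, total, n)
    out = np.column_stack([np.interp(t, s, points[:, k]) for k in range(3)])
    return out, total / max(1, n - 1)


def _transported_frames(guide: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parallel-transported orthonormal frames (T, E1, E2) along a polyline."""
    tangents = np.gradient(guide, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    e1 = np.empty_like(tangents)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(tangents[0] @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    v = ref - (ref @ tangents[0]) * tangents[0]
    e1[0] = v / np.linalg.norm(v)
    for i in range(1, len(guide)):
        v = e1[i - 1] - (e1[i - 1] @ tangents[i]) * tangents[i]
        nv = np.linalg.norm(v)
        e1[i] = v / nv if nv > 1e-9 else e1[i - 1]
    e2 = np.cross(tangents, e1)
    return tangents, e1, e2


def tube_backbone(
    waypoints: np.ndarray, n_res: int, phase0: float = 0.0
) -> list[dict[str, np.ndarray]]:
    """Backbone of ``n_res`` residues wound helically along a guide curve.

    The guide polyline is resampled to one point per residue; N, CA and C
    are placed at their ideal-helix cylindrical offsets in the transported
    local frame, so a straight guide gives ideal helix geometry.  Carbonyl
    O (and terminal OXT) are rebuilt by NeRF from the local backbone.
    """
    guide, _ = resample_polyline(np.asarray(waypoints, dtype=float), n_res)
    T, E1, E2 = _transported_frames(guide)
    offsets = _helix_frame_offsets()
    res: list[dict[str, np.ndarray]] = []
    for i in range(n_res):
        phase = phase0 + i * HELIX_TWIST
        r: dict[str, np.ndarray] = {}
        for name in ("N", "CA", "C"):
            dph, rad, dz = offsets[name]
            ang = phase + dph
            r[name] = (
                guide[i]
                + rad * (np.cos(ang) * E1[i] + np.sin(ang) * E2[i])
                + dz * T[i]
            )
        res.append(r)
    for i, r in enumerate(res):
        r["O"] = place_atom(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, np.pi / 2)
        if i == n_res - 1:
            r["OXT"] = place_atom(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, -np.pi / 2)
    return res


def backbone_to_structure(
    backbone: list[dict[str, np.ndarray]],
    chain_id: str = "A",
    start_seq: int = 1,
    resname: str = "ALA",
) -> Structure:
    """Turn backbone dicts into a poly-ALA (with template-aligned CB) or
    poly-GLY structure."""
    atoms: list[Atom] = []
    t_names, t_coords, _ = residue_template("ALA")
    t_idx = {n: i for i, n in enumerate(t_names)}
    serial = 0
    for i, r in enumerate(backbone):
        seq = start_seq + i
        entries = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
        if "OXT" in r:
            entries.append(("OXT", "O"))
        coords = dict(r)
        if resname != "GLY":
            R, t = kabsch(
                np.array([t_coords[t_idx[n]] for n in ("N", "CA", "C")]),
                np.array([r[n] for n in ("N", "CA", "C")]),
            )
            coords["CB"] = R @ t_coords[t_idx["CB"]] + t
            entries.insert(4, ("CB", "C"))
        for name, el in entries:
            serial += 1
            atoms.append(
                Atom(serial, name, el, resname, chain_id, seq,
                     np.asarray(coords[name], dtype=float).copy(),
                     ELEMENT_RADII[el])
            )
    return Structure(atoms)


def build_polymer(
    backbone: list[dict[str, np.ndarray]],
    sequence: str,
    chain_id: str = "A",
    start_seq: int = 1,
) -> Structure:
    """Thread a 1-letter sequence onto a backbone, building sidechains with
    the clash-minimising rotamer search."""
    if len(sequence) != len(backbone):
        raise ValueError("sequence length must match backbone length")
    s = backbone_to_structure(backbone, chain_id, start_seq)
    for i, aa in enumerate(sequence):
        if aa == "A":
            continue
        seq = start_seq + i
        if aa == "G":
            # drop the CB entirely
            idxs = s.residue_atoms(chain_id, seq)
            keep = [j for j in range(len(s.atoms))
                    if j not in idxs or s.atoms[j].name != "CB"]
            atoms = [s.atoms[j] for j in keep]
            for a in atoms:
                if a.chain_id == chain_id and a.residue_seq == seq:
                    a.residue_name = "GLY"
            s = Structure([a.copy() for a in atoms])
            continue
        if AA1_TO_3.get(aa) is None:
            raise ValueError(f"unknown amino acid {aa!r}")
        s = mutate_sidechain(s, MutationSpec(chain_id, seq, "A", aa))
    assign_radii(s)
    return s
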