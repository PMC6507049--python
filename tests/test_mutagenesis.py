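import numpy as np
import pytest

from patchsol.builders import build_polymer, ideal_helix_backbone
from patchsol.mutagenesis import (
    MutationSpec,
    mutate_sidechain,
    screen_candidates,
    screen_patch_mutations,
)
from patchsol.pipeline import RunConfig, compute_patches, make_profile_fn
from patchsol.structure_io import assign_charges


def backbone_coords(s, names=("N", "CA", "C", "O")):
    return {
        (a.chain_id, a.residue_seq, a.name): a.position
        for a in s.atoms
        if a.name in names
    }


class TestMutateSidechain:
    def test_identity_mutation_is_noop(self, helix_KDE):
        out = mutate_sidechain(helix_KDE, MutationSpec("A", 10, "K", "K"))
        np.testing.assert_array_equal(out.coords(), helix_KDE.coords())

    def test_backbone_preserved_exactly(self, helix_KDE):
        out = mutate_sidechain(helix_KDE, MutationSpec("A", 10, "K", "F"))
        bb_in, bb_out = backbone_coords(helix_KDE), backbone_coords(out)
        assert bb_in.keys() == bb_out.keys()
        for k in bb_in:
            np.testing.assert_array_equal(bb_in[k], bb_out[k])

    def test_shared_cb_preserved_exactly(self, helix_KDE):
        cb_in = [a.position for a in helix_KDE.atoms
                 if a.residue_seq == 10 and a.name == "CB"][0]
        out = mutate_sidechain(helix_KDE, MutationSpec("A", 10, "K", "R"))
        cb_out = [a.position for a in out.atoms
                  if a.residue_seq == 10 and a.name == "CB"][0]
        np.testing.assert_array_equal(cb_in, cb_out)

    @pytest.mark.parametrize(
        "token,delta",
        [("K10D", -2.0), ("K10N", -1.0), ("D14K", +2.0), ("E17Q", +1.0), ("A1R", +1.0)],
    )
    def test_charge_bookkeeping(self, helix_KDE, token, delta):
        base = assign_charges(helix_KDE).net_charge()
        out = assign_charges(
            mutate_sidechain(helix_KDE, MutationSpec.parse(token))
        )
        assert out.net_charge() - base == pytest.approx(delta)

    def test_wt_mismatch_and_missing_residue(self, helix_KDE):
        with pytest.raises(ValueError, match="expected R"):
            mutate_sidechain(helix_KDE, MutationSpec("A", 10, "R", "D"))
        with pytest.raises(KeyError):
            mutate_sidechain(helix_KDE, MutationSpec("A", 99, "K", "D"))

    def test_deterministic(self, helix_KDE):
        a = mutate_sidechain(helix_KDE, MutationSpec("A", 5, "A", "W"))
        b = mutate_sidechain(helix_KDE, MutationSpec("A", 5, "A", "W"))
        np.testing.assert_array_equal(a.coords(), b.coords())

    def test_new_sidechain_is_complete(self, helix_KDE):
        out = mutate_sidechain(helix_KDE, MutationSpec("A", 5, "A", "R"))
        names = {a.name for a in out.atoms if a.residue_seq == 5}
        assert {"N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"} <= names
        assert [a.residue_name for a in out.atoms if a.residue_seq == 5][0] == "ARG"

    def test_glycine_target_drops_sidechain(self, helix_KDE):
        out = mutate_sidechain(helix_KDE, MutationSpec("A", 5, "A", "G"))
        names = {a.name for a in out.atoms if a.residue_seq == 5}
        assert names == {"N", "CA", "C", "O"}

    def test_rotamer_avoids_clashes(self):
        # place a Lys in the tight core of a bundle of alanines: the chosen
        # rotamer must not be worse than every alternative
        s = build_polymer(ideal_helix_backbone(12), "A" * 12)
        out = mutate_sidechain(s, MutationSpec("A", 6, "A", "K"))
        assert len(out.atoms) == len(s.atoms) + 4  # CG, CD, CE, NZ added

    def test_order_invariance_of_double_mutant(self, helix_KDE):
        ab = mutate_sidechain(
            mutate_sidechain(helix_KDE, MutationSpec.parse("K10D")),
            MutationSpec.parse("D14K"),
        )
        ba = mutate_sidechain(
            mutate_sidechain(helix_KDE, MutationSpec.parse("D14K")),
            MutationSpec.parse("K10D"),
        )
        assert [a.name for a in ab.atoms] == [a.name for a in ba.atoms]
        np.testing.assert_allclose(ab.coords(), ba.coords(), atol=1e-9)


@pytest.fixture(scope="module")
def patchy_helix():
    # K10 and K11 adjacent: a single positive patch with two basics
    seq = list("A" * 18)
    seq[9], seq[10], seq[2] = "K", "K", "D"
    s = build_polymer(ideal_helix_backbone(18), "".join(seq))
    cfg = RunConfig(dots_per_atom=128, threshold=100.0)
    out = compute_patches(s, cfg)
    return s, out.patches, cfg


class TestScreen:
    def test_candidate_enumeration_counts_basics(self, patchy_helix):
        s, patches, _ = patchy_helix
        patch = patches.largest("POS")
        assert patch is not None
        cands = screen_candidates(s, patch, "basic_to_D")
        in_patch_basics = {
            seq for _, seq in patch.member_residues
            if s.atoms[s.residue_atoms("A", seq)[0]].residue_name in ("LYS", "ARG")
        }
        assert {c.residue_seq for c in cands} == in_patch_basics
        assert all(c.new_aa == "D" for c in cands)

    def test_rows_match_independent_pipeline_rerun(self, patchy_helix):
        s, patches, cfg = patchy_helix
        patch = patches.largest("POS")
        fn = make_profile_fn(cfg)
        res = screen_patch_mutations(s, patch, "basic_to_D", fn)
        assert len(res.rows) >= 1
        ratios = [r.ratio for r in res.rows]
        assert ratios == sorted(ratios)
        for row in res.rows:
            redo = fn(mutate_sidechain(s, row.mutation))
            assert row.ratio == pytest.approx(redo.ratio)

    def test_empty_candidate_set_warns(self, patchy_helix):
        s, patches, cfg = patchy_helix
        patch = patches.largest("POS")
        with pytest.warns(UserWarning):
            res = screen_patch_mutations(
                s, patch, "acidic_to_basic", make_profile_fn(cfg)
            )
        assert res.rows == []

    def test_unknown_mode_rejected(self, patchy_helix):
        s, patches, cfg = patchy_helix
        with pytest.raises(ValueError):
            screen_patch_mutations(
                s, patches.largest("POS"), "nonsense", make_profile_fn(cfg)
            )
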