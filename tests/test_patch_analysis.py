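import numpy as np
import pytest

from patchsol.patch_analysis import (
    HYD,
    NEG,
    POS,
    PatchSolubilityClassifier,
    calibrate_threshold,
    segment_patches,
    solubility_profile,
)
from patchsol.structure_io import Atom, Structure
from patchsol.surface_mesh import build_dot_surface, link_neighbours

from _oracles import brute_force_patches, brute_force_threshold


def sphere_surface(dots=256):
    s = Structure([Atom(1, "CA", "C", "ALA", "A", 1, np.zeros(3), 1.9)])
    return link_neighbours(build_dot_surface(s, 1.4, dots))


class TestSegmentation:
    def test_uniform_zero_field_is_one_hyd_patch(self):
        surf = sphere_surface()
        ps = segment_patches(surf, np.zeros(surf.n_dots))
        assert ps.posQmax == 0.0 and ps.negQmax == 0.0
        assert len(ps.patches) == 1
        assert ps.patches[0].sign_class == HYD
        assert ps.hydmax == pytest.approx(surf.total_area)

    def test_hemisphere_patch_is_half_the_sphere(self):
        surf = sphere_surface(512)
        field = np.where(surf.positions[:, 2] > 0, 30.0, 0.0)
        ps = segment_patches(surf, field)
        pos = [p for p in ps.patches if p.sign_class == POS]
        assert len(pos) == 1
        assert ps.posQmax == pytest.approx(surf.total_area / 2, rel=0.02)

    def test_partition_covers_total_area(self):
        surf = sphere_surface()
        rng = np.random.default_rng(3)
        field = rng.normal(scale=40, size=surf.n_dots)
        ps = segment_patches(surf, field)
        assert sum(p.area for p in ps.patches) == pytest.approx(surf.total_area)
        idx = np.concatenate([p.dot_indices for p in ps.patches])
        assert len(idx) == surf.n_dots and len(np.unique(idx)) == surf.n_dots

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_components(self, seed):
        surf = sphere_surface(128)
        rng = np.random.default_rng(seed)
        field = rng.normal(scale=35, size=surf.n_dots)
        ps = segment_patches(surf, field)
        labels = np.zeros(surf.n_dots, dtype=int)
        labels[field > 25] = 1
        labels[field < -25] = -1
        oracle = brute_force_patches(
            surf.positions, surf.areas, labels, surf.link_distance
        )
        ours = {frozenset(int(i) for i in p.dot_indices) for p in ps.patches}
        assert ours == {c for _, c in oracle}

    def test_sign_class_membership_invariant(self):
        surf = sphere_surface(128)
        rng = np.random.default_rng(7)
        field = rng.normal(scale=35, size=surf.n_dots)
        ps = segment_patches(surf, field)
        for p in ps.patches:
            vals = field[p.dot_indices]
            if p.sign_class == POS:
                assert (vals > 25).all()
            elif p.sign_class == NEG:
                assert (vals < -25).all()
            else:
                assert ((vals >= -25) & (vals <= 25)).all()

    def test_missing_graph_raises(self):
        s = Structure([Atom(1, "CA", "C", "ALA", "A", 1, np.zeros(3), 1.9)])
        surf = build_dot_surface(s, 1.4, 64)
        with pytest.raises(ValueError):
            segment_patches(surf, np.zeros(surf.n_dots))

    def test_member_residue_attribution(self, helix_KDE_charged):
        from patchsol.pipeline import RunConfig, compute_patches

        out = compute_patches(helix_KDE_charged, RunConfig(dots_per_atom=64))
        covered = set().union(*(p.member_residues for p in out.patches.patches))
        # every residue with at least one exposed dot appears somewhere
        parents = {helix_KDE_charged.atoms[i].residue_seq for i in out.surface.parent_atom}
        assert {seq for _, seq in covered} == parents


class TestProfile:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(1.49, "insoluble"), (0.47, "soluble"), (1.0, "soluble"), (1.0001, "insoluble")],
    )
    def test_prediction_rule(self, ratio, expected):
        from patchsol.patch_analysis import PatchSet

        ps = PatchSet([], posQmax=ratio * 100.0, negQmax=0, hydmax=0, total_area=0)
        prof = solubility_profile(ps, 100.0)
        assert prof.ratio == pytest.approx(ratio)
        assert prof.prediction == expected

    def test_rescaling_invariance(self):
        from patchsol.patch_analysis import PatchSet

        ps1 = PatchSet([], posQmax=120.0, negQmax=0, hydmax=0, total_area=0)
        ps2 = PatchSet([], posQmax=360.0, negQmax=0, hydmax=0, total_area=0)
        assert (
            solubility_profile(ps1, 100.0).prediction
            == solubility_profile(ps2, 300.0).prediction
        )

    def test_bad_threshold(self):
        from patchsol.patch_analysis import PatchSet

        ps = PatchSet([], posQmax=1.0, negQmax=0, hydmax=0, total_area=0)
        with pytest.raises(ValueError):
            solubility_profile(ps, 0.0)


class TestCalibration:
    def test_perfect_separation(self):
        data = [(10, "soluble"), (20, "soluble"), (30, "insoluble"), (40, "insoluble")]
        cal = calibrate_threshold(data)
        assert cal.threshold == pytest.approx(25.0)
        assert cal.balanced_accuracy == 1.0

    def test_inverted_labels_report_chance_with_warning(self):
        with pytest.warns(UserWarning):
            cal = calibrate_threshold([(10, "insoluble"), (20, "soluble")])
        assert cal.balanced_accuracy == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(5, 100, size=12).astype(float)
        labels = rng.choice(["soluble", "insoluble"], size=12)
        if len(set(labels)) < 2:
            labels[0] = "soluble"
            labels[1] = "insoluble"
        data = list(zip(sizes, labels))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cal = calibrate_threshold(data)
        _, best_acc = brute_force_threshold(data)
        assert cal.balanced_accuracy == pytest.approx(best_acc)

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold([(10, "soluble"), (20, "soluble")])


class TestClassifier:
    def test_fit_predict(self):
        X = [[10.0], [20.0], [30.0], [40.0]]
        y = ["soluble", "soluble", "insoluble", "insoluble"]
        clf = PatchSolubilityClassifier().fit(X, y)
        assert clf.threshold_ == pytest.approx(25.0)
        assert list(clf.predict([[5.0], [99.0]])) == ["soluble", "insoluble"]
        assert clf.score(X, y) == 1.0

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        clf = PatchSolubilityClassifier()
        assert clone(clf).get_params() == clf.get_params()

    def test_unfitted_predict_raises(self):
        with pytest.raises(ValueError):
            PatchSolubilityClassifier().predict([[1.0]])
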