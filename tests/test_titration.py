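import numpy as np
import pytest

from patchsol._constants import GAS_CONSTANT_KJ
from patchsol.builders import build_polymer, ideal_helix_backbone
from patchsol.electrostatics import ElectrostaticParams, interaction_matrix
from patchsol.titration import (
    TitratableSite,
    build_site_model,
    ph_stability,
    ph_stability_for_structure,
    titrate_exact,
    titrate_ideal,
    titrate_mc,
)

from _oracles import four_state_partition

RT = GAS_CONSTANT_KJ * 298.15
GRID = np.arange(0.0, 14.01, 0.5)


def acid(seq, pos, pka=4.0):
    return TitratableSite("A", seq, "ASP", np.asarray(pos, float), pka)


def base(seq, pos, pka=10.4):
    return TitratableSite("A", seq, "LYS", np.asarray(pos, float), pka)


def random_system(seed, n_max=12):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    pk = {"ASP": 4.0, "GLU": 4.4, "HIS": 6.3, "LYS": 10.4, "ARG": 12.0, "TYR": 9.6}
    types = rng.choice(list(pk), size=n)
    pos = rng.normal(size=(n, 3)) * 7
    from scipy.spatial.distance import pdist

    while n > 1 and pdist(pos).min() < 1.0:
        pos = rng.normal(size=(n, 3)) * 7
    sites = [TitratableSite("A", i, t, pos[i], pk[t]) for i, t in enumerate(types)]
    return sites, interaction_matrix(pos, ElectrostaticParams())


class TestExact:
    def test_single_acid_henderson_hasselbalch(self):
        sites = [acid(1, [0, 0, 0])]
        r = titrate_exact(sites, np.zeros((1, 1)), GRID)
        expected = 1.0 / (1.0 + 10.0 ** (GRID - 4.0))
        np.testing.assert_allclose(r.fractions[:, 0], expected, atol=1e-12)
        assert r.fractions[GRID == 4.0, 0] == pytest.approx(0.5)

    def test_distant_sites_titrate_independently(self):
        sites = [acid(1, [0, 0, 0]), base(2, [80.0, 0, 0])]
        W = interaction_matrix(np.array([[0, 0, 0], [80.0, 0, 0.0]]), ElectrostaticParams())
        r = titrate_exact(sites, W, GRID)
        ideal = titrate_ideal(sites, GRID)
        np.testing.assert_allclose(r.fractions, ideal.fractions, atol=1e-3)

    def test_coupled_pair_matches_hand_partition_function(self):
        w = 5.0  # kJ/mol between the two deprotonated acids
        sites = [acid(1, [0, 0, 0], 4.0), acid(2, [4.0, 0, 0], 4.4)]
        W = np.array([[0.0, w], [w, 0.0]])
        r = titrate_exact(sites, W, GRID)
        for k, pH in enumerate(GRID):
            f1, f2, g = four_state_partition(4.0, 4.4, w, pH, RT)
            assert r.fractions[k, 0] == pytest.approx(f1, abs=1e-10)
            assert r.fractions[k, 1] == pytest.approx(f2, abs=1e-10)
            assert r.G[k] == pytest.approx(g, abs=1e-9)

    def test_refuses_oversized_systems(self):
        sites = [acid(i, [3.0 * i, 0, 0]) for i in range(21)]
        with pytest.raises(ValueError):
            titrate_exact(sites, np.zeros((21, 21)), GRID)

    def test_mean_charge_monotone_for_noninteracting(self):
        sites = [acid(1, [0, 0, 0]), base(2, [50, 0, 0]), acid(3, [0, 50, 0], 9.0)]
        r = titrate_exact(sites, np.zeros((3, 3)), GRID)
        assert (np.diff(r.mean_charge) <= 1e-12).all()


class TestMonteCarlo:
    def test_noninteracting_matches_henderson_hasselbalch(self):
        sites = [acid(1, [0, 0, 0]), base(2, [50.0, 0, 0])]
        r = titrate_mc(sites, np.zeros((2, 2)), GRID, sweeps=10_000, seed=3)
        ideal = titrate_ideal(sites, GRID)
        assert np.abs(r.fractions - ideal.fractions).max() < 0.01

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exact_enumeration(self, seed):
        sites, W = random_system(seed)
        ex = titrate_exact(sites, W, GRID)
        mc = titrate_mc(sites, W, GRID, sweeps=10_000, seed=seed)
        assert np.abs(ex.fractions - mc.fractions).max() < 0.01

    def test_same_seed_bit_identical(self):
        sites, W = random_system(5)
        a = titrate_mc(sites, W, GRID, sweeps=2000, seed=11)
        b = titrate_mc(sites, W, GRID, sweeps=2000, seed=11)
        np.testing.assert_array_equal(a.fractions, b.fractions)
        np.testing.assert_array_equal(a.G, b.G)

    def test_free_energy_from_charge_integration_matches_exact(self):
        sites, W = random_system(8)
        fine = np.arange(0.0, 14.01, 0.25)
        ex = titrate_exact(sites, W, fine)
        mc = titrate_mc(sites, W, fine, sweeps=10_000, seed=4)
        assert np.abs(ex.G - mc.G).max() < 0.5  # kJ/mol, integration + MC error


class TestSiteModel:
    def test_site_census_on_peptide(self):
        s = build_polymer(ideal_helix_backbone(9), "ADEHKRYCA")
        sites, W = build_site_model(s)
        kinds = sorted(st.site_type for st in sites)
        assert kinds == sorted(
            ["ASP", "GLU", "HIS", "LYS", "ARG", "TYR", "CYS", "NTERM", "CTERM"]
        )
        assert W.shape == (9, 9)
        np.testing.assert_array_equal(W, W.T)
        np.testing.assert_array_equal(np.diag(W), 0.0)

    def test_disulfide_cys_excluded(self):
        s = build_polymer(ideal_helix_backbone(8), "ACAAAACA")
        sg = [a for a in s.atoms if a.name == "SG"]
        sg[1].position = sg[0].position + np.array([2.0, 0.0, 0.0])
        sites, _ = build_site_model(s)
        assert all(st.site_type != "CYS" for st in sites)

    def test_like_charge_pair_interaction_positive(self):
        s = build_polymer(ideal_helix_backbone(6), "ADADAA")
        sites, W = build_site_model(s)
        i, j = [k for k, st in enumerate(sites) if st.site_type == "ASP"]
        assert W[i, j] > 0  # (-1)(-1) W > 0: like-charge repulsion


class TestPHStability:
    def test_identical_models_give_zero(self):
        sites = [acid(1, [0, 0, 0]), base(2, [4.0, 0, 0])]
        f = titrate_exact(sites, np.zeros((2, 2)), GRID)
        u = titrate_ideal(sites, GRID)
        assert ph_stability(f, u, 7.0).phstab == pytest.approx(0.0, abs=1e-9)

    def test_salt_bridge_stabilises(self):
        sites = [acid(1, [0, 0, 0]), base(2, [4.0, 0, 0])]
        W = interaction_matrix(np.array([[0, 0, 0], [4.0, 0, 0.0]]), ElectrostaticParams())
        f = titrate_exact(sites, W, GRID)
        u = titrate_ideal(sites, GRID)
        assert ph_stability(f, u, 7.0).phstab < 0

    def test_like_charge_pair_destabilises(self):
        sites = [base(1, [0, 0, 0]), base(2, [4.0, 0, 0])]
        W = interaction_matrix(np.array([[0, 0, 0], [4.0, 0, 0.0]]), ElectrostaticParams())
        f = titrate_exact(sites, W, GRID)
        u = titrate_ideal(sites, GRID)
        assert ph_stability(f, u, 7.0).phstab > 0

    def test_mismatched_grids_rejected(self):
        sites = [acid(1, [0, 0, 0])]
        f = titrate_exact(sites, np.zeros((1, 1)), GRID)
        u = titrate_ideal(sites, GRID[:-1])
        with pytest.raises(ValueError):
            ph_stability(f, u)

    def test_structure_wrapper_runs_exact_for_small_systems(self, helix_KDE_charged):
        stab, folded, unfolded = ph_stability_for_structure(
            helix_KDE_charged, pH_grid=GRID, seed=0
        )
        assert folded.method == "exact"
        assert np.isfinite(stab.phstab)
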