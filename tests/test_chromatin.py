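import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import rankdata, spearmanr

from neo3d import chromatin, synthetic
from neo3d.chromatin import (
    ActivityProfile,
    ContactMatrix,
    ReconstructionConfig,
    assign_radial_targets,
    bead_lookup,
    compartment_degree,
    read_contact_maps,
    read_structure,
    reconstruct,
    write_contact_maps,
    write_structure,
)


def checkerboard4():
    """Two 2-bin blocks, within-block counts 10, between-block 1."""
    m = np.array(
        [
            [0.0, 10, 1, 1],
            [10, 0, 1, 1],
            [1, 1, 0, 10],
            [1, 1, 10, 0],
        ]
    )
    return ContactMatrix("chr1", 500_000, m)


def two_block(n=40, enrichment=3.0):
    i = np.arange(n)
    decay = 100.0 / (1.0 + np.abs(i[:, None] - i[None, :]))
    same = (i[:, None] < n // 2) == (i[None, :] < n // 2)
    m = decay * np.where(same, enrichment, 1.0)
    np.fill_diagonal(m, 0.0)
    return ContactMatrix("chr1", 500_000, (m + m.T) / 2)


class TestCompartmentDegree:
    def test_checkerboard_splits_blocks(self):
        act = compartment_degree(checkerboard4()).activity
        signs = np.sign(act)
        assert signs[0] == signs[1] != 0
        assert signs[2] == signs[3] != 0
        assert signs[0] == -signs[2]

    def test_marker_orients_sign(self):
        cm = checkerboard4()
        act = compartment_degree(cm, marker=np.array([1.0, 1, 0, 0])).activity
        assert act[0] > 0 and act[1] > 0 and act[2] < 0
        flipped = compartment_degree(cm, marker=np.array([0.0, 0, 1, 1])).activity
        np.testing.assert_allclose(flipped, -act, atol=1e-12)

    def test_constant_matrix_gives_zero_activity(self):
        m = np.ones((5, 5)) - np.eye(5)
        act = compartment_degree(ContactMatrix("chr1", 500_000, m)).activity
        np.testing.assert_array_equal(act, np.zeros(5))

    def test_count_scale_invariance(self):
        cm = two_block()
        a1 = compartment_degree(cm).activity
        a2 = compartment_degree(
            ContactMatrix("chr1", 500_000, cm.counts * 10.0)
        ).activity
        np.testing.assert_allclose(a1, a2, atol=1e-10)

    def test_all_zero_matrix_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            compartment_degree(ContactMatrix("chr1", 500_000, np.zeros((4, 4))))

    def test_zero_variance_bins_get_zero_activity(self):
        cm = two_block(n=20)
        counts = cm.counts.copy()
        counts[5, :] = 0.0
        counts[:, 5] = 0.0
        act = compartment_degree(ContactMatrix("chr1", 500_000, counts)).activity
        assert act[5] == 0.0
        assert np.count_nonzero(act) >= 18


class TestRadialTargets:
    def test_extreme_activities_map_to_extreme_radii(self):
        prof = ActivityProfile("chr1", np.array([0.0, 0.5, 1.0]))
        out = assign_radial_targets(prof, nucleus_radius=1.0, min_radius_frac=0.1)
        assert out.radial_target[2] == pytest.approx(0.1)  # most active: centre
        assert out.radial_target[0] == pytest.approx(1.0)  # least active: periphery

    def test_tied_activities_share_mean_rank(self):
        prof = ActivityProfile("chr1", np.zeros(4))
        out = assign_radial_targets(prof, nucleus_radius=1.0, min_radius_frac=0.1)
        np.testing.assert_allclose(out.radial_target, 0.55)

    def test_targets_monotone_in_activity(self, rng):
        act = rng.normal(size=30)
        out = assign_radial_targets(ActivityProfile("chr1", act), 10.0)
        order = np.argsort(act)
        assert np.all(np.diff(out.radial_target[order]) <= 1e-12)
        assert np.all(out.radial_target <= 10.0)


def two_bead_oracle(k_bond, k_radial, bond, target):
    """Independent numerical minimiser of the 2-bead potential."""

    def U(flat):
        a, b = flat[:3], flat[3:]
        d = np.linalg.norm(a - b)
        return (
            k_bond * (d - bond) ** 2
            + k_radial * (np.linalg.norm(a) - target) ** 2
            + k_radial * (np.linalg.norm(b) - target) ** 2
        )

    best = None
    for s in range(5):
        x0 = np.random.default_rng(s).normal(size=6)
        res = minimize(U, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
    return best


class TestReconstruct:
    def test_two_bead_minimum_matches_numerical_oracle(self):
        cm = ContactMatrix("chr1", 500_000, np.array([[0.0, 1.0], [1.0, 0.0]]))
        prof = ActivityProfile("chr1", np.zeros(2), radial_target=np.array([0.5, 0.5]))
        cfg = ReconstructionConfig(k_repulsion=0.0, n_steps=3000, seed=4)
        st = reconstruct([cm], [prof], cfg, nucleus_radius=1.0)
        X = st.chains["chr1"]
        d = np.linalg.norm(X[1] - X[0])
        r = np.linalg.norm(X, axis=1)
        assert 0.95 <= d <= 1.05
        assert np.all((r >= 0.45) & (r <= 0.55))
        oracle = two_bead_oracle(100.0, 10.0, 1.0, 0.5)
        assert oracle.fun == pytest.approx(0.0, abs=1e-6)  # constraints are satisfiable
        assert st.diagnostics["energy"]["total"] <= oracle.fun + 0.05

    def test_bond_only_relaxation(self):
        n = 20
        cm = ContactMatrix("chr1", 500_000, np.ones((n, n)) - np.eye(n))
        prof = ActivityProfile("chr1", np.zeros(n), radial_target=np.full(n, 3.0))
        cfg = ReconstructionConfig(k_radial=0.0, k_repulsion=0.0, n_steps=2500, seed=2)
        st = reconstruct([cm], [prof], cfg, nucleus_radius=8.0)
        bl = np.linalg.norm(np.diff(st.chains["chr1"], axis=0), axis=1)
        rms = np.sqrt(np.mean((bl - 1.0) ** 2))
        assert rms < 0.05

    def test_seeded_determinism(self):
        cm = two_block(n=15)
        prof = assign_radial_targets(compartment_degree(cm), 5.0)
        cfg = ReconstructionConfig(n_steps=300, seed=11)
        a = reconstruct([cm], [prof], cfg, nucleus_radius=5.0)
        b = reconstruct([cm], [prof], cfg, nucleus_radius=5.0)
        np.testing.assert_array_equal(a.chains["chr1"], b.chains["chr1"])

    def test_best_energy_monotone_across_checkpoints(self):
        cm = two_block(n=15)
        prof = assign_radial_targets(compartment_degree(cm), 5.0)
        st = reconstruct(
            [cm], [prof], ReconstructionConfig(n_steps=500, seed=1), nucleus_radius=5.0
        )
        hist = st.diagnostics["best_history"]
        assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(hist, hist[1:]))

    def test_radial_fidelity_with_smooth_activity(self):
        n = 50
        act = np.sin(2 * np.pi * np.arange(n) / 25)
        cm = ContactMatrix("chr1", 500_000, np.ones((n, n)) - np.eye(n))
        prof = assign_radial_targets(ActivityProfile("chr1", act), 10.0)
        st = reconstruct(
            [cm], [prof], ReconstructionConfig(n_steps=3000, seed=5), nucleus_radius=10.0
        )
        rho = spearmanr(st.radii("chr1"), prof.radial_target).statistic
        assert rho >= 0.9

    def test_mismatched_profiles_rejected(self):
        cm = two_block(n=10)
        prof = ActivityProfile("chr2", np.zeros(10))
        with pytest.raises(ValueError, match="mismatch"):
            reconstruct([cm], [prof], ReconstructionConfig(n_steps=10, seed=0))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ReconstructionConfig(k_bond=-1.0)
        with pytest.raises(ValueError):
            ReconstructionConfig(n_steps=0)


class TestBeadLookup:
    def test_radius_is_euclidean_norm(self):
        st = chromatin.GenomeStructure(
            cell_line="t",
            chains={"chr1": np.array([[0.3, 0.0, 0.4], [0.0, 0.0, 0.0]])},
            nucleus_radius=1.0,
            bin_size_bp=500_000,
        )
        assert bead_lookup(st, "chr1", 0) == pytest.approx((0.3, 0.0, 0.4, 0.5))
        assert bead_lookup(st, "chr1", 1)[3] == 0.0

    def test_out_of_range_bin_error(self):
        st = chromatin.GenomeStructure(
            cell_line="t",
            chains={"chr1": np.zeros((2, 3))},
            nucleus_radius=1.0,
            bin_size_bp=500_000,
        )
        with pytest.raises(IndexError, match="chr1"):
            bead_lookup(st, "chr1", 2)
        with pytest.raises(KeyError, match="chr5"):
            bead_lookup(st, "chr5", 0)


class TestIO:
    def test_contact_map_roundtrip(self, world, tmp_path):
        maps = next(iter(world.contact_maps.values()))
        path = tmp_path / "maps.tsv"
        write_contact_maps(maps, path)
        back = read_contact_maps(path, world.bin_size_bp)
        assert [cm.chromosome for cm in back] == [cm.chromosome for cm in maps]
        for a, b in zip(maps, back):
            np.testing.assert_array_equal(a.counts, b.counts)

    def test_structure_roundtrip(self, world, tmp_path):
        st = next(iter(world.structures.values()))
        path = tmp_path / "st.tsv"
        write_structure(st, path)
        back = read_structure(path, st.nucleus_radius, st.bin_size_bp)
        assert back.cell_line == st.cell_line
        for chrom in st.chromosomes:
            np.testing.assert_allclose(back.chains[chrom], st.chains[chrom], atol=1e-6)

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ContactMatrix("chr1", 500_000, m)
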