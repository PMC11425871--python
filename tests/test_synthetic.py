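import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from neo3d import synthetic
from neo3d.baseline import DEFAULT_SCORER, SurrogateScorer
from neo3d.chromatin import GenomeStructure
from neo3d.synthetic import (
    EffectParams,
    expected_contacts,
    gen_contact_map,
    gen_gene_table,
    gen_peptide_dataset,
    gen_structure,
)


class TestScorer:
    def test_score_bounded_and_deterministic(self):
        peps = ["ACDEFGHIKLM", "WWWWWWWWWWW", "KLMNPQRSTVWYA"]
        s1 = DEFAULT_SCORER.score_many(peps)
        s2 = SurrogateScorer().score_many(peps)
        assert np.all((s1 >= 0) & (s1 <= 1))
        np.testing.assert_array_equal(s1, s2)

    def test_score_uses_central_core(self):
        # flanking residues outside the central 9-mer must not matter
        assert DEFAULT_SCORER.score("AAAA" + "CDEFGHIKL" + "AAAA") == DEFAULT_SCORER.score(
            "WWWW" + "CDEFGHIKL" + "WWWW"
        )

    def test_short_peptide_rejected(self):
        with pytest.raises(ValueError):
            DEFAULT_SCORER.score("ACDEFGH")


class TestGenStructure:
    def test_two_beads_exact_bond_length(self):
        st = gen_structure(1, 2, 1.0, 5.0, seed=7)
        chain = st.chains["chr1"]
        assert np.linalg.norm(chain[1] - chain[0]) == pytest.approx(1.0)

    def test_confinement(self):
        st = gen_structure(2, 50, 0.5, 5.0, seed=1)
        for chrom in st.chromosomes:
            assert st.radii(chrom).max() <= 5.0

    def test_bond_lengths_exact_along_chain(self):
        st = gen_structure(1, 40, 0.7, 6.0, seed=3)
        bl = np.linalg.norm(np.diff(st.chains["chr1"], axis=0), axis=1)
        np.testing.assert_allclose(bl, 0.7, rtol=1e-12)

    def test_seed_determinism(self):
        a = gen_structure(2, 50, 0.5, 5.0, seed=1)
        b = gen_structure(2, 50, 0.5, 5.0, seed=1)
        for chrom in a.chromosomes:
            np.testing.assert_array_equal(a.chains[chrom], b.chains[chrom])

    @pytest.mark.parametrize(
        "args",
        [
            (0, 10, 1.0, 5.0),
            (1, 1, 1.0, 5.0),
            (1, 10, -1.0, 5.0),
            (1, 10, 1.0, -5.0),
            (1, 10, 12.0, 5.0),  # bond >= 2R: cannot stay confined
        ],
    )
    def test_invalid_dimensions_rejected(self, args):
        with pytest.raises(ValueError):
            gen_structure(*args, seed=0)


class TestGenContactMap:
    def test_power_law_expected_ratio(self):
        # hand-placed 3-bead chain with d01 = 1, d02 = 2
        st = GenomeStructure(
            cell_line="t",
            chains={"chr1": np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])},
            nucleus_radius=5.0,
            bin_size_bp=500_000,
        )
        lam = expected_contacts(st, alpha=1.0, depth=1e4)["chr1"]
        assert lam[0, 1] / lam[0, 2] == pytest.approx(2.0)

    def test_symmetric_zero_diagonal(self, world):
        for maps in world.contact_maps.values():
            for cm in maps:
                np.testing.assert_array_equal(cm.counts, cm.counts.T)
                assert np.all(np.diag(cm.counts) == 0)

    def test_total_depth_concentration(self):
        st = gen_structure(1, 100, 1.0, 6.0, seed=5)
        maps = gen_contact_map(st, alpha=1.0, depth=1e6, seed=6)
        total = sum(cm.counts.sum() for cm in maps)
        assert abs(total - 1e6) <= 4 * np.sqrt(1e6)

    def test_distance_contact_anticorrelation_exact(self):
        st = gen_structure(1, 30, 1.0, 6.0, seed=9)
        lam = expected_contacts(st, alpha=1.0, depth=1e5)["chr1"]
        X = st.chains["chr1"]
        D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
        iu = np.triu_indices(30, k=1)
        rho = spearmanr(lam[iu], D[iu]).statistic
        # exact in real arithmetic; float rounding may flip near-tied ranks
        assert rho == pytest.approx(-1.0, abs=1e-4)

    def test_coincident_beads_error(self):
        st = GenomeStructure(
            cell_line="t",
            chains={"chr1": np.zeros((3, 3))},
            nucleus_radius=5.0,
            bin_size_bp=500_000,
        )
        with pytest.raises(ValueError, match="coincident"):
            gen_contact_map(st, alpha=1.0, depth=1e4, seed=0)


class TestPeptideDataset:
    def test_lengths_within_mhc2_range(self, world):
        lengths = world.peptide_table.peptide.str.len()
        assert lengths.between(11, 30).all()

    def test_peptides_are_substrings_of_source_gene(self, world):
        proteins = dict(zip(world.gene_table.gene_id, world.gene_table.protein_sequence))
        for row in world.truth.itertuples(index=False):
            assert row.peptide in proteins[row.gene_id]

    def test_bit_reproducible(self, world):
        w2 = synthetic.build_world(n_peptides=200, n_genes=120, seed=7)
        pd.testing.assert_frame_equal(world.peptide_table, w2.peptide_table)
        pd.testing.assert_frame_equal(world.truth, w2.truth)

    def test_null_effects_give_half_positive_rate(self, world):
        records, truth = gen_peptide_dataset(
            world.structures,
            world.gene_table,
            n_peptides=2000,
            effect_params=EffectParams(b0=0.0, b_base=0.0, b_rad=0.0, sigma_u=0.0),
            assays_per_peptide=10,
            seed=21,
        )
        rate = records.n_positive.sum() / records.n_total.sum()
        assert rate == pytest.approx(0.5, abs=0.02)

    def test_strong_negative_radial_effect_detectable(self, world):
        _, truth = gen_peptide_dataset(
            world.structures,
            world.gene_table,
            n_peptides=500,
            effect_params=EffectParams(b0=0.0, b_base=0.0, b_rad=-8.0, sigma_u=0.0),
            assays_per_peptide=10,
            seed=22,
        )
        rho = spearmanr(truth.radius_mean, truth.n_positive / truth.n_total).statistic
        assert rho < 0

    def test_label_model_recovery(self, world):
        """Binomial GLM on (score, mean radius) recovers the radial effect.

        A 2-SE band is a ~95% statement, so the generator seed is fixed to a
        typical draw (estimates scatter around the true value across seeds).
        """
        import statsmodels.api as sm

        _, truth = gen_peptide_dataset(
            world.structures,
            world.gene_table,
            n_peptides=5000,
            effect_params=EffectParams(b0=0.6, b_base=0.8, b_rad=-2.0, sigma_u=0.0),
            assays_per_peptide=10,
            seed=24,
        )
        X = sm.add_constant(truth[["score", "radius_mean"]].to_numpy())
        y = np.c_[truth.n_positive, truth.n_total - truth.n_positive]
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        b_rad_hat, se = fit.params[2], fit.bse[2]
        assert b_rad_hat < 0
        assert abs(b_rad_hat - (-2.0)) <= 2 * se

    def test_short_proteins_rejected(self, world):
        short = world.gene_table.copy()
        short["protein_sequence"] = "ACDEFGHIK"  # 9 residues
        with pytest.raises(ValueError, match="shorter than 11"):
            gen_peptide_dataset(world.structures, short, 10, EffectParams(), seed=0)

    @pytest.mark.parametrize("n_peptides, assays", [(0, 10), (10, 0)])
    def test_invalid_sizes_rejected(self, world, n_peptides, assays):
        with pytest.raises(ValueError):
            gen_peptide_dataset(
                world.structures,
                world.gene_table,
                n_peptides,
                EffectParams(),
                assays_per_peptide=assays,
                seed=0,
            )


class TestGeneTable:
    def test_genes_lie_inside_their_bin(self, world):
        bs = world.bin_size_bp
        for row in world.gene_table.itertuples(index=False):
            mid = (row.start_bp + row.end_bp) // 2
            assert row.start_bp // bs == (row.end_bp - 1) // bs == mid // bs

    def test_gene_chromosomes_covered_by_contact_maps(self, world):
        for cell, maps in world.contact_maps.items():
            covered = {cm.chromosome for cm in maps}
            assert set(world.gene_table.chromosome) <= covered

    def test_perturbed_cell_line_correlates_with_reference(self, world):
        cells = list(world.structures)
        a, b = world.structures[cells[0]], world.structures[cells[1]]
        ra = np.concatenate([a.radii(c) for c in a.chromosomes])
        rb = np.concatenate([b.radii(c) for c in b.chromosomes])
        rho = spearmanr(ra, rb).statistic
        assert 0.5 < rho < 1.0
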