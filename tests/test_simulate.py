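"""Meiosis, pedigree, phenotype, bulk and pooled-count generators."""

import math

import numpy as np
import pandas as pd
import pytest

from fuzzmap.errors import InsufficientIndividualsError, InvalidInputError
from fuzzmap.segregation import ratio_chisq
from fuzzmap.simulate import (
    CausalLocus,
    CausalModel,
    MarkerGrid,
    PedigreeSpec,
    SimGenome,
    build_bulks,
    phenotype_from_genotype,
    simulate_meiosis,
    simulate_nil_study,
    simulate_pool_counts,
    simulate_population,
    simulate_selfed_progeny,
)


def het_parent(grid):
    return np.stack(
        [
            np.ones(grid.n_markers, dtype=np.uint8),
            np.zeros(grid.n_markers, dtype=np.uint8),
        ]
    )


class TestMeiosis:
    def test_zero_genetic_distance_always_coinherited(self):
        """With a 0 cM/Mb map the whole chromosome travels as one block."""
        genome = SimGenome(
            chromosomes=(("c1", 10_000_000),), marker_spacing=1_000_000, cm_per_mb=0.0
        )
        grid = MarkerGrid(genome)
        rng = np.random.default_rng(0)
        parent = het_parent(grid)
        for _ in range(200):
            gamete = simulate_meiosis(parent, grid, rng)
            assert gamete.min() == gamete.max()

    def test_independent_assortment_across_chromosomes(self):
        """Markers on different chromosomes recombine at ~1/2."""
        genome = SimGenome(
            chromosomes=(("c1", 1_000_000), ("c2", 1_000_000)),
            marker_spacing=1_000_000,
        )
        grid = MarkerGrid(genome)
        rng = np.random.default_rng(1)
        parent = het_parent(grid)
        gametes = np.stack(
            [simulate_meiosis(parent, grid, rng) for _ in range(10_000)]
        )
        recomb = (gametes[:, 0] != gametes[:, 1]).mean()
        assert recomb == pytest.approx(0.5, abs=0.02)

    def test_haldane_recombination_fraction_at_20cm(self):
        """Observed recombinant fraction matches (1 - e^{-2d})/2 at d = 0.2 M."""
        genome = SimGenome(
            chromosomes=(("c1", 40_000_000),), marker_spacing=10_000_000
        )
        grid = MarkerGrid(genome)  # markers at 10, 20, 30, 40 Mb (1 cM/Mb)
        i, j = grid.index_of("c1", 10_000_000), grid.index_of("c1", 30_000_000)
        rng = np.random.default_rng(2)
        parent = het_parent(grid)
        gametes = np.stack(
            [simulate_meiosis(parent, grid, rng) for _ in range(10_000)]
        )
        observed = (gametes[:, i] != gametes[:, j]).mean()
        expected = (1 - math.exp(-2 * 0.2)) / 2
        assert observed == pytest.approx(expected, abs=0.02)

    def test_deterministic_under_fixed_seed(self, small_grid):
        parent = het_parent(small_grid)
        g1 = simulate_meiosis(parent, small_grid, np.random.default_rng(7))
        g2 = simulate_meiosis(parent, small_grid, np.random.default_rng(7))
        assert np.array_equal(g1, g2)


class TestF2Population:
    def test_mendelian_1_2_1_at_single_marker(self):
        genome = SimGenome(chromosomes=(("c1", 1_000_000),), marker_spacing=1_000_000)
        model = CausalModel(
            loci=(CausalLocus("c1", 1_000_000, "required_recessive", 0.0),)
        )
        grid = MarkerGrid(genome, model.loci)
        pop = simulate_population(
            PedigreeSpec(design="F2", population_size=10_000),
            genome,
            model,
            seed=3,
            grid=grid,
        )
        codes = pop.genotypes.codes["c1_1000000"]
        counts = codes.value_counts()
        from scipy import stats

        chi2 = stats.chisquare(
            [counts.get(1.0, 0), counts.get(0.5, 0), counts.get(0.0, 0)],
            [2500, 5000, 2500],
        )
        assert chi2.pvalue > 0.001

    @pytest.mark.parametrize("n_loci, frac", [(2, 1 / 16), (3, 1 / 64)])
    def test_multilocus_recessive_mutant_fraction(self, n_loci, frac):
        """Fully penetrant k-locus models segregate ~(1/4)^k mutants."""
        genome = SimGenome(
            chromosomes=tuple((f"c{i}", 1_000_000) for i in range(n_loci)),
            marker_spacing=1_000_000,
        )
        model = CausalModel(
            loci=tuple(
                CausalLocus(f"c{i}", 1_000_000, "required_recessive", 0.0)
                for i in range(n_loci)
            )
        )
        grid = MarkerGrid(genome, model.loci)
        n = 8_000
        pop = simulate_population(
            PedigreeSpec(design="F2", population_size=n),
            genome,
            model,
            seed=4,
            grid=grid,
        )
        n_mut = int((pop.phenotypes["fuzz_class"] == "fuzzless").sum())
        assert ratio_chisq(n_mut, n, n_loci).p_value > 0.001


class TestPhenotypeModel:
    def model(self):
        return CausalModel(
            loci=(
                CausalLocus("c1", 1000, "required_recessive", -2.0),
                CausalLocus("c2", 1000, "additive_major", -2.5),
            ),
            baseline_fuzz=11.0,
            noise_sd=1.5,
        )

    def test_mutants_fall_in_fuzzless_class(self):
        model = self.model()
        rng = np.random.default_rng(0)
        classes = [
            phenotype_from_genotype([1.0, 0.0], model, rng)[1] for _ in range(1000)
        ]
        # P(|N(0.7, 0.4)| < 1.5) = Phi(2) - Phi(-5.5) = 0.9772; allow 3 sigma
        assert classes.count("fuzzless") >= 960

    def test_baseline_mean_without_donor_alleles(self):
        model = self.model()
        rng = np.random.default_rng(1)
        draws = [phenotype_from_genotype([0.0, 0.0], model, rng)[0] for _ in range(1000)]
        assert np.mean(draws) == pytest.approx(11.0, abs=0.2)

    def test_additive_locus_shifts_per_copy(self):
        model = self.model()
        rng = np.random.default_rng(2)
        het = [phenotype_from_genotype([0.0, 0.5], model, rng)[0] for _ in range(1000)]
        hom = [phenotype_from_genotype([0.0, 0.0], model, rng)[0] for _ in range(1000)]
        assert np.mean(hom) - np.mean(het) == pytest.approx(2.5, abs=0.25)

    def test_subunity_penetrance_spares_some_mutants(self):
        model = CausalModel(
            loci=(CausalLocus("c1", 1000, "required_recessive", -2.0),),
            penetrance=0.5,
        )
        rng = np.random.default_rng(3)
        classes = [
            phenotype_from_genotype([1.0], model, rng)[1] for _ in range(400)
        ]
        frac = classes.count("fuzzless") / len(classes)
        assert 0.35 < frac < 0.65

    def test_undefined_causal_genotype_rejected(self):
        with pytest.raises(InvalidInputError):
            phenotype_from_genotype([float("nan"), 0.0], self.model(), 0)


class TestBulksAndPools:
    def make_f2(self, small_genome, single_locus_model, small_grid, n=200, seed=11):
        return simulate_population(
            PedigreeSpec(design="F2", population_size=n),
            small_genome,
            single_locus_model,
            seed=seed,
            grid=small_grid,
        )

    def test_recessive_bulk_members_are_causal_homozygotes(
        self, small_genome, single_locus_model, small_grid
    ):
        pop = self.make_f2(small_genome, single_locus_model, small_grid)
        ids = build_bulks(pop, "recessive_bulk", 15, 0)
        codes = pop.genotypes.codes.loc[ids, "A01_2000000"]
        assert (codes == 1.0).all()

    def test_insufficient_eligible_raises_with_counts(
        self, small_genome, single_locus_model, small_grid
    ):
        pop = self.make_f2(small_genome, single_locus_model, small_grid, n=12)
        with pytest.raises(InsufficientIndividualsError, match="eligible"):
            build_bulks(pop, "recessive_bulk", 15, 0)

    def test_pure_pool_sequences_pure(
        self, small_genome, single_locus_model, small_grid
    ):
        pop = self.make_f2(small_genome, single_locus_model, small_grid)
        ids = build_bulks(pop, "recessive_bulk", 10, 1)
        sub = pop.genotypes.codes.loc[ids]
        counts = simulate_pool_counts(pop.genotypes, ids, depth=25, error_rate=0.0, rng=2)
        # wherever the bulk is fixed donor, every read is a donor read
        fixed = (sub == 1.0).all(axis=0).to_numpy()
        assert (
            counts.loc[fixed, "donor_reads"] == counts.loc[fixed, "total_reads"]
        ).all()

    def test_binomial_mean_matches_pool_frequency(self):
        genome = SimGenome(chromosomes=(("c1", 50_000_000),), marker_spacing=10_000)
        grid = MarkerGrid(genome)
        ids = ["h1", "h2"]
        codes = pd.DataFrame(
            np.tile([[1.0], [0.0]], (1, grid.n_markers)),
            index=ids,
            columns=grid.marker_map.marker_ids,
        )
        from fuzzmap.core import GenotypeMatrix

        gm = GenotypeMatrix(markers=grid.marker_map, codes=codes)
        counts = simulate_pool_counts(gm, ids, depth=30, error_rate=0.0, rng=3)
        freq = counts["donor_reads"].sum() / counts["total_reads"].sum()
        assert freq == pytest.approx(0.5, abs=0.01)

    def test_error_rate_shifts_pure_pool(self):
        genome = SimGenome(chromosomes=(("c1", 20_000_000),), marker_spacing=10_000)
        grid = MarkerGrid(genome)
        codes = pd.DataFrame(
            np.ones((1, grid.n_markers)),
            index=["h1"],
            columns=grid.marker_map.marker_ids,
        )
        from fuzzmap.core import GenotypeMatrix

        gm = GenotypeMatrix(markers=grid.marker_map, codes=codes)
        counts = simulate_pool_counts(gm, ["h1"], depth=30, error_rate=0.01, rng=4)
        freq = counts["donor_reads"].sum() / counts["total_reads"].sum()
        assert freq == pytest.approx(0.99, abs=0.005)

    def test_generators_bit_reproducible(
        self, small_genome, single_locus_model, small_grid
    ):
        a = self.make_f2(small_genome, single_locus_model, small_grid, seed=42)
        b = self.make_f2(small_genome, single_locus_model, small_grid, seed=42)
        pd.testing.assert_frame_equal(a.genotypes.codes, b.genotypes.codes)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        ca = simulate_pool_counts(a.genotypes, a.genotypes.individuals[:5], rng=9)
        cb = simulate_pool_counts(b.genotypes, b.genotypes.individuals[:5], rng=9)
        pd.testing.assert_frame_equal(ca, cb)


@pytest.fixture(scope="module")
def study():
    # three chromosomes; only the first two carry causal loci, so A03 is
    # unlinked background that backcrossing should return to recurrent
    genome = SimGenome.default(
        chrom_length=5_000_000, marker_spacing=500_000, n_chromosomes=3
    )
    model = CausalModel(
        loci=(
            CausalLocus("A01", 2_000_000, "required_recessive", -2.0),
            CausalLocus("A02", 3_000_000, "required_recessive", -2.0),
        )
    )
    return simulate_nil_study(genome, model, progeny_size=40, n_lineages=2, seed=0)


class TestNILStudy:

    def test_fuzzless_cohort_fixed_donor_at_causal_loci(self, study):
        for locus in study.model.loci:
            codes = study.fuzzless.genotypes.codes[locus.marker_id]
            assert (codes == 1.0).all()

    def test_segregating_cohort_near_half_at_causal_loci(self, study):
        for locus in study.model.loci:
            codes = study.segregating.genotypes.codes[locus.marker_id]
            assert 0.3 < codes.mean() < 0.7

    def test_normal_cohort_fixed_recurrent_at_causal_loci(self, study):
        for locus in study.model.loci:
            codes = study.normal.genotypes.codes[locus.marker_id]
            assert (codes == 0.0).all()

    def test_background_mostly_recurrent_after_backcrossing(self, study):
        background = [
            m for m in study.grid.marker_map.marker_ids if m.startswith("A03")
        ]
        mean_code = study.fuzzless.genotypes.codes[background].mean().mean()
        # unlinked background is heterozygous w.p. (1/2)^4 after 4 backcrosses
        assert mean_code < 0.35
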