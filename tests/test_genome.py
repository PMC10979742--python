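import numpy as np
import pytest
import scipy.stats

from oracles import brute_total_variance

from grnevol.genome import (
    MATRIX_LABELS,
    Genome,
    GenomeSpec,
    PopulationGenomes,
    crossover,
    devectorize_genome,
    load_genome_triplets,
    mutate_genome,
    population_genetic_variance,
    random_genome,
    save_genome_triplets,
    vectorize_genome,
)


class TestSpecAndCreation:
    def test_standard_scale_nonzero_count(self, rng):
        g = random_genome(GenomeSpec(n=200, density=0.02), rng)
        for m in range(6):
            assert np.count_nonzero(g.matrices[m]) == 800

    def test_full_density_is_dense(self, rng):
        g = random_genome(GenomeSpec(n=4, density=1.0), rng)
        assert np.count_nonzero(g.matrices) == 6 * 16

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_density_rejected(self, bad):
        with pytest.raises(ValueError):
            GenomeSpec(n=10, density=bad)

    def test_nnz_rounds_half_away_from_zero(self):
        assert GenomeSpec(n=10, density=0.125).nnz_per_matrix == 13

    def test_sign_alphabet_values(self, rng):
        g = random_genome(GenomeSpec(n=20, density=0.2), rng)
        vals = g.matrices[g.matrices != 0]
        assert set(np.unique(vals)) <= {-1.0, 1.0}

    def test_nonzero_positions_uniform(self, rng):
        # chi-square goodness of fit over the 100 cells of a 10x10 matrix
        spec = GenomeSpec(n=10, density=0.1)
        counts = np.zeros(100)
        for _ in range(300):
            g = random_genome(spec, rng)
            counts += (g.matrices[0] != 0).ravel()
        res = scipy.stats.chisquare(counts)
        assert res.pvalue > 1e-4


class TestMutation:
    def test_zero_rate_is_identity(self, small_spec, rng):
        g = random_genome(small_spec, rng)
        out = mutate_genome(g, 0.0, rng=rng)
        assert np.array_equal(out.matrices, g.matrices)

    def test_rate_one_resamples_to_spec_density(self, rng):
        # every element resampled: nonzeros ~ Binomial(n^2, density) per matrix
        spec = GenomeSpec(n=200, density=0.02)
        g = random_genome(spec, rng)
        out = mutate_genome(g, 1.0, rng=rng)
        for m in range(6):
            nnz = np.count_nonzero(out.matrices[m])
            sd = np.sqrt(40000 * 0.02 * 0.98)
            assert abs(nnz - 800) < 2.58 * sd  # 99% binomial bounds

    def test_density_preserved_over_mutation_only_drift(self, rng):
        # 200 generations at the standard rate: mean density within 3 SE
        spec = GenomeSpec(n=200, density=0.02)
        pop = PopulationGenomes.random(spec, 2, rng)
        for _ in range(200):
            pop = pop.mutate(0.005, rng)
        se = np.sqrt(0.02 * 0.98 / (2 * spec.total_elements))
        assert abs(pop.mean_density() - 0.02) < 3 * se

    def test_mutation_touches_expected_element_count(self, rng):
        # rate 0.5 on a small genome: selected slots ~ Binomial(6n^2, rate);
        # detectable as a change in sparsity pattern or values
        spec = GenomeSpec(n=30, density=0.1)
        pop = PopulationGenomes.random(spec, 1, rng)
        diffs = []
        for _ in range(30):
            out = pop.mutate(0.5, rng)
            a = np.zeros(spec.total_elements)
            b = np.zeros(spec.total_elements)
            a[pop.position_keys()] = pop.val
            b[out.position_keys()] = out.val
            diffs.append((a != b).sum())
        # a selected zero slot stays zero w.p. 0.9; a nonzero slot changes
        # w.p. 0.95 -> expected visible changes ~ rate * (0.9*nnz... loose 5-sigma
        expected = 0.5 * (0.1 * spec.total_elements * 0.95
                          + 0.9 * spec.total_elements * 0.1)
        assert abs(np.mean(diffs) - expected) / expected < 0.15


class TestCrossover:
    def test_identical_parents_reproduce_themselves(self, small_spec, rng):
        g = random_genome(small_spec, rng)
        c1, c2 = crossover(g, g.copy(), rng)
        assert np.array_equal(c1.matrices, g.matrices)
        assert np.array_equal(c2.matrices, g.matrices)

    def test_rows_travel_as_linkage_blocks(self, rng):
        spec = GenomeSpec(n=8, density=0.3)
        a = random_genome(spec, rng)
        b = random_genome(spec, rng)
        c1, c2 = crossover(a, b, rng)
        for i in range(spec.n):
            from_a = all(
                np.array_equal(c1.matrices[m, i], a.matrices[m, i]) for m in range(6)
            )
            from_b = all(
                np.array_equal(c1.matrices[m, i], b.matrices[m, i]) for m in range(6)
            )
            assert from_a or from_b  # all six matrices swap together
            other = b if from_a else a
            assert all(
                np.array_equal(c2.matrices[m, i], other.matrices[m, i])
                for m in range(6)
            )

    def test_swap_frequency_is_half(self, rng):
        spec = GenomeSpec(n=6, density=0.5)
        a = random_genome(spec, rng)
        b = random_genome(spec, rng)
        swapped = np.zeros(6)
        trials = 1000
        for _ in range(trials):
            c1, _ = crossover(a, b, rng)
            for i in range(6):
                if np.array_equal(c1.matrices[0, i], b.matrices[0, i]):
                    swapped[i] += 1
        freq = swapped / trials
        assert np.all(np.abs(freq - 0.5) < 5 * np.sqrt(0.25 / trials))

    def test_spec_mismatch_rejected(self, rng):
        a = random_genome(GenomeSpec(n=4, density=0.5), rng)
        b = random_genome(GenomeSpec(n=5, density=0.5), rng)
        with pytest.raises(ValueError):
            crossover(a, b, rng)

    def test_population_crossover_conserves_rows(self, rng):
        # multiset of (pair, row index, row content) is invariant
        spec = GenomeSpec(n=10, density=0.2)
        pop = PopulationGenomes.random(spec, 6, rng)
        kids = pop.crossover_pairs(rng)
        dense_p = np.zeros((6, 6, 10, 10))
        dense_k = np.zeros((6, 6, 10, 10))
        dense_p[pop.ind, pop.mat, pop.row, pop.col] = pop.val
        dense_k[kids.ind, kids.mat, kids.row, kids.col] = kids.val
        for pair in range(3):
            for i in range(10):
                prows = {dense_p[2 * pair, :, i].tobytes(),
                         dense_p[2 * pair + 1, :, i].tobytes()}
                krows = {dense_k[2 * pair, :, i].tobytes(),
                         dense_k[2 * pair + 1, :, i].tobytes()}
                assert prows == krows


class TestVectorization:
    def test_length_and_layout(self, rng):
        spec = GenomeSpec(n=3, density=0.4)
        g = random_genome(spec, rng)
        vec = vectorize_genome(g)
        assert vec.shape == (6 * 9,)
        # E is first, row-major: element (m, r, c) sits at (m*n + r)*n + c
        assert vec[(2 * 3 + 1) * 3 + 2] == g.matrices[2, 1, 2]

    def test_zero_genome_maps_to_zero_vector(self, toy_spec):
        g = Genome(np.zeros((6, 3, 3)), toy_spec)
        assert not vectorize_genome(g).any()

    def test_round_trip_bijection(self, small_spec, rng):
        g = random_genome(small_spec, rng)
        back = devectorize_genome(vectorize_genome(g), small_spec)
        assert np.array_equal(back.matrices, g.matrices)

    def test_population_vectorized_matches_per_genome(self, small_spec, rng):
        pop = PopulationGenomes.random(small_spec, 5, rng)
        mat = pop.vectorized()
        for i, g in enumerate(pop.to_genomes()):
            assert np.array_equal(mat[i], vectorize_genome(g))


class TestGeneticVariance:
    def test_identical_genomes_have_zero_variance(self, small_spec, rng):
        g = random_genome(small_spec, rng)
        assert population_genetic_variance([g, g.copy(), g.copy()]) == 0.0

    def test_single_element_difference_of_two(self, toy_spec):
        a = Genome(np.zeros((6, 3, 3)), toy_spec)
        b = Genome(np.zeros((6, 3, 3)), toy_spec)
        b.matrices[0, 0, 0] = 2.0
        # divisor-N variance of {0, 2} is 1
        assert population_genetic_variance([a, b]) == pytest.approx(1.0)

    def test_matches_brute_force_over_vectorized_genomes(self, small_spec, rng):
        genomes = [random_genome(small_spec, rng) for _ in range(7)]
        expected = brute_total_variance(
            [vectorize_genome(g).tolist() for g in genomes]
        )
        assert population_genetic_variance(genomes) == pytest.approx(expected)
        pop = PopulationGenomes.from_genomes(genomes)
        assert pop.genetic_variance() == pytest.approx(expected)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            population_genetic_variance([])


class TestPopulationStore:
    def test_genome_round_trip(self, small_spec, rng):
        genomes = [random_genome(small_spec, rng) for _ in range(4)]
        back = PopulationGenomes.from_genomes(genomes).to_genomes()
        for g, b in zip(genomes, back):
            assert np.array_equal(g.matrices, b.matrices)

    def test_subset_with_repeats(self, small_spec, rng):
        pop = PopulationGenomes.random(small_spec, 4, rng)
        sub = pop.subset([2, 2, 0])
        gen = pop.to_genomes()
        out = sub.to_genomes()
        assert np.array_equal(out[0].matrices, gen[2].matrices)
        assert np.array_equal(out[1].matrices, gen[2].matrices)
        assert np.array_equal(out[2].matrices, gen[0].matrices)

    def test_mean_vector(self, small_spec, rng):
        pop = PopulationGenomes.random(small_spec, 5, rng)
        assert np.allclose(pop.mean_vector(), pop.vectorized().mean(axis=0))

    def test_block_csr_blocks_are_the_individual_matrices(self, small_spec, rng):
        pop = PopulationGenomes.random(small_spec, 3, rng)
        A = pop.block_csr(2).toarray()
        n = small_spec.n
        for i, g in enumerate(pop.to_genomes()):
            assert np.array_equal(A[i * n:(i + 1) * n, i * n:(i + 1) * n], g.G)
            A[i * n:(i + 1) * n, i * n:(i + 1) * n] = 0
        assert not A.any()  # nothing off the diagonal blocks


def test_triplet_serialization_round_trip(tmp_path, small_spec, rng):
    g = random_genome(small_spec, rng)
    path = tmp_path / "genome.txt"
    save_genome_triplets(path, g)
    back = load_genome_triplets(path)
    assert back.spec == small_spec
    assert np.array_equal(back.matrices, g.matrices)
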