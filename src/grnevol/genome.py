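"""Six-matrix sparse genomes and the genetic operators acting on them.

The heritable unit is an ensemble of six n-by-n interaction matrices

* ``E`` — environmental regulation of epigenetic marks,
* ``F`` — epigenetic regulation of gene expression,
* ``G`` — genetic regulation of epigenetic marks,
* ``H`` — regulation of higher-order complexes by gene products,
* ``J`` — interactions among higher-order complexes,
* ``P`` — regulation of the phenotype,

each sparse at a fixed density (default 0.02, i.e. 800 nonzeros for n=200).
Nonzero values default to ±1 with equal probability; a Gaussian alphabet is
available via :class:`GenomeSpec`.

Two representations are provided.  :class:`Genome` is a single individual
with dense (mostly-zero) matrices — convenient for inspection, small tests
and single-individual development.  :class:`PopulationGenomes` stores a whole
population as one set of sparse triplet arrays ``(individual, matrix, row,
col, value)``; crossover is then a vectorized relabeling of the individual
index, mutation a key-set edit, and development assembles block-diagonal CSR
matrices covering the entire population at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "MATRIX_LABELS",
    "GenomeSpec",
    "Genome",
    "PopulationGenomes",
    "random_genome",
    "mutate_genome",
    "crossover",
    "vectorize_genome",
    "devectorize_genome",
    "population_genetic_variance",
    "save_genome_triplets",
    "load_genome_triplets",
]

MATRIX_LABELS = ("E", "F", "G", "H", "J", "P")
N_MATRICES = len(MATRIX_LABELS)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class GenomeSpec:
    """Dimensions and value distribution of a genome.

    Parameters
    ----------
    n
        Matrix dimension (also the number of traits), default 200.
    density
        Nonzero fraction of each matrix, default 0.02.
    value_alphabet
        ``"sign"`` draws nonzero entries uniformly from {+1, -1};
        ``"gaussian"`` draws them from a standard normal.
    """

    n: int = 200
    density: float = 0.02
    value_alphabet: str = "sign"

    def __post_init__(self) -> None:
        if int(self.n) < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0.0 < self.density <= 1.0:
            raise ValueError(f"density must be in (0, 1], got {self.density}")
        if self.value_alphabet not in ("sign", "gaussian"):
            raise ValueError(f"unknown value_alphabet {self.value_alphabet!r}")

    @property
    def nnz_per_matrix(self) -> int:
        return _round_half_away(self.density * self.n * self.n)

    @property
    def total_elements(self) -> int:
        """Number of element slots in one genome (6 n^2)."""
        return N_MATRICES * self.n * self.n

    def sample_values(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.value_alphabet == "sign":
            return (2.0 * rng.integers(0, 2, size=size) - 1.0).astype(np.float64)
        return rng.standard_normal(size)


@dataclass
class Genome:
    """One individual's genome: a (6, n, n) dense array of sparse content."""

    matrices: np.ndarray
    spec: GenomeSpec

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=np.float64)
        n = self.spec.n
        if m.shape != (N_MATRICES, n, n):
            raise ValueError(
                f"matrices must have shape {(N_MATRICES, n, n)}, got {m.shape}"
            )
        self.matrices = m

    def __getitem__(self, label: str) -> np.ndarray:
        return self.matrices[MATRIX_LABELS.index(label)]

    E = property(lambda self: self.matrices[0])
    F = property(lambda self: self.matrices[1])
    G = property(lambda self: self.matrices[2])
    H = property(lambda self: self.matrices[3])
    J = property(lambda self: self.matrices[4])
    P = property(lambda self: self.matrices[5])

    @property
    def density(self) -> float:
        return np.count_nonzero(self.matrices) / self.matrices.size

    def copy(self) -> "Genome":
        return Genome(self.matrices.copy(), self.spec)


def _distinct_uniform(n_total: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform k-subset of range(n_total), returned sorted."""
    if k <= 0:
        return np.empty(0, dtype=np.int64)
    if k >= n_total:
        return np.arange(n_total, dtype=np.int64)
    if k > n_total // 2:
        return np.sort(rng.permutation(n_total)[:k].astype(np.int64))
    keys = np.unique(rng.integers(0, n_total, size=k + k // 8 + 16, dtype=np.int64))
    while keys.size < k:
        extra = rng.integers(0, n_total, size=k, dtype=np.int64)
        keys = np.unique(np.concatenate([keys, extra]))
    if keys.size > k:
        # drop surplus at random so the subset stays exchangeable
        keys = np.sort(rng.permutation(keys)[:k])
    return keys


def _bernoulli_positions(
    n_total: int, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Sorted positions of an independent Bernoulli(rate) sieve over
    range(n_total), sampled via geometric gaps (no dense mask needed)."""
    if rate >= 1.0:
        return np.arange(n_total, dtype=np.int64)
    if rate <= 0.0:
        return np.empty(0, dtype=np.int64)
    expected = n_total * rate
    m = int(expected + 4.0 * np.sqrt(expected) + 16.0)
    parts = []
    last = -1
    while last < n_total - 1:
        pos = last + np.cumsum(rng.geometric(rate, size=m))
        parts.append(pos[pos < n_total])
        last = int(pos[-1])
    return np.concatenate(parts) if len(parts) > 1 else parts[0]


def _setdiff_sorted(keys: np.ndarray, sorted_hit: np.ndarray) -> np.ndarray:
    """Boolean mask of ``keys`` NOT contained in the sorted array."""
    if sorted_hit.size == 0:
        return np.ones(keys.size, dtype=bool)
    idx = np.minimum(np.searchsorted(sorted_hit, keys), sorted_hit.size - 1)
    return sorted_hit[idx] != keys


def random_genome(spec: GenomeSpec, rng: np.random.Generator) -> Genome:
    """Fresh genome with exactly ``round(density * n^2)`` nonzeros per matrix."""
    n = spec.n
    mats = np.zeros((N_MATRICES, n, n), dtype=np.float64)
    nnz = spec.nnz_per_matrix
    for m in range(N_MATRICES):
        pos = _distinct_uniform(n * n, nnz, rng)
        mats[m].flat[pos] = spec.sample_values(nnz, rng)
    return Genome(mats, spec)


class PopulationGenomes:
    """A fixed-size population stored as sparse triplets (structure of arrays).

    Attributes ``ind, mat, row, col`` are integer arrays and ``val`` a float
    array, all of the same length (one entry per nonzero matrix element in
    the population).  Entry order is not significant.
    """

    __slots__ = ("spec", "pop_size", "ind", "mat", "row", "col", "val")

    def __init__(self, spec, pop_size, ind, mat, row, col, val):
        self.spec = spec
        self.pop_size = int(pop_size)
        self.ind = np.asarray(ind, dtype=np.int32)
        self.mat = np.asarray(mat, dtype=np.int8)
        self.row = np.asarray(row, dtype=np.int32)
        self.col = np.asarray(col, dtype=np.int32)
        self.val = np.asarray(val, dtype=np.float64)

    # -- construction ------------------------------------------------------

    @classmethod
    def random(
        cls, spec: GenomeSpec, pop_size: int, rng: np.random.Generator
    ) -> "PopulationGenomes":
        n = spec.n
        nnz = spec.nnz_per_matrix
        blocks = pop_size * N_MATRICES
        pos = np.empty((blocks, nnz), dtype=np.int64)
        for b in range(blocks):
            pos[b] = _distinct_uniform(n * n, nnz, rng)
        ind = np.repeat(np.arange(pop_size, dtype=np.int32), N_MATRICES * nnz)
        mat = np.tile(np.repeat(np.arange(N_MATRICES, dtype=np.int8), nnz), pop_size)
        row = (pos // n).ravel()
        col = (pos % n).ravel()
        val = spec.sample_values(blocks * nnz, rng)
        return cls(spec, pop_size, ind, mat, row, col, val)

    @classmethod
    def from_genomes(cls, genomes: Sequence[Genome]) -> "PopulationGenomes":
        if len(genomes) == 0:
            raise ValueError("need at least one genome")
        spec = genomes[0].spec
        parts = []
        for i, g in enumerate(genomes):
            if g.spec != spec:
                raise ValueError("all genomes must share the same spec")
            m, r, c = np.nonzero(g.matrices)
            parts.append((np.full(m.size, i), m, r, c, g.matrices[m, r, c]))
        ind, mat, row, col, val = (np.concatenate(x) for x in zip(*parts))
        return cls(spec, len(genomes), ind, mat, row, col, val)

    def to_genomes(self) -> list[Genome]:
        n = self.spec.n
        stacks = np.zeros((self.pop_size, N_MATRICES, n, n), dtype=np.float64)
        stacks[self.ind, self.mat, self.row, self.col] = self.val
        return [Genome(stacks[i], self.spec) for i in range(self.pop_size)]

    def copy(self) -> "PopulationGenomes":
        return PopulationGenomes(
            self.spec, self.pop_size, self.ind.copy(), self.mat.copy(),
            self.row.copy(), self.col.copy(), self.val.copy(),
        )

    # -- keys and views ----------------------------------------------------

    @property
    def nnz(self) -> int:
        return self.val.size

    def element_keys(self) -> np.ndarray:
        """Flat int64 key per entry: ((ind*6 + mat)*n + row)*n + col."""
        n = self.spec.n
        return (
            (self.ind.astype(np.int64) * N_MATRICES + self.mat) * n + self.row
        ) * n + self.col

    def position_keys(self) -> np.ndarray:
        """Per-entry position within a genome (ignoring the individual)."""
        n = self.spec.n
        return (self.mat.astype(np.int64) * n + self.row) * n + self.col

    def block_csr(self, matrix_index: int) -> sp.csr_matrix:
        """Block-diagonal CSR of one matrix label over the whole population.

        Block i on the diagonal is individual i's matrix, so a population
        state vector of length ``pop_size * n`` multiplies all individuals
        at once.
        """
        n = self.spec.n
        sel = self.mat == matrix_index
        base = self.ind[sel].astype(np.int64) * n
        return sp.csr_matrix(
            (self.val[sel], (base + self.row[sel], base + self.col[sel])),
            shape=(self.pop_size * n, self.pop_size * n),
        )

    def vectorized(self, dtype=np.float64) -> np.ndarray:
        """Dense (pop_size, 6 n^2) matrix of flattened genomes.

        Row-major within each matrix, matrices concatenated in label order —
        the same layout as :func:`vectorize_genome`.
        """
        out = np.zeros((self.pop_size, self.spec.total_elements), dtype=dtype)
        out[self.ind, self.position_keys()] = self.val
        return out

    def subset(self, indices: Iterable[int]) -> "PopulationGenomes":
        """Gather individuals by index (repeats allowed), renumbered 0..k-1."""
        indices = np.asarray(list(indices), dtype=np.int64)
        order = np.argsort(self.ind, kind="stable")
        counts = np.bincount(self.ind, minlength=self.pop_size)
        ends = np.cumsum(counts)
        starts = ends - counts
        gather = np.concatenate(
            [order[starts[i]:ends[i]] for i in indices]
        ) if indices.size else np.empty(0, dtype=np.int64)
        new_ind = np.repeat(np.arange(indices.size, dtype=np.int32), counts[indices])
        return PopulationGenomes(
            self.spec, indices.size, new_ind, self.mat[gather],
            self.row[gather], self.col[gather], self.val[gather],
        )

    # -- genetic operators -------------------------------------------------

    def mutate(self, rate: float, rng: np.random.Generator) -> "PopulationGenomes":
        """Density-preserving point mutation, independently per element.

        Every element slot (zero or not) of every matrix is selected with
        probability ``rate``; a selected slot is resampled from the marginal
        element distribution — zero with probability ``1 - density``,
        otherwise a fresh value from the spec's alphabet.  Equivalent to
        drawing ``K ~ Binomial(pop * 6n^2, rate)`` distinct slots uniformly.
        """
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate must be in [0, 1], got {rate}")
        if rate == 0.0:
            return self.copy()
        n = self.spec.n
        n_total = self.pop_size * self.spec.total_elements
        hit = _bernoulli_positions(n_total, rate, rng)
        keep = _setdiff_sorted(self.element_keys(), hit)
        nz = hit[rng.random(hit.size) < self.spec.density]
        new_val = self.spec.sample_values(nz.size, rng)
        col = nz % n
        rest = nz // n
        row = rest % n
        rest //= n
        mat = rest % N_MATRICES
        ind = rest // N_MATRICES
        return PopulationGenomes(
            self.spec, self.pop_size,
            np.concatenate([self.ind[keep], ind.astype(np.int32)]),
            np.concatenate([self.mat[keep], mat.astype(np.int8)]),
            np.concatenate([self.row[keep], row.astype(np.int32)]),
            np.concatenate([self.col[keep], col.astype(np.int32)]),
            np.concatenate([self.val[keep], new_val]),
        )

    def crossover_pairs(self, rng: np.random.Generator) -> "PopulationGenomes":
        """Recombine consecutive pairs (0,1), (2,3), ... into two offspring each.

        For each row index, with probability 1/2 the corresponding rows of
        *all six* matrices are exchanged between the two offspring: one gene's
        entire incoming regulation travels as a single linkage block.  The
        union of the offspring's rows equals the union of the parents' rows.
        """
        if self.pop_size % 2:
            raise ValueError("crossover requires an even population")
        swap = rng.random((self.pop_size // 2, self.spec.n)) < 0.5
        parity = (self.ind & 1).astype(np.int32)
        flip = swap[self.ind >> 1, self.row]
        new_ind = (self.ind & ~1) + (parity ^ flip)
        return PopulationGenomes(
            self.spec, self.pop_size, new_ind, self.mat, self.row, self.col, self.val
        )

    # -- statistics --------------------------------------------------------

    def genetic_variance(self) -> float:
        """Sum over all 6 n^2 element positions of the across-population
        variance of that element (population variance, divisor N)."""
        m = self.spec.total_elements
        pos = self.position_keys()
        s1 = np.bincount(pos, weights=self.val, minlength=m)
        s2 = np.bincount(pos, weights=self.val**2, minlength=m)
        n = self.pop_size
        return float(np.sum(s2 / n - (s1 / n) ** 2))

    def mean_vector(self, dtype=np.float64) -> np.ndarray:
        """Population-mean vectorized genome, length 6 n^2."""
        s1 = np.bincount(
            self.position_keys(), weights=self.val, minlength=self.spec.total_elements
        )
        return (s1 / self.pop_size).astype(dtype)

    def mean_density(self) -> float:
        return self.nnz / (self.pop_size * self.spec.total_elements)


# -- single-genome operation wrappers -------------------------------------


def mutate_genome(
    genome: Genome, rate: float, spec: GenomeSpec | None = None,
    rng: np.random.Generator | None = None,
) -> Genome:
    """Mutate one genome (see :meth:`PopulationGenomes.mutate`)."""
    if rng is None:
        raise ValueError("rng is required")
    spec = spec or genome.spec
    pop = PopulationGenomes.from_genomes([Genome(genome.matrices, spec)])
    return pop.mutate(rate, rng).to_genomes()[0]


def crossover(
    parent_a: Genome, parent_b: Genome, rng: np.random.Generator
) -> tuple[Genome, Genome]:
    """Row-linkage recombination of two parents into two offspring."""
    if parent_a.spec != parent_b.spec:
        raise ValueError("parents must share the same GenomeSpec")
    pop = PopulationGenomes.from_genomes([parent_a, parent_b])
    c1, c2 = pop.crossover_pairs(rng).to_genomes()
    return c1, c2


def vectorize_genome(genome: Genome) -> np.ndarray:
    """Flatten and concatenate E, F, G, H, J, P (row-major) into one vector."""
    return genome.matrices.reshape(-1).copy()


def devectorize_genome(vec: np.ndarray, spec: GenomeSpec) -> Genome:
    vec = np.asarray(vec, dtype=np.float64)
    if vec.size != spec.total_elements:
        raise ValueError(
            f"expected length {spec.total_elements}, got {vec.size}"
        )
    return Genome(vec.reshape(N_MATRICES, spec.n, spec.n).copy(), spec)


def population_genetic_variance(genomes) -> float:
    """Genetic variance of a population (sum of per-element variances).

    Accepts a :class:`PopulationGenomes` or an iterable of :class:`Genome`.
    """
    if isinstance(genomes, PopulationGenomes):
        return genomes.genetic_variance()
    genomes = list(genomes)
    if not genomes:
        raise ValueError("need at least one genome")
    return PopulationGenomes.from_genomes(genomes).genetic_variance()


# -- serialization ---------------------------------------------------------


def save_genome_triplets(path, genome: Genome) -> None:
    """Write a genome as text triplets: ``label row col value`` per line.

    A header line carries the spec (n, density, alphabet).
    """
    with open(path, "w") as fh:
        fh.write(
            f"# n={genome.spec.n} density={genome.spec.density} "
            f"alphabet={genome.spec.value_alphabet}\n"
        )
        for m, label in enumerate(MATRIX_LABELS):
            r, c = np.nonzero(genome.matrices[m])
            for i, j in zip(r, c):
                fh.write(f"{label} {i} {j} {float(genome.matrices[m, i, j])!r}\n")


def load_genome_triplets(path) -> Genome:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("missing spec header line")
        kv = dict(item.split("=") for item in header[1:].split())
        spec = GenomeSpec(
            n=int(kv["n"]), density=float(kv["density"]), value_alphabet=kv["alphabet"]
        )
        mats = np.zeros((N_MATRICES, spec.n, spec.n), dtype=np.float64)
        for line in fh:
            label, i, j, v = line.split()
            mats[MATRIX_LABELS.index(label), int(i), int(j)] = float(v)
    return Genome(mats, spec)
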