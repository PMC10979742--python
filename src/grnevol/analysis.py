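"""Derived statistics: projections, mismatch, cross-covariance SVD, bias.

Evolutionary trajectories are visualized in a two-dimensional
genotype-phenotype space.  The phenotype axis joins the ancestral and novel
environments restricted to the selected traits; projections of 0 and 1 mean
perfectly adapted to the ancestral and the novel environment.  The genotype
axis joins the population-mean vectorized genomes of the first and last
generation of an epoch.

Developmental bias is quantified through the cross-covariance between the
selected phenotype and either the environmental cue (Pheno-Cue) or the
vectorized genome (Pheno-Geno).  The first singular value measures how
strongly phenotypic variation couples to environmental noise or genetic
variation; the proportion sigma_1^2 / sum sigma_i^2 measures the dominance
(skew) of the leading mode; and the alignment |u_1 . (e_n - e_a)| /
||e_n - e_a|| measures its orientation relative to the environmental change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from . import environment as envmod
from .development import develop_population
from .evolution import EvolutionConfig
from .genome import PopulationGenomes

__all__ = [
    "mismatch",
    "ProjectionFrame",
    "project_phenotype",
    "project_genotype",
    "cross_covariance",
    "CrossCovResult",
    "svd_cross_covariance",
    "bias_proportion",
    "alignment",
    "transition_sweep",
    "detect_transition",
]


class DegenerateFrameError(ValueError):
    """The projection axis has zero length (no environmental or genetic change)."""


def mismatch(adult, env, n_selected: int) -> float | np.ndarray:
    """L1 distance between adult phenotype and environment over the first
    ``n_selected`` traits.  Accepts a single adult (1-d) or a population
    (2-d, one row per individual)."""
    adult = np.asarray(adult, dtype=np.float64)
    env = np.asarray(env, dtype=np.float64)
    if adult.shape[-1] < n_selected or env.size < n_selected:
        raise ValueError("adult and env must have at least n_selected elements")
    d = np.abs(adult[..., :n_selected] - env[:n_selected]).sum(axis=-1)
    return float(d) if adult.ndim == 1 else d


@dataclass
class ProjectionFrame:
    """Axes of the genotype-phenotype plot.

    ``e_a_sel`` / ``e_n_sel`` are the ancestral and novel environments
    restricted to the selected traits; ``genotype_origin`` /
    ``genotype_end`` are the population-mean vectorized genomes at the first
    and last generation of the epoch being plotted (optional until genotype
    projections are requested).
    """

    e_a_sel: np.ndarray
    e_n_sel: np.ndarray
    genotype_origin: np.ndarray | None = None
    genotype_end: np.ndarray | None = None

    @classmethod
    def from_environments(cls, env_ancestral, env_novel, n_selected: int,
                          genotype_origin=None, genotype_end=None):
        env_ancestral = np.asarray(env_ancestral, dtype=np.float64)
        env_novel = np.asarray(env_novel, dtype=np.float64)
        return cls(env_ancestral[:n_selected], env_novel[:n_selected],
                   genotype_origin, genotype_end)

    @property
    def phenotype_axis(self) -> np.ndarray:
        axis = np.asarray(self.e_n_sel, float) - np.asarray(self.e_a_sel, float)
        if not np.any(axis):
            raise DegenerateFrameError("ancestral and novel environments coincide")
        return axis

    @property
    def genotype_axis(self) -> np.ndarray:
        if self.genotype_origin is None or self.genotype_end is None:
            raise DegenerateFrameError("genotype anchors are not set")
        axis = np.asarray(self.genotype_end, float) - np.asarray(
            self.genotype_origin, float
        )
        if not np.any(axis):
            raise DegenerateFrameError("genotype anchors coincide (no evolution)")
        return axis


def project_phenotype(adult, frame: ProjectionFrame):
    """Scalar phenotype coordinate: 0 at the ancestral optimum, 1 at the novel.

    ``(p~_sel - e_a) . (e_n - e_a) / ||e_n - e_a||^2`` over the selected
    traits.  Accepts a single adult or a population (2-d)."""
    axis = frame.phenotype_axis
    t = axis.size
    adult = np.asarray(adult, dtype=np.float64)
    if adult.shape[-1] < t:
        raise ValueError(f"adult must have at least {t} elements")
    proj = (adult[..., :t] - np.asarray(frame.e_a_sel, float)) @ axis / (axis @ axis)
    return float(proj) if adult.ndim == 1 else proj


def project_genotype(genome_vec, frame: ProjectionFrame):
    """Scalar genotype coordinate: 0 at the epoch-start population mean,
    1 at the epoch-end mean."""
    axis = frame.genotype_axis
    origin = np.asarray(frame.genotype_origin, dtype=np.float64)
    vec = np.asarray(genome_vec, dtype=np.float64)
    proj = (vec - origin) @ axis / (axis @ axis)
    return float(proj) if vec.ndim == 1 else proj


def cross_covariance(phenos: np.ndarray, covars: np.ndarray) -> np.ndarray:
    """Cross-covariance matrix C_ij = (1/N) sum_k (p_ik - p-bar_i)(x_jk - x-bar_j).

    ``phenos`` is (N, T) — one row per individual, selected traits — and
    ``covars`` is (N, M) — cue elements (Pheno-Cue) or vectorized genomes
    (Pheno-Geno).  Divisor N, both sides centered.
    """
    phenos = np.asarray(phenos, dtype=np.float64)
    covars = np.asarray(covars, dtype=np.float64)
    if phenos.ndim != 2 or covars.ndim != 2 or phenos.shape[0] != covars.shape[0]:
        raise ValueError("phenos and covars must be 2-d with equal row counts")
    n = phenos.shape[0]
    if n < 2:
        raise ValueError("need at least 2 individuals")
    pc = phenos - phenos.mean(axis=0)
    xc = covars - covars.mean(axis=0)
    return pc.T @ xc / n


@dataclass
class CrossCovResult:
    """SVD of a cross-covariance matrix, singular values nonincreasing.

    ``left_vectors[:, i]`` is the i-th principal axis of phenotypic
    variation, ``right_vectors[:, i]`` the matching axis of cue/genome
    variation.  Signs follow the convention that the first nonzero component
    of each left vector is nonnegative.
    """

    singular_values: np.ndarray
    left_vectors: np.ndarray
    right_vectors: np.ndarray

    @property
    def total_sq(self) -> float:
        return float(np.sum(self.singular_values**2))


def _fix_signs(u: np.ndarray, v: np.ndarray):
    for i in range(u.shape[1]):
        col = u[:, i]
        nz = np.nonzero(col)[0]
        if nz.size and col[nz[0]] < 0:
            u[:, i] = -col
            v[:, i] = -v[:, i]
    return u, v


def svd_cross_covariance(C: np.ndarray, gram_ratio: float = 4.0) -> CrossCovResult:
    """SVD of a cross-covariance matrix.

    For very wide matrices (the Pheno-Geno case: 40 x 6n^2) the
    decomposition runs economically through the T x T Gram matrix C C^T on
    the phenotype side, which yields the same singular values and left
    vectors as a direct SVD; right vectors are recovered as C^T u / sigma.
    """
    C = np.asarray(C, dtype=np.float64)
    if C.ndim != 2:
        raise ValueError("C must be a matrix")
    if not np.isfinite(C).all():
        raise ValueError("C contains non-finite entries")
    t, m = C.shape
    if m >= gram_ratio * t:
        gram = C @ C.T
        evals, evecs = scipy.linalg.eigh(gram)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        u = evecs[:, order]
        s = np.sqrt(evals)
        v = np.zeros((m, t))
        pos = s > max(s[0], 1.0) * 1e-12 if s.size else np.zeros(0, bool)
        if pos.any():
            v[:, pos] = C.T @ u[:, pos] / s[pos]
    else:
        u, s, vt = scipy.linalg.svd(C, full_matrices=False)
        v = vt.T
    u, v = _fix_signs(u.copy(), v.copy())
    return CrossCovResult(singular_values=s, left_vectors=u, right_vectors=v)


def bias_proportion(singular_values) -> float:
    """Dominance of the leading mode: sigma_1^2 / sum_i sigma_i^2."""
    s = np.asarray(singular_values, dtype=np.float64)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise ValueError("all singular values are zero; bias undefined")
    return float(s[0] ** 2) / total


def alignment(u1, frame: ProjectionFrame) -> float:
    """|u_1 . (e_n - e_a)| / ||e_n - e_a||: orientation of the leading
    phenotypic mode relative to the environmental change.  Invariant to the
    sign ambiguity of the singular vector."""
    axis = frame.phenotype_axis
    u1 = np.asarray(u1, dtype=np.float64)
    if u1.size != axis.size:
        raise ValueError("u1 must have one element per selected trait")
    return float(np.abs(u1 @ axis) / np.linalg.norm(axis))


# -- magnitude sweep -------------------------------------------------------


def _first_generation_stats(genomes, env_old, env_new, cfg, rng):
    """Develop the first post-change generation and compute the 8 sweep
    statistics (before any selection)."""
    t = cfg.fitness.n_selected_traits
    pop = genomes.pop_size
    if cfg.model == "full":
        cues = envmod.generate_cues(env_new, cfg.cue_noise, pop, rng)
        out = develop_population(genomes, cues, "full", cfg.dev)
    else:
        cues = np.tile(env_new, (pop, 1))
        out = develop_population(genomes, None, "nocue", cfg.dev)
    frame = ProjectionFrame.from_environments(env_old, env_new, t)
    proj = project_phenotype(out.adults, frame)
    phen = out.adults[:, :t]
    res_cue = svd_cross_covariance(cross_covariance(phen, cues.astype(np.float64)))
    res_geno = svd_cross_covariance(
        cross_covariance(phen, genomes.vectorized(np.float64))
    )
    return {
        "mean_proj_pheno": float(np.mean(proj)),
        "var_proj_pheno": float(np.var(proj)),
        "sv1_pheno_cue": float(res_cue.singular_values[0]),
        "sv1_pheno_geno": float(res_geno.singular_values[0]),
        "bias_pheno_cue": bias_proportion(res_cue.singular_values),
        "bias_pheno_geno": bias_proportion(res_geno.singular_values),
        "align_pheno_cue": alignment(res_cue.left_vectors[:, 0], frame),
        "align_pheno_geno": alignment(res_geno.left_vectors[:, 0], frame),
        "frac_converged": float(out.converged.mean()),
    }


def transition_sweep(
    genomes: PopulationGenomes,
    env: np.ndarray,
    cfg: EvolutionConfig,
    magnitudes: Sequence[float],
    epochs_per_magnitude: int = 10,
    seed_seq: np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """First-generation response of an equilibrated population to
    environmental changes of different magnitudes.

    For every magnitude and replicate epoch: flip that fraction of the
    adapted environment, develop the first generation (no selection), and
    record the projected-phenotype mean and variance, the first singular
    values of the Pheno-Cue and Pheno-Geno cross-covariances, their bias
    proportions and their alignments.  One tidy row per (magnitude, epoch).

    ``genomes``/``env`` must come from an equilibrated snapshot (e.g.
    :func:`grnevol.evolution.prepare_population`).
    """
    if genomes is None or env is None:
        raise ValueError("an equilibrated (genomes, env) snapshot is required")
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(cfg.seed).spawn(3)[2]
    rows = []
    for mag in magnitudes:
        for ss in seed_seq.spawn(epochs_per_magnitude):
            rng = np.random.default_rng(ss)
            env_new = envmod.flip_environment(env, mag, rng)
            stats = _first_generation_stats(genomes, env, env_new, cfg, rng)
            rows.append({"magnitude": mag, **stats})
    df = pd.DataFrame(rows)
    df.insert(1, "epoch", df.groupby("magnitude").cumcount() + 1)
    return df


def detect_transition(
    sweep: pd.DataFrame,
    statistic: str = "mean_proj_pheno",
    baseline_magnitude: float | None = None,
    factor: float = 3.0,
) -> float | None:
    """Smallest magnitude whose median statistic exceeds ``factor`` times the
    small-change baseline median.  Returns None when no magnitude qualifies.
    """
    med = sweep.groupby("magnitude")[statistic].median().sort_index()
    if baseline_magnitude is None:
        baseline_magnitude = med.index[0]
    base = med.loc[baseline_magnitude]
    hits = med[med > factor * base]
    hits = hits[hits.index > baseline_magnitude]
    return float(hits.index[0]) if len(hits) else None
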