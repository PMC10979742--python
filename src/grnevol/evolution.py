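"""Genetic-algorithm protocol: fitness, selection, epochs, experiments.

One generation: every offspring genome develops twice — under a cue drawn
from the *novel* (current selective) environment and under one from the
*ancestral* (previously adapted) environment.  Fitness uses only the
novel-environment outcome,

    log w_i = -( alpha * || p~ - e ||_1  +  beta * N_step ),

with the L1 mismatch taken over the first ``n_selected_traits`` traits (40
of 200 by default), alpha = 20 and beta = 1/20.  Non-converged individuals
get log-fitness -inf ("zero fitness").  All fitness arithmetic stays in log
space; normalized fitness is exp(log w_i - max_j log w_j), so the maximum is
exactly 1 and constant shifts cancel.  Parents are drawn by
acceptance-rejection roulette with replacement; consecutive acceptances form
pairs, each producing two offspring by row-linkage crossover followed by
density-preserving mutation.

An *epoch* is a fixed number of generations in a constant environment; an
experiment runs preparatory epochs under fresh uncorrelated environments to
equilibrate the population, then production epochs each preceded by flipping
a set fraction of the environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

from . import environment as envmod
from .development import DevConfig, develop_population
from .genome import GenomeSpec, PopulationGenomes

__all__ = [
    "FitnessParams",
    "EvolutionConfig",
    "ExtinctionError",
    "GenerationRecord",
    "EpochResult",
    "ExperimentResult",
    "raw_log_fitness",
    "normalize_fitness",
    "select_parents",
    "reproduce",
    "run_generation",
    "run_epoch",
    "prepare_population",
    "run_production",
    "run_experiment",
]


class ExtinctionError(RuntimeError):
    """The whole population failed to develop a converged adult phenotype."""

    def __init__(self, message: str, epoch: int | None = None,
                 generation: int | None = None):
        super().__init__(message)
        self.epoch = epoch
        self.generation = generation


@dataclass(frozen=True)
class FitnessParams:
    """Selection-side parameters: strength, step penalty, selection window."""

    alpha_sel: float = 20.0
    beta_step: float = 1.0 / 20.0
    n_selected_traits: int = 40

    def __post_init__(self) -> None:
        if self.alpha_sel <= 0 or self.beta_step <= 0:
            raise ValueError("alpha_sel and beta_step must be positive")
        if self.n_selected_traits < 1:
            raise ValueError("n_selected_traits must be >= 1")


@dataclass(frozen=True)
class EvolutionConfig:
    """Full experiment configuration; defaults are the standard study values."""

    n_env: int = 200
    pop_size: int = 1000
    generations_per_epoch: int = 200
    n_epochs: int = 10
    env_change_fraction: float = 0.5
    cue_noise: float = 0.05
    mutation_rate: float = 0.005
    n_prep_epochs: int = 40
    model: Literal["full", "nocue"] = "full"
    dev: DevConfig = field(default_factory=DevConfig)
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    fitness: FitnessParams = field(default_factory=FitnessParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2 or self.pop_size % 2:
            raise ValueError("pop_size must be even and >= 2")
        for name in ("env_change_fraction", "cue_noise", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.generations_per_epoch < 1 or self.n_epochs < 0 or self.n_prep_epochs < 0:
            raise ValueError("epoch schedule fields must be nonnegative "
                             "(generations_per_epoch >= 1)")
        if self.model not in ("full", "nocue"):
            raise ValueError(f"model must be 'full' or 'nocue', got {self.model!r}")
        if self.n_env != self.genome.n:
            raise ValueError(
                f"n_env ({self.n_env}) must equal the genome dimension "
                f"({self.genome.n})"
            )
        if self.fitness.n_selected_traits > self.n_env:
            raise ValueError("n_selected_traits cannot exceed n_env")


# -- fitness ---------------------------------------------------------------


def raw_log_fitness(adult, env, n_steps: int, converged: bool,
                    params: FitnessParams) -> float:
    """Log of the raw fitness; -inf if development did not converge.

    Only the first ``n_selected_traits`` phenotype elements are compared
    with the environment; the rest evolve free of selection.
    """
    adult = np.asarray(adult, dtype=np.float64)
    env = np.asarray(env, dtype=np.float64)
    t = params.n_selected_traits
    if adult.size < t or env.size < t:
        raise ValueError("adult and env must have at least n_selected_traits elements")
    if not converged:
        return -np.inf
    l1 = float(np.abs(adult[:t] - env[:t]).sum())
    return -(params.alpha_sel * l1 + params.beta_step * n_steps)


def _log_fitness_population(adults, n_steps, converged, env, params) -> np.ndarray:
    t = params.n_selected_traits
    l1 = np.abs(adults[:, :t] - np.asarray(env, dtype=np.float64)[:t]).sum(axis=1)
    out = -(params.alpha_sel * l1 + params.beta_step * n_steps)
    out[~converged] = -np.inf
    return out


def normalize_fitness(log_ws) -> np.ndarray:
    """Max-normalized fitness: exp(log w - max log w); -inf maps to 0."""
    log_ws = np.asarray(log_ws, dtype=np.float64)
    m = np.max(log_ws)
    if m == -np.inf:
        raise ExtinctionError("all individuals failed to converge")
    with np.errstate(invalid="ignore"):
        omega = np.exp(log_ws - m)
    omega[np.isneginf(log_ws)] = 0.0
    return omega


def select_parents(omegas, n_pairs: int, rng: np.random.Generator) -> np.ndarray:
    """Acceptance-rejection roulette with replacement.

    Repeatedly draw a uniform individual and accept it with probability
    equal to its normalized fitness until ``2 * n_pairs`` acceptances;
    consecutive acceptances form the parent pairs (selfing is possible).
    Returns an (n_pairs, 2) index array.
    """
    omegas = np.asarray(omegas, dtype=np.float64)
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not (omegas > 0).any():
        raise ExtinctionError("all selection probabilities are zero")
    need = 2 * n_pairs
    mean = max(float(omegas.mean()), 1.0 / (4 * omegas.size))
    chosen: list[np.ndarray] = []
    while need > 0:
        m = max(64, int(need / mean * 1.3))
        idx = rng.integers(0, omegas.size, size=m)
        acc = idx[rng.random(m) < omegas[idx]][:need]
        chosen.append(acc)
        need -= acc.size
    return np.concatenate(chosen).reshape(n_pairs, 2)


def reproduce(genomes: PopulationGenomes, pairs: np.ndarray,
              cfg: EvolutionConfig, rng: np.random.Generator) -> PopulationGenomes:
    """Crossover each parent pair into two offspring, then mutate everyone."""
    if 2 * len(pairs) != cfg.pop_size:
        raise ValueError("need pop_size/2 parent pairs")
    parents = genomes.subset(np.asarray(pairs).ravel())
    children = parents.crossover_pairs(rng)
    return children.mutate(cfg.mutation_rate, rng)


# -- records ---------------------------------------------------------------


@dataclass
class GenerationRecord:
    """Pre-selection population statistics of one generation."""

    generation: int
    mean_proj_pheno_novel: float
    sd_proj_pheno_novel: float
    mean_proj_pheno_ancestral: float
    sd_proj_pheno_ancestral: float
    mean_mismatch_novel: float
    mean_mismatch_ancestral: float
    frac_converged_novel: float
    frac_converged_ancestral: float
    genetic_variance: float
    mean_n_steps_novel: float
    mean_proj_geno: float = np.nan   # filled at epoch end (axis needs gen 1 & last)
    sd_proj_geno: float = np.nan     # filled only with full genotype tracking


@dataclass
class EpochResult:
    """One epoch's trajectory plus the material needed to continue."""

    records: pd.DataFrame
    final_genomes: PopulationGenomes
    env_novel: np.ndarray
    env_ancestral: np.ndarray
    mean_genomes: list[np.ndarray] | None = None        # per-generation G-bar
    generation_genomes: list[PopulationGenomes] | None = None


@dataclass
class ExperimentResult:
    records: pd.DataFrame
    final_genomes: PopulationGenomes
    final_env: np.ndarray
    environments: list[np.ndarray]
    cfg: EvolutionConfig


def _projection_stats(adults, env_a, env_n, t):
    """Mean/sd of selected-trait phenotype projections onto the change axis."""
    axis = (env_n[:t] - env_a[:t]).astype(np.float64)
    denom = float(axis @ axis)
    if denom == 0.0:
        return np.nan, np.nan
    proj = (adults[:, :t] - env_a[:t]) @ axis / denom
    return float(proj.mean()), float(proj.std())


def _mismatch_mean(adults, env, t):
    return float(np.abs(adults[:, :t] - np.asarray(env, float)[:t]).sum(axis=1).mean())


def run_generation(
    genomes: PopulationGenomes,
    env_novel: np.ndarray,
    env_ancestral: np.ndarray,
    cfg: EvolutionConfig,
    rng: np.random.Generator,
    generation: int = 0,
    measure_ancestral: bool = True,
    return_outcomes: bool = False,
):
    """Develop, measure, select and reproduce one generation.

    Every genome develops under a fresh cue from the novel environment and —
    for measurement only — under a fresh cue from the ancestral environment.
    Selection sees only the novel-environment outcomes.  Returns the next
    generation's genomes and this generation's :class:`GenerationRecord`.

    The ancestral-context measurement draws from its own random substream,
    so toggling ``measure_ancestral`` cannot alter the evolutionary
    trajectory.
    """
    pop = genomes.pop_size
    t = cfg.fitness.n_selected_traits
    rng_novel, rng_anc, rng_ga = rng.spawn(3)
    if cfg.model == "full":
        cues_n = envmod.generate_cues(env_novel, cfg.cue_noise, pop, rng_novel)
        if measure_ancestral:
            cues_a = envmod.generate_cues(env_ancestral, cfg.cue_noise, pop, rng_anc)
            out_n, out_a = develop_population(
                genomes, [cues_n, cues_a], "full", cfg.dev
            )
        else:
            out_n = develop_population(genomes, cues_n, "full", cfg.dev)
            out_a = None
    else:
        # cue-free development: the two environmental contexts share outcomes
        out_n = develop_population(genomes, None, "nocue", cfg.dev)
        out_a = out_n if measure_ancestral else None

    mean_n, sd_n = _projection_stats(out_n.adults, env_ancestral, env_novel, t)
    if out_a is not None:
        mean_a, sd_a = _projection_stats(out_a.adults, env_ancestral, env_novel, t)
        mm_a = _mismatch_mean(out_a.adults, env_ancestral, t)
        fc_a = float(out_a.converged.mean())
    else:
        mean_a = sd_a = mm_a = fc_a = np.nan

    record = GenerationRecord(
        generation=generation,
        mean_proj_pheno_novel=mean_n,
        sd_proj_pheno_novel=sd_n,
        mean_proj_pheno_ancestral=mean_a,
        sd_proj_pheno_ancestral=sd_a,
        mean_mismatch_novel=_mismatch_mean(out_n.adults, env_novel, t),
        mean_mismatch_ancestral=mm_a,
        frac_converged_novel=float(out_n.converged.mean()),
        frac_converged_ancestral=fc_a,
        genetic_variance=genomes.genetic_variance(),
        mean_n_steps_novel=float(out_n.n_steps.mean()),
    )

    log_ws = _log_fitness_population(
        out_n.adults, out_n.n_steps, out_n.converged, env_novel, cfg.fitness
    )
    omegas = normalize_fitness(log_ws)
    pairs = select_parents(omegas, pop // 2, rng_ga)
    nxt = reproduce(genomes, pairs, cfg, rng_ga)
    if return_outcomes:
        return nxt, record, {"novel": out_n, "ancestral": out_a, "omegas": omegas}
    return nxt, record


def run_epoch(
    genomes: PopulationGenomes,
    env_novel: np.ndarray,
    env_ancestral: np.ndarray,
    cfg: EvolutionConfig,
    seed_seq: np.random.SeedSequence,
    measure_ancestral: bool = True,
    track_genotype: Literal["none", "mean", "full"] = "mean",
) -> EpochResult:
    """Evolve for ``generations_per_epoch`` generations in a fixed environment.

    Deterministic given ``seed_seq`` (one child stream per generation).  With
    ``track_genotype="mean"`` the per-generation population-mean genome
    vectors are kept and the records' mean projected genotype is filled in
    at epoch end (the genotype axis joins the generation-1 and last-
    generation means, so it only exists post hoc); ``"full"`` additionally
    retains every generation's population for per-individual projections.
    """
    streams = seed_seq.spawn(cfg.generations_per_epoch)
    records: list[GenerationRecord] = []
    means: list[np.ndarray] | None = [] if track_genotype in ("mean", "full") else None
    pops: list[PopulationGenomes] | None = [] if track_genotype == "full" else None
    for gen in range(1, cfg.generations_per_epoch + 1):
        rng = np.random.default_rng(streams[gen - 1])
        if means is not None:
            means.append(genomes.mean_vector())
        if pops is not None:
            pops.append(genomes.copy())
        try:
            genomes, rec = run_generation(
                genomes, env_novel, env_ancestral, cfg, rng,
                generation=gen, measure_ancestral=measure_ancestral,
            )
        except ExtinctionError as exc:
            raise ExtinctionError(
                f"population extinct at generation {gen}: {exc}", generation=gen
            ) from exc
        records.append(rec)

    if means is not None and len(means) >= 2:
        axis = means[-1] - means[0]
        denom = float(axis @ axis)
        if denom > 0.0:
            for rec, m in zip(records, means):
                rec.mean_proj_geno = float((m - means[0]) @ axis / denom)
            if pops is not None:
                for rec, p in zip(records, pops):
                    vecs = p.vectorized(np.float64)
                    proj = (vecs - means[0]) @ axis / denom
                    rec.sd_proj_geno = float(proj.std())

    return EpochResult(
        records=pd.DataFrame([asdict(r) for r in records]),
        final_genomes=genomes,
        env_novel=env_novel,
        env_ancestral=env_ancestral,
        mean_genomes=means,
        generation_genomes=pops,
    )


# -- experiment schedule ---------------------------------------------------


def _epoch_frames(epochs: list[pd.DataFrame], phase: str, model: str) -> pd.DataFrame:
    frames = []
    for i, df in enumerate(epochs, start=1):
        df = df.copy()
        df.insert(0, "epoch", i)
        df.insert(0, "phase", phase)
        df.insert(0, "model", model)
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def prepare_population(
    cfg: EvolutionConfig, seed_seq: np.random.SeedSequence | None = None,
    progress: bool = False,
):
    """Equilibrate a random population: preparatory epochs under fresh,
    completely uncorrelated random environments.

    Returns ``(genomes, env, records)`` where ``env`` is the last adapted
    environment — the ancestral environment of any production run that
    follows.
    """
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(cfg.seed).spawn(2)[0]
    init_ss, *epoch_ss = seed_seq.spawn(cfg.n_prep_epochs + 1)
    rng = np.random.default_rng(init_ss)
    genomes = PopulationGenomes.random(cfg.genome, cfg.pop_size, rng)
    env = envmod.new_environment(cfg.n_env, rng)
    epochs = []
    for ep, ss in enumerate(epoch_ss, start=1):
        env_prev = env
        env = envmod.new_environment(cfg.n_env, np.random.default_rng(ss.spawn(1)[0]))
        try:
            res = run_epoch(
                genomes, env, env_prev, cfg, ss,
                measure_ancestral=False, track_genotype="none",
            )
        except ExtinctionError as exc:
            raise ExtinctionError(
                f"extinct in preparatory epoch {ep}: {exc}", epoch=ep,
                generation=exc.generation,
            ) from exc
        genomes = res.final_genomes
        epochs.append(res.records)
        if progress:
            last = res.records.iloc[-1]
            print(f"[prep {ep}/{cfg.n_prep_epochs}] mismatch "
                  f"{last.mean_mismatch_novel:.2f} genvar {last.genetic_variance:.1f}")
    return genomes, env, _epoch_frames(epochs, "prep", cfg.model)


def run_production(
    genomes: PopulationGenomes,
    env: np.ndarray,
    cfg: EvolutionConfig,
    seed_seq: np.random.SeedSequence | None = None,
    track_genotype: Literal["none", "mean", "full"] = "mean",
    progress: bool = False,
) -> ExperimentResult:
    """Production phase: each epoch flips ``env_change_fraction`` of the
    current environment and evolves in the flipped one; the pre-change
    environment is that epoch's ancestral environment."""
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(cfg.seed).spawn(2)[1]
    epoch_ss = seed_seq.spawn(cfg.n_epochs)
    environments = [env]
    epochs = []
    for ep, ss in enumerate(epoch_ss, start=1):
        env_old = env
        env = envmod.flip_environment(
            env_old, cfg.env_change_fraction, np.random.default_rng(ss.spawn(1)[0])
        )
        try:
            res = run_epoch(genomes, env, env_old, cfg, ss,
                            track_genotype=track_genotype)
        except ExtinctionError as exc:
            raise ExtinctionError(
                f"extinct in production epoch {ep}: {exc}", epoch=ep,
                generation=exc.generation,
            ) from exc
        genomes = res.final_genomes
        environments.append(env)
        epochs.append(res.records)
        if progress:
            last = res.records.iloc[-1]
            print(f"[epoch {ep}/{cfg.n_epochs}] mismatch "
                  f"{last.mean_mismatch_novel:.2f} genvar {last.genetic_variance:.1f}")
    return ExperimentResult(
        records=_epoch_frames(epochs, "production", cfg.model),
        final_genomes=genomes,
        final_env=env,
        environments=environments,
        cfg=cfg,
    )


def run_experiment(
    cfg: EvolutionConfig,
    track_genotype: Literal["none", "mean", "full"] = "mean",
    progress: bool = False,
) -> ExperimentResult:
    """Preparatory equilibration followed by the production epochs."""
    ss_prep, ss_prod = np.random.SeedSequence(cfg.seed).spawn(2)
    genomes, env, prep_records = prepare_population(cfg, ss_prep, progress=progress)
    result = run_production(
        genomes, env, cfg, ss_prod, track_genotype=track_genotype, progress=progress
    )
    frames = [df for df in (prep_records, result.records) if len(df)]
    if frames:
        result.records = pd.concat(frames, ignore_index=True)
    return result
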