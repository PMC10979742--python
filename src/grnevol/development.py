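"""Recursive hierarchical developmental dynamics (Full and NoCue models).

Development iterates four regulatory layers — epigenetic marks ``f``, gene
expression ``g``, higher-order complexes ``h`` and the expressed phenotype
``p`` — as a mutually recursive map driven by the genome matrices and, in the
Full model, by the environmental cue ``e``:

    f(s) = sigma_f( G g(s-1) + E (e - p~(s-1)) )        (Full)
    f(s) = sigma_f( G g(s-1) - E p~(s-1) )              (NoCue)
    g(s) = sigma_g( F f(s) )
    h(s) = sigma_h( H g(s) + J h(s-1) )
    p(s) = sigma_p( P h(s) )
    p~(s) = a p(s) + (1-a) p~(s-1)
    v_i(s) = (1-a) { v_i(s-1) + a [p~_i(s-1) - p_i(s)]^2 }

where ``p~`` is the exponential moving average (EMA) of the phenotype, ``v``
its EMA variance, and ``a`` the EMA weight.  The inner layers squash through
``(2/pi) arctan(gain x)`` and the phenotype through ``tanh(gain x)``, so all
state stays strictly inside (-1, 1).  Development stops when the total EMA
variance ``sum_i v_i(s)`` drops below ``conv_tol`` (converged) or at
``max_steps``; the adult phenotype is the EMA at the stopping step.

Initial conditions: f=0, g=1, h=0, p=0, p~=0; v starts at 1 per trait so the
convergence test cannot trigger spuriously before the EMA has burned in.

:func:`develop` runs one individual in float64.  :func:`develop_population`
runs a whole population (and, for the Full model, several cue sets at once)
through block-diagonal sparse matrices — the same recursion, batched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .genome import Genome, PopulationGenomes

__all__ = [
    "DevConfig",
    "DevState",
    "DevOutcome",
    "PopulationDevOutcome",
    "activation",
    "initial_state",
    "dev_step",
    "develop",
    "develop_population",
]

Model = Literal["full", "nocue"]
_LAYER_IDX = {"f": 0, "g": 1, "h": 2, "p": 3}


@dataclass(frozen=True)
class DevConfig:
    """Developmental-dynamics parameters.

    ``ema_alpha`` is the EMA weight of the phenotype average (distinct from
    the selection strength used in the fitness function).  Gains scale the
    activation inputs per layer.  The default 0.65 keeps the recursion
    slightly supercritical for the standard sparse ±1 genome (expected fan-in
    density*n = 4): strongly contractive gains collapse the cue-free dynamics
    to the origin (the phenotype then carries no trace of the genotype),
    while unit gains leave the cue-free map oscillating forever.
    """

    max_steps: int = 200
    conv_tol: float = 1e-5
    ema_alpha: float = 1.0 / 3.0
    gain_f: float = 0.65
    gain_g: float = 0.65
    gain_h: float = 0.65
    gain_p: float = 0.65

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if not self.conv_tol > 0:
            raise ValueError("conv_tol must be > 0")
        if not 0.0 < self.ema_alpha < 1.0:
            raise ValueError("ema_alpha must be in (0, 1)")

    def gain(self, layer: str) -> float:
        return getattr(self, f"gain_{layer}")


def activation(layer: str, x, gain: float = 1.0):
    """Layer activation: ``(2/pi) arctan(gain x)`` for f/g/h, ``tanh(gain x)`` for p.

    Odd, monotone, range (-1, 1).
    """
    if layer not in _LAYER_IDX:
        raise ValueError(f"unknown layer {layer!r}")
    if layer == "p":
        return np.tanh(gain * np.asarray(x, dtype=np.float64))
    return (2.0 / np.pi) * np.arctan(gain * np.asarray(x, dtype=np.float64))


@dataclass
class DevState:
    """Per-step developmental state of one individual."""

    f: np.ndarray
    g: np.ndarray
    h: np.ndarray
    p: np.ndarray
    p_ema: np.ndarray
    v: np.ndarray
    step: int = 0

    @property
    def total_variance(self) -> float:
        return float(self.v.sum())


@dataclass
class DevOutcome:
    """Adult phenotype (EMA at stopping step), step count, convergence flag."""

    adult: np.ndarray
    n_steps: int
    converged: bool


@dataclass
class PopulationDevOutcome:
    """Batched development results: one row per individual."""

    adults: np.ndarray      # (pop, n)
    n_steps: np.ndarray     # (pop,) int
    converged: np.ndarray   # (pop,) bool


def initial_state(n: int) -> DevState:
    return DevState(
        f=np.zeros(n), g=np.ones(n), h=np.zeros(n), p=np.zeros(n),
        p_ema=np.zeros(n), v=np.ones(n), step=0,
    )


def _check_cue(model: str, cue, n: int | None = None):
    if model not in ("full", "nocue"):
        raise ValueError(f"model must be 'full' or 'nocue', got {model!r}")
    if model == "nocue":
        if cue is not None:
            raise ValueError("the NoCue model takes no environmental cue")
        return None
    if cue is None:
        raise ValueError("the Full model requires an environmental cue")
    cue = np.asarray(cue, dtype=np.float64)
    if n is not None and cue.shape[-1] != n:
        raise ValueError(f"cue length {cue.shape[-1]} != n {n}")
    return cue


def dev_step(
    state: DevState,
    genome: Genome,
    cue: np.ndarray | None = None,
    model: Model = "full",
    cfg: DevConfig = DevConfig(),
) -> DevState:
    """Advance one developmental step (pure; returns a new state)."""
    cue = _check_cue(model, cue, genome.spec.n)
    a = cfg.ema_alpha
    E, F, G, H, J, P = genome.matrices
    if model == "full":
        drive = E @ (cue - state.p_ema)
    else:
        drive = -(E @ state.p_ema)
    f = activation("f", G @ state.g + drive, cfg.gain_f)
    g = activation("g", F @ f, cfg.gain_g)
    h = activation("h", H @ g + J @ state.h, cfg.gain_h)
    p = activation("p", P @ h, cfg.gain_p)
    v = (1.0 - a) * (state.v + a * (state.p_ema - p) ** 2)
    p_ema = a * p + (1.0 - a) * state.p_ema
    return DevState(f=f, g=g, h=h, p=p, p_ema=p_ema, v=v, step=state.step + 1)


def develop(
    genome: Genome,
    cue: np.ndarray | None = None,
    model: Model = "full",
    cfg: DevConfig = DevConfig(),
) -> DevOutcome:
    """Run development to convergence (or max_steps) for one individual.

    Deterministic given (genome, cue, model, cfg).  Non-convergence is a
    reported outcome, not an error.
    """
    _check_cue(model, cue, genome.spec.n)
    state = initial_state(genome.spec.n)
    for _ in range(cfg.max_steps):
        state = dev_step(state, genome, cue, model, cfg)
        if state.total_variance < cfg.conv_tol:
            return DevOutcome(state.p_ema.copy(), state.step, True)
    return DevOutcome(state.p_ema.copy(), state.step, False)


def develop_population(
    genomes: PopulationGenomes,
    cues: np.ndarray | Sequence[np.ndarray] | None = None,
    model: Model = "full",
    cfg: DevConfig = DevConfig(),
) -> PopulationDevOutcome | list[PopulationDevOutcome]:
    """Develop every individual of a population in one batched recursion.

    Parameters
    ----------
    cues
        For the Full model, either one (pop, n) array of per-individual cues
        or a sequence of such arrays (e.g. cues drawn from the novel and the
        ancestral environment); all cue sets share the genome matrices and
        run as columns of one state matrix.  Must be None for NoCue.

    Returns one :class:`PopulationDevOutcome` per cue set (a bare outcome if
    a single array — or None for NoCue — was passed).
    """
    pop, n = genomes.pop_size, genomes.spec.n
    single = False
    if model == "nocue":
        _check_cue(model, cues)
        cue_mat = np.zeros((pop * n, 1))
        ncol = 1
        single = True
    else:
        if cues is None:
            raise ValueError("the Full model requires an environmental cue")
        if isinstance(cues, np.ndarray) and cues.ndim == 2:
            cues = [cues]
            single = True
        cue_arrs = []
        for c in cues:
            c = np.asarray(c, dtype=np.float64)
            if c.shape != (pop, n):
                raise ValueError(f"each cue set must have shape {(pop, n)}")
            cue_arrs.append(c.reshape(pop * n))
        cue_mat = np.stack(cue_arrs, axis=1)
        ncol = len(cue_arrs)

    E, F, G, H, J, P = (genomes.block_csr(m) for m in range(6))
    a = cfg.ema_alpha
    cf, cg, ch, cp = cfg.gain_f, cfg.gain_g, cfg.gain_h, cfg.gain_p
    two_over_pi = 2.0 / np.pi

    # batched state, one column per cue set
    g = np.ones((pop * n, ncol))
    h = np.zeros((pop * n, ncol))
    p_ema = np.zeros((pop * n, ncol))
    v = np.ones((pop * n, ncol))

    adults = np.zeros((ncol, pop, n))
    n_steps = np.full((ncol, pop), cfg.max_steps, dtype=np.int64)
    converged = np.zeros((ncol, pop), dtype=bool)
    done = np.zeros((pop, ncol), dtype=bool)

    # active-individual compaction bookkeeping
    orig = np.arange(pop)

    for step in range(1, cfg.max_steps + 1):
        if model == "full":
            drive = E @ (cue_mat - p_ema)
        else:
            drive = -(E @ p_ema)
        f = two_over_pi * np.arctan(cf * (G @ g + drive))
        g = two_over_pi * np.arctan(cg * (F @ f))
        h = two_over_pi * np.arctan(ch * (H @ g + J @ h))
        p = np.tanh(cp * (P @ h))
        v = (1.0 - a) * (v + a * (p_ema - p) ** 2)
        p_ema = a * p + (1.0 - a) * p_ema

        tot = v.reshape(-1, n, ncol).sum(axis=1)  # (k_active, ncol)
        newly = (tot < cfg.conv_tol) & ~done
        if newly.any():
            for c in range(ncol):
                hit = np.nonzero(newly[:, c])[0]
                if hit.size:
                    gi = orig[hit]
                    adults[c, gi] = p_ema.reshape(-1, n, ncol)[hit, :, c]
                    n_steps[c, gi] = step
                    converged[c, gi] = True
            done |= newly
        if done.all():
            break

        # shrink the batch once most individuals have finished
        active = ~done.all(axis=1)
        k = active.sum()
        if k and k <= done.shape[0] // 2 and step < cfg.max_steps:
            idx = np.nonzero(active)[0]
            rows = (idx[:, None] * n + np.arange(n)).ravel()
            E, F, G, H, J, P = (M[rows][:, rows] for M in (E, F, G, H, J, P))
            g, h, p_ema, v = (
                x.reshape(-1, n, ncol)[idx].reshape(-1, ncol) for x in (g, h, p_ema, v)
            )
            cue_mat = cue_mat.reshape(-1, n, ncol)[idx].reshape(-1, ncol)
            done = done[idx]
            orig = orig[idx]

    if not done.all():
        pe = p_ema.reshape(-1, n, ncol)
        for c in range(ncol):
            left = np.nonzero(~done[:, c])[0]
            adults[c, orig[left]] = pe[left, :, c]

    outs = [
        PopulationDevOutcome(adults[c], n_steps[c], converged[c]) for c in range(ncol)
    ]
    return outs[0] if single else outs
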