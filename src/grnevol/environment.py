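"""±1 environment vectors: the selector/inducer duality.

A single environment vector ``e`` plays two roles: as *selector* it is the
optimal phenotype entering the fitness function, and as *inducer* it is the
source of each individual's noisy developmental cue.  Environments are plain
1-d numpy arrays whose elements are exactly +1 or -1 (stored as ``int8``).

Environmental change is modeled by flipping an exact number of elements,
``k = round(fraction * n_env)`` (half away from zero), chosen uniformly
without replacement.  With exact flip counts the correlation between the
vectors before and after a change is the identity ``1 - 2k/n_env``: flipping
50% of a 200-element vector gives correlation 0, flipping 90% gives -0.8.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "new_environment",
    "flip_environment",
    "generate_cue",
    "generate_cues",
    "env_correlation",
    "flip_count",
    "save_environment",
    "load_environment",
]


def _validate_env(env: np.ndarray, name: str = "env") -> np.ndarray:
    env = np.asarray(env)
    if env.ndim != 1 or env.size < 1:
        raise ValueError(f"{name} must be a non-empty 1-d vector")
    if not np.isin(env, (-1, 1)).all():
        raise ValueError(f"{name} elements must all be +1 or -1")
    return env.astype(np.int8, copy=False)


def flip_count(n_env: int, fraction: float) -> int:
    """Number of elements flipped for a given change magnitude.

    Exact count ``round(fraction * n_env)``, rounding halves away from zero.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    return int(math.floor(fraction * n_env + 0.5))


def new_environment(n_env: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a fresh environment: each element +1 or -1 with equal probability."""
    if int(n_env) < 1:
        raise ValueError(f"n_env must be a positive integer, got {n_env}")
    return (2 * rng.integers(0, 2, size=int(n_env)) - 1).astype(np.int8)


def flip_environment(
    env: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip exactly ``round(fraction * n_env)`` distinct elements of ``env``.

    Positions are chosen uniformly without replacement; the input is not
    modified.
    """
    env = _validate_env(env)
    k = flip_count(env.size, fraction)
    out = env.copy()
    if k:
        idx = rng.choice(env.size, size=k, replace=False)
        out[idx] = -out[idx]
    return out


def generate_cue(
    env: np.ndarray, noise_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Derive one individual's environmental cue from the macro-environment.

    The cue is the environment with an exact ``round(noise_fraction * n_env)``
    elements flipped at fresh uniformly-chosen positions: micro-environmental
    noise experienced during a single development.
    """
    return flip_environment(env, noise_fraction, rng)


def generate_cues(
    env: np.ndarray, noise_fraction: float, n_cues: int, rng: np.random.Generator
) -> np.ndarray:
    """Batch of independent cues, one row per individual.

    Equivalent to stacking ``n_cues`` calls of :func:`generate_cue`; the flip
    sets are sampled via per-row partial argsorts so the whole population's
    cues come from one vectorized draw.
    """
    env = _validate_env(env)
    n = env.size
    k = flip_count(n, noise_fraction)
    cues = np.tile(env, (int(n_cues), 1))
    if k:
        # k smallest of i.i.d. uniforms per row = uniform k-subset w/o replacement
        u = rng.random((int(n_cues), n))
        idx = np.argpartition(u, k - 1, axis=1)[:, :k]
        np.put_along_axis(cues, idx, -np.take_along_axis(cues, idx, axis=1), axis=1)
    return cues


def env_correlation(e1: np.ndarray, e2: np.ndarray) -> float:
    """Normalized inner product ``(e1 . e2) / n_env`` of two ±1 vectors.

    Coincides with the Pearson correlation when element means vanish, and for
    a k-flip pair equals ``1 - 2k/n_env`` exactly.
    """
    e1 = _validate_env(e1, "e1")
    e2 = _validate_env(e2, "e2")
    if e1.size != e2.size:
        raise ValueError(f"length mismatch: {e1.size} != {e2.size}")
    return float(np.dot(e1.astype(np.int64), e2.astype(np.int64))) / e1.size


def save_environment(path, env: np.ndarray) -> None:
    """Write an environment (or cue) as a one-row CSV of ±1 integers."""
    env = _validate_env(env)
    with open(path, "w") as fh:
        fh.write(",".join(str(int(x)) for x in env) + "\n")


def load_environment(path) -> np.ndarray:
    with open(path) as fh:
        row = fh.readline().strip()
    return _validate_env(np.array([int(x) for x in row.split(",")]))
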