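"""Small deterministic fixtures: toy genomes, environments, worked traces."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .development import DevConfig, dev_step, initial_state
from .environment import new_environment, save_environment
from .genome import GenomeSpec, random_genome, save_genome_triplets

__all__ = ["make_fixtures", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("toy-genome", "toy-environment", "worked-development")


def make_fixtures(kind: str, out_dir, rng: np.random.Generator) -> list[Path]:
    """Write small deterministic fixture files; returns the paths written.

    * ``toy-genome`` — n=3 and n=10 genomes in the sparse-triplet text format.
    * ``toy-environment`` — ±1 environment CSVs of lengths 4, 10 and 200.
    * ``worked-development`` — a step-by-step JSON trace of the development
      recursion (Full and NoCue) on an n=3 toy genome and cue.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "toy-genome":
        for n, density in ((3, 0.4), (10, 0.1)):
            g = random_genome(GenomeSpec(n=n, density=density), rng)
            path = out_dir / f"toy_genome_n{n}.txt"
            save_genome_triplets(path, g)
            written.append(path)
    elif kind == "toy-environment":
        for n in (4, 10, 200):
            path = out_dir / f"toy_environment_n{n}.csv"
            save_environment(path, new_environment(n, rng))
            written.append(path)
    elif kind == "worked-development":
        spec = GenomeSpec(n=3, density=0.4)
        genome = random_genome(spec, rng)
        cue = new_environment(3, rng)
        cfg = DevConfig(max_steps=5)
        trace: dict = {
            "n": 3,
            "matrices": {
                label: genome.matrices[i].tolist()
                for i, label in enumerate("EFGHJP")
            },
            "cue": cue.tolist(),
            "ema_alpha": cfg.ema_alpha,
            "gains": [cfg.gain_f, cfg.gain_g, cfg.gain_h, cfg.gain_p],
            "steps": {"full": [], "nocue": []},
        }
        for model in ("full", "nocue"):
            state = initial_state(3)
            for _ in range(cfg.max_steps):
                state = dev_step(
                    state, genome, cue if model == "full" else None, model, cfg
                )
                trace["steps"][model].append(
                    {k: getattr(state, k).tolist()
                     for k in ("f", "g", "h", "p", "p_ema", "v")}
                )
        path = out_dir / "worked_development_n3.json"
        with open(path, "w") as fh:
            json.dump(trace, fh, indent=1)
        written.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    return written
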