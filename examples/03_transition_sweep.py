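"""Sweep the magnitude of environmental change and watch robustness break.

Equilibrates a small Full-model population, then measures first-generation
responses (before selection) to environmental flips of increasing magnitude:
the mean projected phenotype (plastic response), its variance (uncovered
cryptic variation), and the leading singular values of the Pheno-Cue and
Pheno-Geno cross-covariance matrices (susceptibility to environmental noise
and to genetic variation).

Runs in a couple of minutes.
"""

from grnevol import EvolutionConfig, FitnessParams, GenomeSpec
from grnevol.analysis import detect_transition, transition_sweep
from grnevol.evolution import prepare_population

cfg = EvolutionConfig(
    n_env=100, pop_size=100, generations_per_epoch=30,
    n_epochs=0, n_prep_epochs=8,
    genome=GenomeSpec(n=100, density=0.02),
    fitness=FitnessParams(n_selected_traits=20),
    seed=11,
)

genomes, env, _ = prepare_population(cfg, progress=True)
table = transition_sweep(
    genomes, env, cfg, magnitudes=[0.05, 0.15, 0.25, 0.35, 0.5],
    epochs_per_magnitude=4,
)
med = table.groupby("magnitude")[
    ["mean_proj_pheno", "var_proj_pheno", "sv1_pheno_cue", "sv1_pheno_geno"]
].median()
print(med.round(4))
loc = detect_transition(table, "mean_proj_pheno")
print(f"detected transition (mean projected phenotype > 3x the 5% baseline): {loc}")
print("The cue-induced response grows with the magnitude of change.  At this "
      "small scale the growth is gradual (the detector typically reports "
      "None); the sharp robustness breakdown emerges only after long "
      "full-scale preparatory equilibration.")
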