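# Methods

## The model

`grnevol` simulates the evolution of a hierarchical, recurrent
gene-regulatory-network (GRN) model of development in which a single
environment vector plays two roles: *selector* (it is the optimal phenotype
entering the fitness function) and *inducer* (each individual develops under
a noisy copy of it, the environmental cue).  The point of the model is the
transition between two evolutionary regimes of one and the same
developmental system: mutation-led evolution (MLE) under small environmental
changes, where the developmental system is robust and adaptation waits for
favorable mutations, and plasticity-led evolution (PLE) under large changes,
where robustness breaks down, the cue induces adaptive plastic responses,
cryptic genetic variation is uncovered, and selection then genetically
accommodates the induced phenotype.

### Environment

The environment is a vector **e** of n = 200 elements, each exactly ±1.
Environmental change flips an exact count k = round(f·n) of uniformly chosen
positions (half-away-from-zero rounding).  With exact counts the
correlation of the changed vector with the original, computed as the
normalized inner product (e·e′)/n, is the identity 1 − 2k/n: flipping 50%
gives 0, flipping 90% gives −0.8.  A per-element Bernoulli flip would only
satisfy these in expectation, which is why the exact-count convention is
used.  Cues are fresh exact-count flips (default 5%) drawn independently per
individual per development — micro-environmental noise, not a
per-epoch constant.

### Genome and development

A genome is the ensemble of six sparse n×n matrices (E, F, G, H, J, P),
each at density 0.02 (800 nonzeros), nonzero values ±1 with equal
probability by default (a Gaussian alphabet is configurable).  Development
iterates epigenetic marks f, gene expression g, higher-order complexes h and
the expressed phenotype p:

    f(s) = σ_f(G g(s−1) + E(e − p̃(s−1)))     (Full; NoCue drops the cue e)
    g(s) = σ_g(F f(s))
    h(s) = σ_h(H g(s) + J h(s−1))
    p(s) = σ_p(P h(s))

with p̃ the exponential moving average (EMA) of p and v its EMA variance.
Development stops when Σ_i v_i < 10⁻⁵ (converged) or after 200 steps.  The
adult phenotype is p̃ at the stopping step.  Initial conditions: f = 0,
g = **1**, h = 0, p = 0, p̃ = 0 and v = 1 per trait; starting v at 1 forces a
genuine burn-in (≈42 steps at the default EMA weight) so convergence cannot
trigger before the EMA is informative.

Numerical/structural choices that the model statement leaves open:

* **Activations.** σ_f, σ_g, σ_h are (2/π)·arctan(gain·x), σ_p is
  tanh(gain·x) — odd, monotone, range (−1, 1).  The gain defaults to 0.65
  per layer.  This value was chosen against two failure modes of the
  standard sparse genome (expected fan-in = density·n = 4): at gain 1 the
  cue-free recursion essentially never meets the convergence criterion
  (sustained oscillation — a NoCue population would go extinct at its first
  generation), while at gain ≤ 0.5 the odd cue-free map contracts to the
  origin, the adult phenotype becomes identically 0 for every genotype, and
  selection is blind.  0.65 keeps the dynamics slightly supercritical:
  nearly all Full-model random genomes converge, a workable minority
  (~20%) of NoCue random genomes converge (selection for convergence fixes
  the rest within ~10 generations), and attractors are genotype-dependent.
  All four gains are configurable.
* **EMA weight.** The phenotype-average weight α defaults to 1/3.  It is a
  distinct named parameter (`ema_alpha`) from the selection strength α = 20
  of the fitness function (`alpha_sel`).
* **The v recursion** is applied per trait (the only dimensionally
  consistent reading); its fixed point under constant squared innovation Δ²
  is (1−α)·Δ².
* **Order within a step** is strictly f → g → h → p → p̃ → v, with f using
  g(s−1) and h using h(s−1); the convergence test is evaluated on the total
  EMA variance after each full step.

### Genetic algorithm

Raw fitness is ω = exp(−(20·L1 + N_step/20)) where L1 is the mismatch — the
L1 distance between adult phenotype and environment over the first 40 of
200 traits (the other 160 evolve free) — and N_step the developmental step
count.  Non-converged individuals get zero fitness.  All fitness arithmetic
is in log space (20·L1 can reach ≈1600, far beyond float range after
exponentiation); normalized fitness Ω_i = exp(log ω_i − max_j log ω_j) is
invariant under constant log shifts by construction.  Parents are drawn by
acceptance-rejection roulette: uniform draws accepted with probability Ω_i,
with replacement, consecutive acceptances paired (selfing is allowed — the
sampler places no exclusion).  Each pair produces two offspring by
row-linkage crossover — for every row index, with probability 1/2 the rows
of *all six* matrices are exchanged, so one gene's entire incoming
regulation travels as one block — followed by point mutation: every element
slot is independently resampled with probability 0.005 from the marginal
element distribution (zero with probability 1 − density, else a fresh
alphabet value), which preserves density in expectation without any global
renormalization.

Each generation the offspring genomes develop twice — under cues from the
novel environment (these outcomes feed fitness and selection) and under
cues from the ancestral environment (measurement only, discarded).  The
NoCue model develops once and reuses the outcome for both contexts, which
is exact because its development takes no environmental input.  An *epoch*
is 200 generations (50 in the desk preset) under one fixed environment.  An
experiment runs preparatory epochs under completely uncorrelated fresh
random environments (40 at full scale) to equilibrate the random initial
population, then production epochs, each preceded by flipping the
configured fraction of the current environment.  A whole population of
non-converged individuals raises a labeled extinction error rather than
silently continuing.

During preparatory epochs the ancestral-context development is skipped:
those measurements are never analyzed, and the measurement stream is
separated from the evolution stream (per-generation substreams spawned from
the master seed) precisely so that skipping it cannot alter the trajectory.

### Analysis statistics

* **Projections.** The phenotype axis joins the ancestral and novel
  environments restricted to the 40 selected traits; projections of 0/1 mean
  perfect adaptation to the ancestral/novel optimum.  The genotype axis
  joins the population-mean vectorized genomes (all six matrices flattened,
  row-major, label order E F G H J P) of the first and last generation of an
  epoch.  Because the genotype axis only exists once the epoch has ended,
  per-generation mean genotype projections are filled in post hoc from
  stored per-generation mean genome vectors; per-individual genotype
  projection spreads require keeping every generation's population
  (`track_genotype="full"`), which is intended for small configurations.
  Degenerate axes (no environmental change, or no genetic change over the
  epoch) raise an error rather than returning NaN from the analysis
  functions; trajectory records store NaN for the projection columns in
  that case.
* **Cross-covariances.**  C = (1/N)·Pᶜ (Xᶜ)ᵀ with divisor N and both sides
  centered; the phenotype side uses the 40 selected traits, the covariate
  side the full 200-element cues (Pheno-Cue) or the full 6n²-element
  vectorized genomes (Pheno-Geno).  The 40-trait phenotype side is forced
  by the alignment statistic, which dots the leading left singular vector
  with the 40-element environmental change; it is configurable through
  `n_selected_traits`.
* **SVD.**  For wide matrices (Pheno-Geno: 40 × 240 000) the decomposition
  runs through the 40×40 Gram matrix C Cᵀ (identical singular values and
  left vectors; right vectors recovered as Cᵀu/σ), otherwise directly.
  Left-vector signs follow the first-nonzero-nonnegative convention so
  outputs are reproducible.  Developmental bias is σ₁²/Σσ_i²; alignment is
  |u₁·(e_n − e_a)|/‖e_n − e_a‖.
* **Sweep.**  From an equilibrated snapshot, for each magnitude and
  replicate: flip the environment, develop the first generation (no
  selection), record mean/variance of projected phenotype, both first
  singular values, both bias proportions and both alignments.  The
  transition detector flags the smallest magnitude whose median statistic
  exceeds a configurable multiple (default 3×) of the smallest-magnitude
  baseline median; nothing is auto-fitted.

## Implementation notes

Genomes of a population are stored as sparse triplet arrays (individual,
matrix, row, column, value).  Development of a whole population runs
through six block-diagonal CSR matrices, with the novel- and
ancestral-context developments as two columns of one batched state matrix;
individuals that have converged are frozen and the active batch is
compacted.  Crossover is a vectorized relabeling of the individual index;
mutation samples the Bernoulli sieve over element slots by geometric gaps.
The batched path and the single-individual float64 path agree to ~1e-10
relative; both are deterministic given (genome, cue, config).  A master
seed drives a SeedSequence tree (per phase, per epoch, per generation, with
separate measurement and evolution substreams), so runs are reproducible
and measurement toggles cannot perturb evolution.

## Scales, defaults, and what the synthetic conditions do (and do not) show

Full-scale study conditions (population 1000, 200 traits, 200
generations/epoch, 40 preparatory epochs) are the configuration defaults.
Tests and the acceptance script run reduced scales chosen for single-CPU
turnaround: the `desk` preset (population 200, 50 generations/epoch, 3
preparatory + 3 production epochs, three seeds) for the PLE/MLE contrast
and for the magnitude sweep, and a population-100, 40-generation,
8-preparatory-epoch configuration for the acceptance script.

Reduced scale reproduces the qualitative signatures: the generation-1
adaptive plastic response under 50% change (novel-context projections above
ancestral-context ones), immediate mismatch decline in the Full model, and
monotone growth of the cue-induced response with change magnitude.  It does
*not* reproduce quantitative full-scale features: the sharp transition
location (~30% change), the bias-proportion transition (~25%), or the
NoCue model's 20–30-generation adaptation delay, all of which depend on the
deep canalization built up over 40 full-length preparatory epochs.  Equally,
shortened preparation leaves the Full model's cue processing imperfectly
tuned, so its residual mismatch under small changes remains above the NoCue
model's at desk scale, where the full-scale study finds the two models'
small-change trajectories nearly identical.

The synthetic generator *is* the study design (there is no external data):
±1 environments, exact-count flips and cues, ±1 sparse genomes.  None of
this emulates features of real regulatory networks such as unequal layer
sizes, signed-degree heterogeneity, or continuous environmental gradients;
passing tests demonstrate properties of the model, not of any biological
dataset.

## Known limitations

* The activation scaling (gain 0.65) is a package choice inside the band of
  viable near-critical values; quantitative statistics (singular values,
  variance levels) shift with it, though the qualitative regime structure
  does not.
* Selection noise is inherent to cue-driven fitness (each individual is
  evaluated on one noisy cue); no fitness averaging over cues is performed,
  matching the protocol.
* Diploidy, linkage maps beyond whole-row blocks, variable population size
  and alternative GA schemes (tournament, elitism) are out of scope.
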