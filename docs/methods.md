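# Methods

## The screening model

`pepscreen` frames library screening as goal-conditioned navigation of a 2D
projection of chemical space. The assumptions behind that framing:

* Activity is *clustered*: peptides with high predicted cell inhibition
  concentrate in regions ("activity cliffs") of a low-dimensional embedding
  of the library, because the drivers of membranolytic activity (charge,
  amphipathicity, hydrophobicity) are smooth functions of composition and
  arrangement.
* The oracle is expensive relative to navigation: scoring a peptide
  dominates cost, so the quantity to minimize is unique oracle calls, not
  steps.
* A policy trained on a random subset transfers to the remainder because
  batches are drawn from the same distribution and projected through the
  frozen training-subset projector (same standardization, loadings and
  min–max extremes).

The agent's kinematics are deliberately smooth: each action scales the
previous displacement by λ ∈ [0.95, 1.05] and rotates it by θ ∈ [−π/3, π/3].
Bounds are enforced by a tanh squash of a Gaussian policy, never by
rejection, so gradients are unbiased and 100% of sampled actions are legal.

### Episode structure and the goal bonus

An episode ends in exactly three cases: the agent leaves the board
(position outside [−1−m, 1+m]²), a peptide more potent than the current
target's best is discovered (the hotspot set is extended and the episode
ends as `goal_updated`), or the step limit is reached. Reaching the goal
disc is a *location class*, not a termination: the agent is paid
`goal_bonus` for every step it holds the disc. This makes "navigate to the
hotspot, then stay and sweep it" the optimal behavior, which is also
exactly the behavior inference screening exploits. A goal-terminating
variant (`EnvConfig.terminate_on_goal=True`) exists for episodic evaluation.

Two geometric constraints tie the environment parameters together. The
tightest circle the agent can fly has radius ℓ₀ / (2·sin(θ_max/2)) = ℓ₀, so
the goal radius must satisfy ε_goal > ℓ₀ or holding the disc is physically
impossible. Defaults: ℓ₀ = 0.01 × board diagonal ≈ 0.028 and ε_goal = 0.08.
The pickup radius defaults to ε = sqrt(4/(πN)) — one expected library point
per ε-disc under uniform density — so pickup rates are scale-free in N.

### Reward

r = β₁·r_dist + β₂·r_oracle + β₃·r_penalty (+ goal bonus), with defaults
β = (1, 1, 1), κ = 0.01, goal_bonus = 1.0/step:

* r_dist = (d_before − d_after)/ℓ₀ — a potential-based shaping term, at most
  ~1 per step in magnitude;
* r_oracle = max(new predictions)/100 — paid only for *newly* scored
  peptides, the intrinsic-motivation term that rewards sweeping fresh
  potent ground;
* r_penalty = −κ per step.

During training the board's visit registry is reset at each PPO iteration so
r_oracle keeps paying for sweeping behavior across iterations; a memoizing
oracle cache guarantees each unique peptide is still scored at most once,
preserving the conservation identity (unique oracle calls = unique peptides
visited) that the search-space-reduction metric relies on.

### Hotspot bandit

Returns observed at a hotspot are modeled as Normal with unknown mean and
variance under a Normal–Inverse-Gamma prior (μ₀ = 0, κ₀ = 1, α₀ = 2,
β₀ = 1, i.e. prior σ ≈ 1). Posterior draws are exact (variance from an
inverse gamma, mean from a Normal given the variance), so "posterior
sampling" is deterministic up to the seed. The observation recorded is the
**per-step** episode return, which puts observations on the ~unit scale the
prior assumes; with raw returns (hundreds), unexplored arms would be locked
out of Thompson selection, and the bandit demonstrably fixates on the first
arm observed — including "false cliffs", isolated high-activity peptides
with no neighborhood to harvest. σ_i is the posterior scale of the mean,
sqrt(β_n/(α_n·κ_n)), not the predictive scale. Hotspots closer than the
goal radius merge, keeping the higher best-prediction.

Cold start: before any discovery, 100 random peptides are probed and one
hotspot is seeded at the best scorer's location.

### PPO

Defaults: clip 0.2, γ 0.99, learning rate 3e-4, 10 epochs per update,
minibatch 64, entropy coefficient c = 0.01 with the entropy term *added* to
the maximized objective, policy/value MLPs 64×64. The advantage is, by
default, the literal Q_ψ(s, a) − V_ψ(s) with both networks regressed on
discounted empirical returns each iteration; generalized advantage
estimation is a config switch. The policy input augments the state
(position, goal, distance, heading) with the heading-frame bearing of the
goal (cos/sin), which makes turn control near-linear in the features and is
what makes training converge reliably in ~15 iterations × 1500 steps.

### Inference screening

Per batch, trajectories draw a goal from the frozen hotspot Gaussians,
navigate, and *collect only after first entering the goal disc* — the agent
identifies a promising region and then explores its local neighborhood;
transit through inactive space costs no oracle calls. En-route collection
is available (`StopConfig.collect_en_route`). A batch stops when any of
these fires:

* the running mean of all scored predictions drops below 40% (evaluated
  only after 50 peptides) — the potency stopping rule;
* a per-batch oracle-call budget is exhausted (the analogue of screening
  only the top few percent of each batch; the packaged benchmark uses 250
  calls per 10,000-peptide batch);
* 25 consecutive trajectories yield no fresh pickups (neighborhoods
  exhausted), or the 500-trajectory outer budget is reached.

The scored *stream* (all pickups, in order) drives the stopping rule; the
collected set S keeps only predictions ≥ 40% (the collection floor). The
hotspot posteriors and projector are verified bit-identical before and
after a batch screen.

## The fusion QSAR oracle

Inputs: the 431-feature panel (11 global descriptors, AAC 20, DPC 400) into
an MLP branch (128, 64, ReLU), and the 15×22 per-residue encoding (one-hot
+ Eisenberg hydrophobicity + charge sign; zero-padded) into a CNN branch
(two 1D convolutions, 32 filters, kernels 3 and 5, global max-pool); trunk
64 with dropout 0.1; 2-output regression head trained with masked MSE on
labels/100; optional binary head trained in a second phase on its own
dataset with only the head's parameters moving. Adam 3e-3, 150 epochs,
batch 32, early stopping on a 10% validation split (patience 40), all
seeded. After per-feature standardization, each composition block is scaled
by 1/sqrt(block size); without this the 400 DPC features drown the 11
informative global descriptors (held-out Pearson drops from ~0.9 to ~0.55
on the scaffold dataset). Small capacity throughout: the reference training
set has 210 labeled peptides.

Cross-validation stratifies folds by label quantile, re-draws folds per
seed, and reports Pearson r aggregated over folds × seeds; zero-variance
folds are flagged as degenerate rather than averaged in. The single-branch
MLP baseline (`baseline_mlp`, sklearn MLPRegressor) uses identical fold
assignments for a controlled feature-family comparison.

Descriptor conventions: EMBOSS pKa set with Henderson–Hasselbalch charge;
isoelectric point by bisection on [0.01, 13.99] to 1e-4 (boundary returned
and flagged when the charge never crosses zero, e.g. fully amidated basic
peptides); Eisenberg consensus hydrophobicity with 100°/residue helical
periodicity for the moment; Guruprasad dipeptide weights for the
instability index; monoisotopic masses with a −0.984 Da amidation
correction. Amidation defaults to true for activity prediction (the
reference scaffold is C-terminally amidated) and false for generic
descriptor reporting.

## The synthetic data generator

The generator emulates the *structure* the method assumes, with full
control and a known ground truth:

* **Landscape**: activity = 100·logistic(w·z + b) where z standardizes
  (net charge, hydrophobic moment, hydrophobic ratio) against a fixed
  internal background population. Two heads share features but not weights
  (MDA-like: w = (1.2, 1.0, 0.6), b = −2.5; PBMC-like: w = (0.3, 0.5, 1.5),
  b = −2.2), giving correlated but non-interchangeable targets (r ≈ 0.5–0.7)
  so selectivity filtering has discordant cases to act on. Background
  peptides average ~16–20% activity with ~13% above the 40% floor; planted
  actives average ~90%.
* **Library**: round(p·N) actives (default p = 0.05) generated by mutating
  K/L-rich amphipathic templates (12% per-position substitution, occasional
  N-terminal crops), the rest composition-random 5–15-mers. Actives cluster
  compositionally, hence spatially after projection — the planted activity
  cliff.
* **Scaffold dataset**: the wild type plus single substitutions of the
  14-mer Mastoparan scaffold in fixed position-major order (266 possible;
  n = 210 default), labels = landscape activity + Gaussian noise (sd 5),
  clipped to [0, 100].

What it does **not** emulate: real structural constraints (helicity), label
heteroscedasticity and batch effects of cell assays, the redundancy
structure of sliding-window libraries, or realistic embedding geometry
beyond "actives cluster". Passing tests therefore demonstrate that the
machinery finds planted, clustered signal under honest accounting — not
that it would rank real peptides correctly; that depends entirely on the
quality of the trained oracle and embeddings supplied.

## Packaged benchmark problem sizes

The reference experiment (`pepscreen.protocols.reduction_benchmark`, also
run by `scripts/acceptance.py`) uses: 100,000 peptides, 5% actives, a
10,000-peptide training subset (15 PPO iterations × 1500 steps, episode cap
300), 9 screening batches with 250 oracle calls budget each and a 200-step
rollout cap. These sizes make the full experiment run in about a minute on
one CPU while leaving the accounting identical to a large-scale run. Across
seeds 0–11 the measured reduction is 90–96% with collected-set ground-truth
means of 89–99% versus a library mean of ~20%.

## Known limitations

* 2D projection loses information; distinct peptides can overlap, and the
  ε-disc pickup rule is a reconstruction of "the agent found a peptide" in
  continuous coordinates.
* The literal Q−V advantage is noisier than GAE; it is kept as the default
  for fidelity to the stated formulation, and both value networks are fit
  to the same return targets.
* Policy quality varies across seeds more than the screening outcome does:
  the stopping rules and call budget bound the damage of a weak policy, but
  collected-set quality is policy-dependent.
* The bandit assumes stationary arm distributions; within a batch,
  neighborhood exhaustion makes arms effectively non-stationary, which the
  idle-trajectory stop absorbs rather than models.
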