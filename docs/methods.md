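# Methods

`ehrmtl` studies when multitask learning (MTL) helps supervised electronic
phenotyping — deciding from a patient's coded medical history whether they
have a condition of interest — on sparse, heavily imbalanced binary feature
data. Because real clinical-warehouse data cannot be redistributed, the
package pairs the full experimental protocol with a synthetic cohort
generator whose statistical structure matches what the protocol assumes.
This note records the models, the generator, the numerical choices, and what
the desk-scale experiments do and do not show.

## The phenotyping problem and the three model families

Each patient is a multi-hot binary vector: one indicator per code in an
abstract vocabulary (stand-ins for diagnosis/procedure/drug indicators) plus
indicators for each demographic level (integer age 0–99, sex, race,
ethnicity). A target phenotype is a binary label, typically rare (prevalence
well under 1%). Three families are compared:

- **STNN** — a feed-forward net: input → (linear → batch norm → ReLU) × L →
  a single sigmoid head, minimizing binary cross-entropy.
- **MTNN** — the same trunk shared by K+1 sigmoid heads (hard parameter
  sharing): the target head plus one head per auxiliary task. Auxiliary
  tasks are *phecode-style* labels — a patient is positive for a group if
  their code set intersects the group's member codes — sampled from groups
  whose prevalence lies in a fixed band (0.08%–2.95% by default). The loss
  is a weighted mean of the per-task cross-entropies. The library default
  is the unweighted mean; per-task weights are exposed (a weight of 0
  provably reduces the trunk trajectory to the single-task one, which is
  asserted in a test), and the protocol offers a *target-balanced* mode in
  which the target carries half the loss and the auxiliaries share the
  other half. The reference study uses the balanced mode: under a fixed
  optimization budget the unweighted mean slows target-head training in
  proportion to the number of auxiliaries, which confounds the
  representation-sharing effect under study with plain gradient dilution.
- **LR** — L1-regularized logistic regression over the same features, with
  the penalty strength chosen on the validation set from 7 log-spaced
  values. This is the strong linear baseline; ties favor the stronger
  penalty.

Training uses Xavier-uniform initialization, Adam (β₁ = 0.9, β₂ = 0.99), a
fixed budget of 6 epochs, and per-epoch early stopping on the **target**
task's validation AUPRC (auxiliary heads get no say). The canonical
hyperparameter grid crosses depth (1, 2), width (128, 256, 512, 1024, 2048)
and initial learning rate (1e-4, 5e-5): 20 configurations.

Evaluation uses AUPRC via the average-precision estimator (step
interpolation; tied scores handled group-wise, so a constant scorer earns
exactly the prevalence). Under extreme imbalance AUPRC is far more
informative than AUROC. Model selection is disciplined: test AUPRC is
computed for every run but "optimal" always means best *validation* AUPRC;
every selection is written to an audit log. Ties break toward fewer layers,
smaller width, lower learning rate.

## The protocol

For each of `n_splits` repetitions the cohort is split into stratified
train/validation/test partitions (80/10/10), with positives and negatives
allocated separately by floor + largest-remainder rounding, so each
partition's target prevalence matches the overall prevalence up to integer
rounding. Per split, the protocol runs the STNN grid, the MTNN grid at each
auxiliary-set size, and the LR path. Auxiliary sets are nested by
construction: the largest set is drawn uniformly from the eligible groups,
smaller sets are prefixes of it. Every training run's seed derives
deterministically from (master seed, split, family, auxiliary size, grid
index), so a protocol re-run is bit-identical.

## The synthetic cohort generator

Patients are generated from independent latent disease factors. Factor *f*
is active with probability `latent_prevalences[f]`; an active factor emits
each of its associated codes independently with a per-code probability
(noisy-OR-style), on top of a spontaneous per-code background rate. This
induces code co-occurrence blocks — the structure MTL exploits, since a
phenotype rule over a factor's codes and phecode groups drawn from the same
factor's codes share a latent cause. Demographics are sampled with fixed
plausible marginals and carry no outcome signal by default.

Target phenotypes are flat DNF rules (OR of AND clauses) over a small
ordered list of *oracle codes*, with optional required-absent literals, and
optionally requiring a per-patient **hidden flag** (Bernoulli, default rate
0.75). The hidden flag is generative state that never enters the feature
matrix; it stands in for the temporal predicates of real rule-based
phenotype definitions that a bag-of-codes representation cannot see, and it
caps the achievable AUPRC strictly below 1. Label noise (independent flips)
is available but defaults to 0.

What the generator does **not** emulate: timestamps, visit structure,
longitudinal dynamics, code semantics, realistic long-tailed code-frequency
profiles, or demographic confounding. Passing the desk-scale experiments
therefore shows that the pipeline recovers the qualitative phenomena under
the generator's assumptions — not that the same effect sizes would appear in
any particular clinical warehouse.

## Phenotype complexity

For a rule with oracle codes (c₁..c_k), each patient's *signature* is the
binary string whose digit i indicates presence of c_i. Signatures are
hashed into a fixed number of buckets (default 32) — FNV-1a 64-bit, a fixed,
documented, platform-stable non-cryptographic hash — or indexed directly
(collision-free) when 2^k fits in the bucket count. Separate histograms are
accumulated for cases and controls. Complexity is summarized by

- the Shannon entropy of the normalized case histogram,
  H = −Σᵢ pᵢ ln pᵢ (natural log by default, base configurable): higher
  means the positive cases are more diverse along the oracle axes;
- the KL divergence D(P⁺‖P⁻) = Σᵢ P⁺(xᵢ) ln (P⁺(xᵢ)/P⁻(xᵢ)) between the
  case and control histograms: lower means cases are harder to tell from
  controls on the oracle features alone.

Zero-count buckets are handled by additive smoothing (α = 0.5 added to every
count of both histograms before normalization, recorded in every report);
with α = 0 a case-occupied, control-empty bucket correctly yields an
infinite divergence, reported with a warning. `make_complexity_controlled_rule`
constructs rules whose satisfying signature set has an exact requested
cardinality, so entropy recovery can be tested against log(support size)
and prevalence×complexity interactions can be studied causally.

## Desk-scale reference experiment

The shipped reference study (`presets.rare_phenotype_study`) asks whether
MTL helps a rare phenotype: 20,000 patients, 1,000 codes, 8 latent factors
(blocks of 30 codes; per-code emission probabilities drawn once from
[0.4, 0.7]; background rate 0.002 → ~8 codes per patient). The target rule
is an OR of six 3-code conjunctions over factor 0's first six codes, each
clause also requiring the hidden flag (rate 0.75); realized prevalence
≈ 0.5%. Three-way conjunctions are deliberately not rankable by a linear
score over the indicators: the claim under study concerns *complex* rare
phenotypes, and with a linearly separable target the linear baseline wins
and neither neural family has anything to contribute. Fourteen phecode
groups draw members from factor 0's block and land
inside the auxiliary prevalence band; the remaining factors are common
enough (3.5–5%) that their groups fall above the band and are excluded by
the band filter itself, so every auxiliary task shares the target's latent
factor. The protocol uses 5 stratified splits, a reduced grid
(1 layer × {128, 256} × lr 1e-4), nested auxiliary sets of 5 and 10, and the
7-point LR path.

Two scale-bridging choices matter and are deliberate:

- **Minibatch size 16.** The 6-epoch budget is meaningful only in optimizer
  steps. A warehouse-scale epoch contains tens of times more minibatches;
  at 20,000 patients and batch 256 the budget ends with both families far
  from convergence and the comparison degenerates into "who warmed up
  faster". Batch 16 gives ≈6,000 Adam steps over the 6 epochs, the same
  order as a warehouse-scale run.
- **Precise batch-norm statistics.** Evaluation-time normalization uses
  exact statistics of the training set under the current weights, recomputed
  at every epoch boundary, rather than the exponential moving average
  accumulated during training. With batch 16 the EMA window covers only a
  few hundred rows and becomes a pure noise source in validation-based
  early stopping and in test scoring; exact statistics remove it for every
  family equally.

Known limitation: at this scale a 10% validation or test partition contains
only ~9 positive cases, so per-split AUPRC estimates — and therefore
per-split MTNN−STNN differences — are intrinsically noisy; conclusions
should be read from medians across splits, as the protocol reports them.
More fundamentally, phecode-style auxiliary labels are deterministic
functions of the input features, so auxiliary supervision contributes an
optimization/representation bias rather than new information. That bias is
what matters at warehouse scale (tens of thousands of indicator features,
trunks up to 2048 wide, erratic single-task training); at desk scale the
single-task net is already stable and the multitask increment sits inside
the per-split sampling noise. The suite's phenomenon checks assert the
warehouse-scale expectations and therefore document exactly where the
desk-scale study does and does not reproduce them.

## Numerical and degenerate-input conventions

- Logits-based, overflow-safe cross-entropy; sigmoid evaluated stably on
  both branches.
- Batch-norm ε = 1e-5; training batches of fewer than 2 rows are skipped
  (batch statistics undefined).
- Head weight columns are initialized per task in sequence, so the target
  head's draw does not depend on how many auxiliary heads follow it.
- Single-class target labels raise a degenerate-label error; a single-class
  *auxiliary* task is dropped (loss weight 0) with a warning and the run
  continues.
- AUPRC on single-class labels raises an undefined-metric error; empty
  case or control signature sets raise an insufficient-data error.
- Stratified splitting refuses fewer than 10 positives.
- All randomness flows through NumPy `SeedSequence` children of a single
  master seed; derived seeds stay below 2³¹.
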