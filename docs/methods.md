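# Methods

## The learning problem

Across languages, some verbs express causation directly in a transitive
frame ("Someone broke the truck" — the *less-transparent* causative) while
others require a dedicated marker ("Someone made the boy laugh" — the
*more-transparent* or periphrastic causative).  Children briefly
overgeneralize the transitive pattern ("*Someone laughed the boy") and then
retreat from it without corrective feedback.  The package implements a
corpus-prediction account of this trajectory: a learner that only ever tries
to predict which construction each verb occurs in, given the verb's identity
and its semantics, ends up with graded by-verb construction preferences that
track human acceptability judgments — and passes through an
overgeneralization stage on the way.

## Model

Each corpus utterance is abstracted to a (verb, construction) pair with
construction ∈ {less-transparent causative, more-transparent causative,
other}.  The input vector concatenates a one-hot lexical unit over the verb
inventory, one causative-context node (1 for causative tokens, 0 for
"other"), and four continuous semantic ratings in [0, 1] (event-merge,
causee autonomy, requires-a-causer, directive-vs-physical causation).  The
output is a 3-way softmax.  Training items are drawn i.i.d. in proportion to
the corpus counts.  At test the network is *interrogated for a causative
form*: lexical unit on, causative node 1, the verb's ratings on the semantic
units; the output activations are read as graded grammaticality judgments,
and `p_less − p_more` is the model-side difference score.  All reported
predictions are averaged over 48 runs differing in their initial random
weights.

**Baseline (no hidden layer).**  Weights and biases are initialized
uniformly on [−0.5, +0.5] and fit by warm-started BFGS, epoch by epoch, on a
fresh 10,000-utterance sample per epoch.  The objective per epoch is the
summed cross-entropy plus `weight_decay × Σθ²` with decay 0.5 (equivalently,
mean cross-entropy plus `0.5/n Σθ²`).  Two numerical choices matter and are
deliberate:

* *Penalty scale.*  The decay is applied to the summed loss (the classical
  neural-net convention).  Applied instead to the per-item mean loss, a
  decay of 0.5 shrinks every weight whose feature occurs in fewer than
  ~100% of items to near zero — lexical entrenchment becomes impossible and
  the model is semantics-only at every epoch, which contradicts both the
  asymptotic by-verb behaviour and the developmental trajectory the model
  exists to produce.
* *Per-epoch iteration budget.*  The penalized objective is convex, so an
  optimizer run to convergence reaches the same optimum every epoch and the
  developmental trajectory is flat.  Epoch-indexed development arises from
  bounded optimization: each epoch runs at most `max_iter` BFGS iterations
  (default 5), warm-started from the previous epoch's weights.
  Densely-active directions (output biases, the causative flag, semantic
  units) converge within the first epochs, giving early predictions
  dominated by corpus-wide base rates and coarse semantics; sparsely-active
  lexical directions — rare verbs above all — are carved out over many
  epochs.  On the bundled retreat-demo corpus (twenty high-frequency
  externally-caused transitive-preferring verbs plus one low-frequency
  internally-caused verb whose rare causative uses are periphrastic) this
  places the preference flip for the rare verb at about epoch 13 of 50,
  with a final periphrastic probability around 0.8.  `max_iter` is an
  ordinary config field; oracle-equivalence checks raise it (with
  `resample_each_epoch=False`) to converge fully.

**Extended (1–2 hidden layers).**  tanh hidden units; architectures
{[4], [10], [4,4], [8,8]}; mini-batch SGD (batch 32) with learning rate
0.01; inverted dropout on hidden units (0 or 0.75); harmonic annealing
`lr = lr0 / (1 + annealing · items_seen)` (0 or 0.75); L1 and L2 penalties
of 0.01 each.  The penalty is an epoch-level term (`l1 Σ|W| + l2 ΣW²` added
to the epoch's mean cross-entropy), so each batch update carries a
`batch/n` share of the penalty gradient; applying the full penalty gradient
at every update would make the effective regularization grow with the
number of updates and, at L1 = 0.01, empirically collapses the first-layer
weights.  The canonical epoch for these models is 300,000 utterances;
grid-cell epochs take values {2, 5, 15, 50}.

## Protocols

* **Trajectories.**  `run_condition` trains `runs` independent replicates
  and records every verb's causative-query probabilities after every epoch.
  Seeds derive from (base seed, condition tags, run index), so any condition
  reproduces in isolation.
* **Split-half (item-wise).**  Per run, a fresh uniformly random half of the
  verbs is withheld from the training stream (never from the architecture);
  held-out verbs are queried through their untrained lexical unit plus their
  true semantic ratings.  This tests generalization to verbs known only by
  their semantics — it is *not* a split of human data, which the model never
  sees.
* **Semantics ablation.**  `shuffle_semantics` permutes the verb→ratings
  mapping (fresh permutation per run), destroying semantic systematicity
  while preserving counts and the rating multiset.
* **Grid.**  The factorial design crosses 4 epoch settings × 4
  architectures × 2 dropout × 2 annealing (= 64 configs) with
  {all-verbs, split-half} × {real, shuffled semantics} over 8 corpora
  (5 adult-directed languages + 3 child-directed), 2,048 models in all,
  ranked by corpus log loss — the count-weighted mean negative log
  probability of the true construction, computed on the training corpus and
  never on human data.
* **Evaluation.**  Binary judgments aggregate to by-verb acceptance
  proportions with equivocal responses excluded before the denominator;
  production to less/(less+more) with non-causative responses as missing;
  adult ratings to by-verb means.  Difference scores are less-minus-more.
  Model–human fit is Pearson r with one-tailed critical values
  `t_crit / sqrt(t_crit² + df)`.  Group-level over/under-generalization is
  the child-minus-adult difference of by-verb z-scores (sample SD), with a
  default flag threshold of 1.5 z-units (chosen to reproduce the sparsity
  of flagged verbs on synthetic data of realistic size; it is a parameter).

**Split-half correlations are computed per run and averaged.**  All verbs
held out of the same run face the same trained network, so run-level shifts
in the learned construction base rate — which depend on exactly which verbs
were excluded from training — enter the within-run correlation only as an
additive constant that Pearson r discards.  Correlating run-averaged
predictions instead lets those shifts leak back in as spurious by-verb
signal (each verb is held out in a different subset of runs): in the
shuffled-semantics null this produces correlations of −0.2 to −0.5 with the
verbs' own preferences, the frequent verbs driving the effect.  The per-run
statistic restores a clean null (|r| ≤ 0.04 across seeds) while leaving the
real-semantics signal intact.

## Synthetic worlds

`SyntheticSpec` defines a generative stand-in for a language and its
speakers, with one latent internal-causation scalar θ ∈ [0, 1] per verb:

| parameter | default | role |
|---|---|---|
| `n_verbs` | 60 | verb inventory (matches the standardized test set size) |
| `sem_loadings` | (0.9, 0.7, 0.8, 0.6) | signed weights mapping θ to the 4 ratings |
| `sem_noise_sd` | 0.08 | rating noise; makes the 4 cues redundant and imperfect |
| `freq_shape` | 1.0 | Zipf exponent of total verb frequency |
| `total_tokens` | 100,000 | corpus size |
| `p_causative` | 0.15 | causative share of each verb's tokens |
| `pref_intercept`, `pref_slope` | 0, 6 | ground truth P(less \| causative) = expit(a + b(0.5 − θ)) |
| `kappa` | 0.5 | attenuation of the more-form's dispreference (periphrastic forms are rarely fully unacceptable) |
| `adult_noise_sd` | 0.5 | rating noise on the 1–5 adult scale |
| `n_adults`, `n_children` | 48, 48 | rater counts per task |
| `child_leniency` | 1.0 | additive log-odds bias toward "accept" |
| `equivocal_rate` | 0.02 | rare equivocal/no-answer responses |
| `prime_effect` | 1.0 | log-odds shift toward reproducing the primed form |
| `other_missing_rate` | 0.2 | production responses excluded as missing |

θ is one-dimensional although four features are rated: the loadings give the
features distinct scales and noise, so the learner must exploit redundant,
noisy cues, mirroring the strong intercorrelation of real ratings.  Ratings
follow `clip(0.5 + loading·(0.5 − θ) + ε, 0, 1)`.  Adult ratings are
`round(clip(1 + 4·acceptability + ε, 1, 5))` with acceptability of the less
form = P(less | causative) and of the more form = `1 − κ·P(less)`.  Child
binary judgments shift the acceptability log-odds by `child_leniency`;
production shifts P(less) log-odds by ±`prime_effect` according to the
prime.

What the generator does *not* emulate: lexical content and morphology,
sentence-level structure, age-graded change within the child samples,
by-participant random effects, and any relation between valence and
judgments.  Passing the synthetic recovery suite therefore shows that the
pipeline recovers known structure of this statistical shape — not that the
model is correct for any particular natural language.

## Problem sizes used in tests and the acceptance script

Baseline runs use the canonical 48 runs × 10,000-utterance epochs.
Extended-model runs use 48 runs × 15 epochs of 50,000 utterances (the
canonical epoch is 300,000): the size at which single-run [8,8] networks
are trained well enough that per-run held-out correlations are stable
across seeds, while a full split-half condition completes in about two
minutes on one CPU.  The Monte-Carlo check of the critical-r formula uses
2×10⁵ replicates (the 95th-percentile MC error, ~7×10⁻⁴, is far inside the
±0.01 assertion band).

## Known limitations

* The baseline's developmental timescale is set by the per-epoch iteration
  budget; it is a free parameter of the account, fixed once (5) against the
  published flip epoch, not estimated from data.
* Extended models use plain SGD; the original grid explored library
  defaults (momentum, initialization) that are not part of this contract.
* Split-half predictions for held-out verbs pass through untrained lexical
  weights, so single-run predictions carry irreducible initialization noise;
  conclusions should always rest on run-averaged (or per-run-averaged)
  statistics.
* The uniform-null expected-count argument treats correlations as
  independent Uniform(0,1) draws; it is a deliberately conservative sanity
  bound, not a calibrated null model.
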