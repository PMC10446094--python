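# causnet

Corpus-frequency-driven network models of how learners acquire by-verb
restrictions on causative constructions — for researchers in child language
acquisition and computational cognitive science who want a tested, seeded
reimplementation of the full modeling-and-evaluation pipeline.

## The problem and the model

Languages express causation either directly in a transitive frame
("Someone broke the truck" — the *less-transparent* causative) or with a
dedicated marker ("Someone made the boy laugh" — the *more-transparent*,
periphrastic causative), and which option a verb allows must be learned
verb by verb.  Children pass through a stage of overgeneralization
("\*Someone laughed the boy") and retreat from it without correction.

The model is a softmax classifier trained on (verb, construction) pairs
sampled in proportion to corpus frequency.  For verb *v* with semantic
ratings **s**ᵥ ∈ [0,1]⁴ (event-merge, autonomy, requires, directive), the
input is

    x = [one-hot(v) | causative flag | s_v]            (n_verbs + 5 units)

and the output P(construction | x) = softmax(Wx + b) over {less, more,
other}.  The baseline network has no hidden layer, initial weights uniform
on [−0.5, 0.5], weight decay 0.5, and is fit by warm-started BFGS on fresh
10,000-utterance epochs; extended variants add 1–2 tanh hidden layers
({4}, {10}, {4,4}, {8,8}) trained by SGD with dropout, learning-rate
annealing and L1/L2 penalties of 0.01.  Queried with the causative flag on,
the output activations are graded grammaticality judgments; `p_less −
p_more` is the model's difference score, correlated by verb against human
judgment and production measures.  Everything is averaged over 48 runs with
different initial weights.  See `docs/methods.md` for the full account.

The package also ships the evaluation protocol (split-half generalization
to held-out verbs, semantics-shuffling ablation, a 2,048-model factorial
hyperparameter grid ranked by corpus log loss, one-tailed critical-r
significance thresholds, over/under-generalization z-score classification)
and a synthetic-language generator with known ground truth: Zipf-skewed
verb frequencies, a latent internal-causation scalar driving both the
construction split and four noisy semantic ratings, simulated adult raters,
lenient child judges, and primed child producers.

## Worked example

```python
import pandas as pd
from causnet import (ModelConfig, SyntheticSpec, generate_language, generate_child_trials,
                     run_condition, model_by_verb, aggregate_judgments, difference_scores,
                     pearson_r, retreat_demo_language)

# 1. a synthetic language with known ground truth
spec = SyntheticSpec(seed=0)
lang, truth = generate_language(spec, spec.rng())

# 2. train the baseline learner: 48 runs x 15 epochs of 10,000 utterances
config = ModelConfig.baseline(epochs=15, runs=48, seed=0)
records = run_condition(lang, config)
model = model_by_verb(records)          # run-averaged, final epoch

# 3. simulate 48 children and correlate difference scores
binary, _ = generate_child_trials(truth, spec, spec.rng())
agg = aggregate_judgments(binary)
child = difference_scores(agg[agg.kind == "accept_prop_less"],
                          agg[agg.kind == "accept_prop_more"]).set_index("verb")["value"]
shared = model.set_index("verb").index.intersection(child.index)
res = pearson_r(model.set_index("verb")["diff"].loc[shared], child.loc[shared], tails="one")
print(f"model-child difference-score r = {res.r:.3f} "
      f"(n = {res.n}, critical r at p<.01 one-tailed = {res.critical_r_01:.2f})")

# 4. the overgeneralize-then-retreat trajectory for a laugh-like verb
demo = retreat_demo_language()
rec = run_condition(demo, ModelConfig.baseline(epochs=50, runs=8, seed=0))
rare = rec[rec.verb == "laughlike"].groupby("epoch")[["p_less", "p_more"]].mean()
print(rare.loc[[1, 5, 10, 15, 25, 50]].round(3))
```

prints

```
model-child difference-score r = 0.941 (n = 60, critical r at p<.01 one-tailed = 0.30)
       p_less  p_more
epoch
1       0.888   0.032
5       0.829   0.163
10      0.595   0.402
15      0.462   0.536
25      0.316   0.683
50      0.211   0.787
```

The model, trained only on corpus counts and semantic ratings (never on any
human judgment), predicts the simulated children's by-verb difference
scores at r = 0.94 — far above the one-tailed critical value.  The
trajectory shows the retreat from overgeneralization: the rare
internally-caused verb starts out predicted in the transitive causative
(p_less = 0.89 at epoch 1, the base-rate-driven error) and flips to the
correct periphrastic preference (p_more = 0.79 by epoch 50) purely from
continued exposure.

A command-line layer mirrors the pipeline stages:

```sh
causnet synth --out fixtures/ --seed 0
causnet train --input fixtures/language.csv --out preds.csv --seed 0
causnet eval  --preds preds.csv --human fixtures/child_binary.csv --form diff --out corr.csv
causnet grid  --inputs corpora/ --grid grid.json --targets targets/ --out grid_results.csv
```

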