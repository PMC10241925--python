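# boolfeat

Interpretable clinical prediction models from tabular subject-level data, via
symbolic regression over Boolean feature representations.

## The problem

Phenotyping models trained on summarized electronic-health-record features —
"number of encounters while on 3+ antihypertensive medications", "maximum
calcium", "mean systolic blood pressure" — are usually either accurate or
readable, rarely both.  Penalized linear models keep hundreds of small
coefficients; tree ensembles are opaque.  Clinicians, however, reason in
thresholded rules, and decision-support triggers are safer when the model can
be read and second-guessed.

`boolfeat` searches for a small set of derived features
`Φ(x) = (φ₁(x), …, φ_p(x))` — each a Boolean expression over threshold
comparisons on raw columns, or a raw column itself — feeding a logistic
model:

    logit P(y = 1 | x) = β · Φ(x) + β₀

The search is a genetic program: candidate representations undergo
epsilon-lexicase parent selection on per-subject balanced losses, tree
variation (insertion, deletion, point mutation, crossover, correlation
pruning), and NSGA-II survival on the two objectives *(balanced logistic
loss, representation complexity)*.  Comparison thresholds are learned by
weighted Gini impurity, as in classification trees, so they stay in raw
clinical units.  The accumulated Pareto archive is simplified post-run
(exact logical rewrites, correlation deletion, bounded subtree deletion) and
the final model is the archive member with the lowest balanced log-loss on
an internal 20% validation split — optionally robustified over 10 restarts
by dropping the lowest quartile of validation average precision and keeping
the smallest survivor.  A decision threshold is then calibrated so the
prevalence-adjusted positive predictive value meets a clinical target.

The result reads like a handful of weighted rules, e.g.

    +20.230 * [(x0 > 0.499237 AND x1 > -0.298496)]
    intercept: -10.115
    decision threshold: 0.500

See `docs/methods.md` for the full model description, parameter defaults,
and the synthetic-data generators that define the test conditions.

## Worked example

```python
import numpy as np
from sklearn.model_selection import train_test_split
from boolfeat import expressions as ex
from boolfeat import EvolutionConfig, run, auroc
from boolfeat.synthetic import SyntheticSpec, make_planted_rule

# a cohort whose labels follow a hidden two-term rule
rule = ex.Representation((ex.and_(ex.gt(0, 0.5), ex.gt(1, -0.3)),))
ds, _ = make_planted_rule(SyntheticSpec(n=2000, d=20, rule=rule, seed=107))
idx = np.arange(ds.n)
tr, te = train_test_split(idx, train_size=0.75, stratify=ds.y, random_state=7)
train, test = ds.subset(np.sort(tr)), ds.subset(np.sort(te))

archive, model, history = run(train, EvolutionConfig(pop_size=100,
                                                     generations=40, seed=7))
print("test AUROC:", round(auroc(test.y, model.predict_proba(test)), 4))
print("model size:", model.size)
for tree, b in zip(model.representation.trees, model.beta):
    print(f"{b:+.3f} * [{ex.describe_node(tree, model.feature_names)}]")
```

Output:

```
test AUROC: 1.0
model size: 5
+20.230 * [(x0 > 0.499237 AND x1 > -0.298496)]
```

The search recovered the planted rule: one derived Boolean feature whose
thresholds sit within 0.002 of the true cut-points (0.5 and −0.3), a model
of size 5 (one AND, two splits, two feature leaves) that separates the test
set perfectly.  The large coefficient reflects noise-free labels — the
logistic fit is ridge-capped rather than divergent.

## Command line

```bash
boolfeat fit --data cohort.csv --label atrh --seed 0 --robust --out out/
boolfeat predict --model out/model.json --data new_subjects.csv --out scores.csv
boolfeat report --model out/model.json
boolfeat benchmark --suite ablation --out bench/
```

`fit` writes `model.json` (bit-exact round-trip), `archive.json` (the Pareto
front with losses), and `history.csv` (per-generation best loss, median
complexity, archive size).

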