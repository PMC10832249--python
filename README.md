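# pathpred

Multi-label metabolic pathway prediction from enzymatic-reaction abundance
profiles.

Given an organism's (or community's) *reactome* — the set of enzymatic
reactions inferred from its annotated genome, identified by EC numbers and
quantified as occurrence counts — which metabolic pathways from a reference
database are present?  `pathpred` casts this as multi-label classification:
a reference database fixes a catalog of *r* reactions and *t* pathway
labels; each sample is an abundance vector **x** ∈ ℝ^r and carries a label
vector **y** ∈ {−1,+1}^t.  The package provides the full workflow: a
synthetic corrupted-dataset generator, feature transforms, gradient-boosted
binary classifiers composed into multi-label models, evaluation metrics,
and a command-line pipeline.

## Models

**Binary relevance (BR).** One independent binary scorer
g_j : ℝ^m → ℝ per label; the predicted label set is
Y\* = { λ_j : g_j(Φ(**x**)) > 0 }.  The default scorer is an XGBoost
classifier (`tree_method="hist"`, max depth 4, 22 estimators — selected by
6-fold cross-validated grid search over depth {2,4,6,8} × estimators
{22,23,24}), adapted to the sign rule by score = p − ½.

**Classifier chain.** A permutation π orders the labels; the classifier at
position j is *trained* on [Φ(**x**), y_π(1), …, y_π(j−1)] (ground-truth
±1 labels) and at *prediction* time consumes the previously *predicted*
assignments η propagated through the sign rule.  This lets later
classifiers exploit correlations between pathway labels that independent
binary problems cannot see.

**Ranked chain order.** Rather than an ensemble of random chains, the
chain order is computed once: hold out a validation split, train BR on the
rest, score each label's validation F1, and sort descending (stable
tie-break by label index).  Well-predicted labels go early; weak labels go
late, where they can condition on many predicted labels.

**Features.** The abundance group (AB) is the identity embedding of the
reaction-count vector; an optional reaction-evidence group (RE) appends
configurable summary features of the reactome (catalog coverage, nonzero
abundance order statistics, pathway coverage, incomplete-EC prevalence).

**Synthetic data.** Each sample selects k ~ Poisson(λ) pathways (truncated
to [1, t]), pools their reaction multisets, and corrupts the pool: every
occurrence is dropped with probability `p_remove` and Poisson(`p_insert`)
spurious reactions are inserted per selected pathway — emulating the
missed and spurious EC assignments of real annotation pipelines.

## Worked example

```python
from pathpred import *

db = generate_toy_db(20, 5, 0.0, seed=1)           # 20 disjoint pathways
print(db_summary(db))
corr = CorruptionConfig(p_remove=0.1, p_insert=0.5)
train = generate_dataset(db, GeneratorConfig(500, 5.0, corr, seed=101))
test  = generate_dataset(db, GeneratorConfig(150, 5.0, corr, seed=202))
Xtr, _ = transform_dataset(train, db)
Xte, _ = transform_dataset(test, db)
model = ClassifierChain(order="ranked", valid_fraction=0.2, random_state=0)
model.fit(Xtr, train.labels)
rep = evaluate(model, Xte, test.labels, granularity="sample_average")
print(f"hamming_loss={rep.hamming_loss:.4f} precision={rep.precision:.4f} "
      f"recall={rep.recall:.4f} f1={rep.f1:.4f}")
print(model.predict_label_sets(Xte[:1], label_ids=db.pathway_ids)[0])
```

prints

```
{'r': 100, 't': 20, 'reactions_per_pathway': {5: 20}}
hamming_loss=0.0050 precision=0.9928 recall=0.9917 f1=0.9915
['PWY-0004', 'PWY-0007', 'PWY-0014', 'PWY-0016', 'PWY-0018', 'PWY-0019']
```

i.e. on a 20-pathway toy database with 10% reaction dropout and ~0.5
spurious insertions per pathway, the ranked chain recovers held-out pathway
complements with sample-averaged F1 ≈ 0.99; the last line is the predicted
pathway set for the first held-out sample (here exactly the true set).

The same workflow is available from the shell:

```sh
pathpred make-db --pathways 20 --reactions-per-pathway 5 --seed 1 --out db.tsv
pathpred generate --db db.tsv --n 500 --lambda 5 --seed 101 --out train
pathpred tune  --db db.tsv --dataset train --folds 6 --out best.json
pathpred train --db db.tsv --dataset train --mode ranked-chain --out model/
pathpred predict  --db db.tsv --model model/ --dataset test --out preds.tsv
pathpred evaluate --db db.tsv --model model/ --dataset test --out report.json
```

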