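# Methods

## Problem setting

A reference pathway database fixes an ordered catalog of r enzymatic
reactions (EC-number identifiers, treated as opaque strings — incomplete
EC classes such as `EC-1.2.3.-` are ordinary catalog members) and t
pathway definitions, each a multiset over the catalog (a pathway may use
one EC class for several steps; the TSV dialect encodes multiplicity by
repetition).  The catalog and pathway orderings are file order, not
lexicographic, and define the column indices of every matrix the package
produces; a SHA-256 fingerprint of the orderings travels with datasets and
models so mismatched artifacts fail loudly instead of mispredicting.

A sample is a non-negative integer abundance vector a ∈ ℤ≥0^r (total
occurrences of each reaction in the annotated genome or metagenome) paired
with a label vector y ∈ {−1,+1}^t marking which pathways are present.

## Synthetic data generator

The generator emulates corrupted synthetic training corpora for pathway
prediction.  Per sample:

1. draw k ~ Poisson(λ), truncate to [1, t];
2. select k distinct pathways uniformly without replacement; these are the
   +1 labels;
3. for each selected pathway, corrupt its reaction multiset — every
   occurrence is independently deleted with probability `p_remove`, and a
   Poisson(`p_insert`) count of spurious occurrences is inserted, drawn
   uniformly from the catalog excluding the pathway's own reactions (with
   a logged fallback to the whole catalog if a pathway spans it);
4. sum the surviving occurrences over selected pathways into the abundance
   row, so reactions shared between selected pathways accumulate counts.

Truncating k to [1, t] completes the unstated boundary behaviour: k = 0
would produce an all-negative sample that degenerates per-sample
precision/recall, and k > t is impossible without replacement.  At the
scale this emulates (λ ≈ t/5 with t in the thousands) both tails are
negligible anyway.

The corruption scheme is a parametric **stand-in**, not a reproduction of
any historical corpus: the constraints used to build those corpora are
defined in earlier work and not restated here.  Defaults `p_remove = 0.1`,
`p_insert = 0.5` were chosen once as a plausible annotation-noise level —
roughly one missed reaction in ten and about one spurious EC assignment
per two pathways — and are exposed, not claimed to match any published
dataset.  One RNG stream per dataset, consumed in documented order
(sample → selection → per-pathway corruption in pathway-index order, with
occurrences visited in catalog order), makes a seed fix the dataset
byte-for-byte.

What the generator does *not* emulate: read-level sequencing noise,
abundance correlations between functionally related pathways, taxonomic
structure, or the long-tailed reaction-sharing graph of a curated
database (the toy databases share reactions only through an optional
common pool).  Tests passing on this generator therefore demonstrate
algorithmic correctness and noise robustness of the learning machinery,
not field performance on curated pathway/genome databases.

## Features

Φ concatenates enabled group transforms, AB first:

* **AB** (width r) — the abundance vector itself, in catalog order.
* **RE** (width = number of enabled features, default 9) — named summary
  features from a registry: total abundance; distinct reactions present;
  fraction of catalog present; mean/max/median nonzero abundance; count of
  incomplete-EC reactions present (ids with a trailing `-`); mean and max
  per-pathway coverage (fraction of a pathway's distinct reactions
  present).  Order statistics on an empty support return 0 by convention
  so all-zero samples flow through.

The RE set is configurable rather than fixed because the historical
68-feature reaction-evidence transform is not specified in recoverable
form; the registry default is a compact, documented substitute.  Per-label
feature groups (pathway-evidence style) are excluded by design: every
binary scorer here consumes one shared per-sample vector.

## Multi-label models

**Binary relevance.**  For each label j a binary training set
S_j = {(Φ(x^i), y^i_j)} induces a scorer g_j; the relevant label set of a
query is {λ_j : g_j > 0}.  The decision rule is strictly `score > 0`;
probabilistic learners are adapted as score = p − ½ so p = ½ exactly maps
to absent.  Every label is trained with the same seed, making a scorer a
function of (features, its own column, learner spec, seed) only — hence
deleting or permuting other label columns provably cannot change it.  A
single-class training column yields a constant scorer (±½) rather than an
error.

**Classifier chain.**  Training at position j augments the features with
the j−1 *ground-truth* labels earlier in the chain, encoded ±1; prediction
propagates the *predicted* signs η instead.  This asymmetry is the
defining property of the method and is asserted by tests (an
augmentation-blind learner must make the chain collapse exactly to binary
relevance; a scorer that reads the appended coordinate must copy the
previous label's prediction).

**Ranked order.**  The chain permutation is computed from a seeded row
shuffle: the last ⌈0.2·n⌉ shuffled rows form the validation split
(`valid_fraction` default 0.2 — the historical split size is unstated, and
one-fifth is the conventional hold-out), binary relevance is trained on
the rest, per-label validation F1 is computed, and labels are sorted
descending with a stable tie-break on label index.  A label with no
positive validation instances scores F1 = 0 and ranks last, which is the
intended behaviour: unlearnable labels should see the most predicted-label
context.  No chain ensemble is built; one ranked chain (or an explicitly
seeded random order) is trained per run.

**Hyperparameter search.**  `grid_search_cv` partitions rows into k seeded
folds (no label stratification), trains binary relevance per grid point on
k−1 folds, scores sample-averaged F1 on the held-out fold, and returns the
highest-mean setting (ties: first in grid order).  Defaults: k = 6, grid =
max depth {2, 4, 6, 8} × estimators {22, 23, 24}; the package default
learner uses depth 4 with 22 estimators and the `hist` tree method.

## Metrics

Hamming loss is the fraction of disagreeing (sample, label) cells.
Precision/recall/F1 are computed at three granularities: over one sample's
label vector (the single-organism table setting), per sample then averaged
(the community setting), and per label column (used for chain ranking).
Zero-division conventions: empty truth ∧ empty prediction → P = R = F1 = 1
for that unit; empty prediction against non-empty truth → P = 0; empty
truth against non-empty prediction → R = 0.  These standard multi-label
conventions keep sample averages defined; the ranking path overrides the
empty-empty case to 0 as described above.  Note that F1, being symmetric
in FP and FN, is invariant under exchanging the roles of truth and
prediction even though precision and recall swap.

## Numerical and serialization choices

Labels are {0,1} at file boundaries (TSV) and ±1 internally, because the
chain's augmented coordinates require the ±1 encoding.  Models are saved
as a directory of per-position XGBoost JSON boosters plus a `model.json`
carrying the format version, learner spec, chain permutation, feature
width, and the database fingerprint; loading re-checks version and
fingerprint.  XGBoost runs single-threaded with a fixed `random_state`,
making training and prediction deterministic for fixed inputs.

## Problem sizes

The shipped test and reproduction runs use desk-sized instances chosen to
exercise every code path at statistical power sufficient for their
assertions: toy databases of 10–50 pathways, datasets of 300–2000 samples,
λ = t/5 so mean pathway prevalence ≈ 0.2 (matching the ~1:5 positive
imbalance typical of pathway corpora).  The reproduction script tunes on a
400-sample subsample — the grid verdict is stable under subsampling at
this scale — then trains on all 1500 training samples.

The chain-dependence demonstration uses a constructed dataset: three
parent labels, each carried by a weak distributed signal (15 Gaussian
features at effect size 0.4), plus a dependent label present iff all three
parents are present and carrying no feature signal of its own.  A
depth-limited tree ensemble cannot compose the three weak estimates from
raw features, but the chain recovers the dependent label directly from the
parents' appended predictions — isolating exactly the label-correlation
benefit the chain exists to capture.

## Known limitations

* The corruption model and RE feature set are documented stand-ins (see
  above), so absolute metric values on the synthetic benchmark do not
  transfer to curated databases.
* Toy databases draw shared reactions from a single common pool; real
  reaction-sharing structure is far richer.
* Scores are not calibrated probabilities; only their sign is meaningful.
* No ensemble-of-chains or Bayes-optimal chain inference; one permutation
  per model.
* Custom learners registered at runtime can train and predict but not
  serialize unless they implement the scorer save/load hooks.
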