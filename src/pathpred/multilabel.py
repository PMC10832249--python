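"""Multi-label learning: binary relevance and classifier chains with a
ranked chain order.

Binary relevance decomposes the t-label problem into t independent binary
problems; label j is predicted present iff its scorer's output on the
sample is strictly positive.

A classifier chain fixes a permutation pi over labels.  The scorer at
chain position j is *trained* on the features augmented with the j-1
ground-truth label columns earlier in the chain (encoded +-1), and at
*prediction* time consumes the previously *predicted* +-1 assignments
propagated through the sign rule.  The train-with-truth /
predict-with-predictions asymmetry is intentional and is what lets later
classifiers exploit label correlations; symmetrizing it is a common
implementation bug.

The ranked chain order is obtained by holding out a validation split,
training binary relevance on the remainder, and sorting labels by their
per-label validation F1 in descending order with a stable tie-break on
label index — well-predicted labels go early so weaker labels can condition
on their predictions.  A label with no positive validation instances
scores 0 and therefore ranks last.

Estimators follow scikit-learn conventions (``fit``/``predict``/
``decision_function``, ``get_params``/``set_params``, fitted attributes
with a trailing underscore); the module-level ``train_*``/``predict_*``
functions are thin wrappers over them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold

from .exceptions import ConfigError, ConsistencyError, ValidationError
from .learners import (
    BinaryLearnerSpec,
    default_learner_grid,
    fit_binary,
    load_scorer,
)
from .metrics import prf1

__all__ = [
    "RankingConfig",
    "BinaryRelevance",
    "ClassifierChain",
    "rank_chain_order",
    "grid_search_cv",
    "save_model",
    "load_model",
    "train_binary_relevance",
    "predict_binary_relevance",
    "train_classifier_chain",
    "predict_classifier_chain",
]

MODEL_FORMAT_VERSION = 1


def _check_xy(X, Y):
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y)
    if X.ndim != 2 or Y.ndim != 2:
        raise ValidationError("features and labels must be 2-D matrices")
    if X.shape[0] != Y.shape[0]:
        raise ValidationError(f"row mismatch: {X.shape[0]} feature rows vs {Y.shape[0]} label rows")
    bad = np.setdiff1d(np.unique(Y), (-1, 1))
    if bad.size:
        raise ValidationError(f"label matrix contains values outside {{-1,+1}}: {bad}")
    return X, Y.astype(np.int8)


def _check_perm(order, t: int) -> np.ndarray:
    order = np.asarray(order, dtype=np.intp)
    if order.shape != (t,) or not np.array_equal(np.sort(order), np.arange(t)):
        raise ValidationError(f"order must be a permutation of 0..{t - 1}")
    return order


@dataclass(frozen=True)
class RankingConfig:
    """Validation-split configuration for ranked chain ordering."""

    valid_fraction: float = 0.2
    metric: str = "f1"
    seed: int = 0
    tie_break: str = "stable_by_label_index"

    def __post_init__(self):
        if not (0.0 < self.valid_fraction < 1.0):
            raise ConfigError("valid_fraction must be in (0, 1)")
        if self.metric != "f1":
            raise ConfigError("only the f1 ranking metric is supported")
        if self.tie_break != "stable_by_label_index":
            raise ConfigError("only stable_by_label_index tie-break is supported")


class BinaryRelevance(BaseEstimator):
    """One independent binary scorer per label; label present iff score > 0.

    Parameters
    ----------
    learner : BinaryLearnerSpec or None
        Training backend; None selects the default boosted-tree learner.
    random_state : int
        Seed passed to every per-label training run.  All labels share the
        same seed so a scorer depends only on (features, its own column,
        learner) — permuting label columns permutes scorers identically.
    """

    def __init__(self, learner: BinaryLearnerSpec | None = None, random_state: int = 0):
        self.learner = learner
        self.random_state = random_state

    def _spec(self) -> BinaryLearnerSpec:
        return self.learner if self.learner is not None else BinaryLearnerSpec()

    def fit(self, X, Y):
        X, Y = _check_xy(X, Y)
        spec = self._spec()
        self.scorers_ = [
            fit_binary(spec, X, Y[:, j], seed=self.random_state) for j in range(Y.shape[1])
        ]
        self.n_features_in_ = X.shape[1]
        self.n_labels_ = Y.shape[1]
        return self

    def _check_query(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ConsistencyError(
                f"query features must be (n, {self.n_features_in_}); got {X.shape}"
            )
        return X

    def decision_function(self, X) -> np.ndarray:
        X = self._check_query(X)
        return np.column_stack([s.scores(X) for s in self.scorers_])

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, 1, -1).astype(np.int8)

    def predict_label_sets(self, X, label_ids=None) -> list[list]:
        """Relevant label set per sample: labels whose score is > 0."""
        pred = self.predict(X)
        ids = label_ids if label_ids is not None else list(range(self.n_labels_))
        return [[ids[j] for j in np.flatnonzero(row == 1)] for row in pred]


class ClassifierChain(BaseEstimator):
    """Classifier chain over a fixed, random, or validation-ranked order.

    Parameters
    ----------
    learner : BinaryLearnerSpec or None
    order : "ranked", "random", or an explicit permutation of label indices.
    valid_fraction : float
        Validation fraction for ranked ordering (ignored otherwise).
    random_state : int
        Seeds training, the ranking split and the random order.
    """

    def __init__(
        self,
        learner: BinaryLearnerSpec | None = None,
        order="ranked",
        valid_fraction: float = 0.2,
        random_state: int = 0,
    ):
        self.learner = learner
        self.order = order
        self.valid_fraction = valid_fraction
        self.random_state = random_state

    def _spec(self) -> BinaryLearnerSpec:
        return self.learner if self.learner is not None else BinaryLearnerSpec()

    def fit(self, X, Y):
        X, Y = _check_xy(X, Y)
        t = Y.shape[1]
        if isinstance(self.order, str) and self.order == "ranked":
            self.order_ = rank_chain_order(
                X, Y, self._spec(),
                RankingConfig(valid_fraction=self.valid_fraction, seed=self.random_state),
            )
        elif isinstance(self.order, str) and self.order == "random":
            self.order_ = np.random.default_rng(self.random_state).permutation(t)
        elif isinstance(self.order, str):
            raise ConfigError(f"order must be 'ranked', 'random' or a permutation; got {self.order!r}")
        else:
            self.order_ = _check_perm(self.order, t)
        spec = self._spec()
        scorers = []
        for j in range(t):
            # augment with ground-truth labels of earlier chain positions
            aug = np.hstack([X, Y[:, self.order_[:j]].astype(np.float64)])
            scorers.append(fit_binary(spec, aug, Y[:, self.order_[j]], seed=self.random_state))
        self.scorers_ = scorers
        self.n_features_in_ = X.shape[1]
        self.n_labels_ = t
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ConsistencyError(
                f"query features must be (n, {self.n_features_in_}); got {X.shape}"
            )
        n, t = X.shape[0], self.n_labels_
        eta = np.zeros((n, t))  # predicted +-1 assignments in chain-position order
        for j in range(t):
            aug = np.hstack([X, eta[:, :j]])
            # sign rule with the strict decision convention: score > 0 -> +1
            eta[:, j] = np.where(self.scorers_[j].scores(aug) > 0, 1.0, -1.0)
        pred = np.empty((n, t), dtype=np.int8)
        pred[:, self.order_] = eta.astype(np.int8)
        return pred

    def predict_label_sets(self, X, label_ids=None) -> list[list]:
        pred = self.predict(X)
        ids = label_ids if label_ids is not None else list(range(self.n_labels_))
        return [[ids[j] for j in np.flatnonzero(row == 1)] for row in pred]


def rank_chain_order(
    features, labels, learner: BinaryLearnerSpec | None = None,
    config: RankingConfig | None = None,
) -> np.ndarray:
    """Chain order by descending per-label validation F1.

    Rows are split (seeded shuffle) into a training part and a validation
    part of ``valid_fraction``; binary relevance is trained on the training
    part; labels are sorted by their per-label F1 on the validation part,
    descending, ties broken by ascending label index.  Per-label F1 with no
    positive validation instances is 0.
    """
    config = config or RankingConfig()
    X, Y = _check_xy(features, labels)
    n = X.shape[0]
    n_valid = int(round(config.valid_fraction * n))
    if n_valid < 1 or n_valid >= n:
        raise ConfigError(
            f"valid_fraction={config.valid_fraction} with n={n} leaves an empty split"
        )
    perm = np.random.default_rng(config.seed).permutation(n)
    valid_idx, train_idx = perm[:n_valid], perm[n_valid:]
    br = BinaryRelevance(learner=learner, random_state=config.seed)
    br.fit(X[train_idx], Y[train_idx])
    pred = br.predict(X[valid_idx])
    _, _, f1 = prf1(Y[valid_idx], pred, granularity="per_label", empty_both=0.0)
    # stable argsort of -f1: descending F1, ties by ascending label index
    return np.argsort(-np.asarray(f1), kind="stable")


def grid_search_cv(
    features,
    labels,
    learner_grid: list[BinaryLearnerSpec] | None = None,
    k: int = 6,
    metric: str = "f1_sample_avg",
    seed: int = 0,
):
    """k-fold cross-validated grid search over binary-learner settings.

    For each grid point, binary relevance is trained on k-1 folds and
    scored (sample-averaged F1) on the held-out fold; the setting with the
    highest mean fold score wins (ties: first in grid order).  Returns
    ``(best_spec, report)`` where the report lists per-setting fold scores.
    """
    if metric != "f1_sample_avg":
        raise ConfigError("only the f1_sample_avg selection metric is supported")
    X, Y = _check_xy(features, labels)
    if k < 2:
        raise ConfigError("k must be >= 2")
    if k > X.shape[0]:
        raise ConfigError(f"k={k} exceeds n={X.shape[0]}")
    grid = learner_grid if learner_grid is not None else default_learner_grid()
    if not grid:
        raise ConfigError("learner grid must be non-empty")
    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(X))
    report = []
    for spec in grid:
        fold_scores = []
        for train_idx, test_idx in folds:
            br = BinaryRelevance(learner=spec, random_state=seed)
            br.fit(X[train_idx], Y[train_idx])
            _, _, f1 = prf1(Y[test_idx], br.predict(X[test_idx]), granularity="sample_average")
            fold_scores.append(float(f1))
        report.append(
            {"spec": spec.to_dict(), "fold_scores": fold_scores, "mean": float(np.mean(fold_scores))}
        )
    best = int(np.argmax([r["mean"] for r in report]))
    return grid[best], {"k": k, "seed": seed, "metric": metric, "results": report,
                        "best_index": best}


# ---------------------------------------------------------------------------
# Persistence: directory with model.json + per-position scorer files
# ---------------------------------------------------------------------------

def save_model(model, path, fingerprint: str | None = None, label_ids=None, extra: dict | None = None):
    """Save a fitted BinaryRelevance or ClassifierChain to a directory.

    ``fingerprint`` (e.g. the reference-database or feature-layout hash)
    is stored and re-checked on load so a model is never silently applied
    to mismatched inputs.
    """
    if not hasattr(model, "scorers_"):
        raise ValidationError("model must be fitted before saving")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    kind = "chain" if isinstance(model, ClassifierChain) else "br"
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": kind,
        "learner": model._spec().to_dict(),
        "random_state": model.random_state,
        "n_features_in": int(model.n_features_in_),
        "n_labels": int(model.n_labels_),
        "fingerprint": fingerprint,
        "label_ids": list(label_ids) if label_ids is not None else None,
        "scorers": [s.save(path, f"scorer_{j:05d}") for j, s in enumerate(model.scorers_)],
    }
    if kind == "chain":
        meta["order"] = [int(j) for j in model.order_]
    if extra:
        meta["extra"] = extra
    (path / "model.json").write_text(json.dumps(meta, indent=1) + "\n")
    return path


def load_model(path, expect_fingerprint: str | None = None):
    """Load a model directory written by :func:`save_model`.

    Raises :class:`ConsistencyError` on format-version or fingerprint
    mismatch instead of predicting silently against the wrong layout.
    """
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise ConsistencyError(
            f"model format version {meta.get('format_version')} != {MODEL_FORMAT_VERSION}"
        )
    if expect_fingerprint is not None and meta.get("fingerprint") != expect_fingerprint:
        raise ConsistencyError(
            "model fingerprint mismatch: saved "
            f"{str(meta.get('fingerprint'))[:12]}... != expected {expect_fingerprint[:12]}..."
        )
    spec = BinaryLearnerSpec.from_dict(meta["learner"])
    if meta["kind"] == "chain":
        model = ClassifierChain(learner=spec, order=meta["order"], random_state=meta["random_state"])
        model.order_ = _check_perm(meta["order"], meta["n_labels"])
    else:
        model = BinaryRelevance(learner=spec, random_state=meta["random_state"])
    model.scorers_ = [load_scorer(path, m) for m in meta["scorers"]]
    model.n_features_in_ = meta["n_features_in"]
    model.n_labels_ = meta["n_labels"]
    model.meta_ = meta
    return model


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def train_binary_relevance(features, labels, learner=None, seed: int = 0) -> BinaryRelevance:
    return BinaryRelevance(learner=learner, random_state=seed).fit(features, labels)


def predict_binary_relevance(model: BinaryRelevance, features, label_ids=None):
    pred = model.predict(features)
    return pred, model.predict_label_sets(features, label_ids=label_ids)


def train_classifier_chain(features, labels, learner=None, order="ranked", seed: int = 0,
                           valid_fraction: float = 0.2) -> ClassifierChain:
    return ClassifierChain(
        learner=learner, order=order, valid_fraction=valid_fraction, random_state=seed
    ).fit(features, labels)


def predict_classifier_chain(model: ClassifierChain, features, label_ids=None):
    pred = model.predict(features)
    return pred, model.predict_label_sets(features, label_ids=label_ids)
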