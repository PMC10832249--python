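"""Shared fixtures: toy databases, datasets, and deterministic toy binary
learners registered against the pluggable learner contract.

The toy learners make algorithmic behaviour checkable in closed form:

* ``majority`` — scorer is the constant training-target mean, so the
  predicted sign is the column's majority sign;
* ``col0_threshold`` — thresholds feature 0 at the midpoint of the class
  means and ignores every other coordinate, hence is *augmentation-blind*:
  a classifier chain built from it must equal binary relevance;
* ``last_coordinate`` — scorer returns the last input coordinate, which at
  chain position j >= 2 is the previous predicted label, enabling
  hand-traced propagation checks;
* ``zero`` — scores exactly 0 everywhere (exercises the strict > 0 rule);
* ``lookup:<key>`` — returns predetermined scores addressed by a row-id
  column, used to construct exact ranking scenarios.
"""

from __future__ import annotations

import numpy as np
import pytest

from pathpred import (
    CorruptionConfig,
    GeneratorConfig,
    generate_dataset,
    generate_toy_db,
    register_learner,
)
from pathpred.learners import BinaryLearnerSpec, Scorer


class ConstScore(Scorer):
    kind = "toy"

    def __init__(self, value):
        self.value = float(value)

    def scores(self, X):
        return np.full(np.asarray(X).shape[0], self.value)


class Col0Score(Scorer):
    kind = "toy"

    def __init__(self, threshold):
        self.threshold = float(threshold)

    def scores(self, X):
        return np.asarray(X, dtype=float)[:, 0] - self.threshold


class LastCoordScore(Scorer):
    kind = "toy"

    def scores(self, X):
        return np.asarray(X, dtype=float)[:, -1]


class LookupScore(Scorer):
    """Maps the row-id column (feature 0) to a predetermined score column."""

    kind = "toy"

    def __init__(self, score_column):
        self.score_column = np.asarray(score_column, dtype=float)

    def scores(self, X):
        ids = np.asarray(X)[:, 0].astype(int)
        return self.score_column[ids]


LOOKUP_TABLES: dict[str, np.ndarray] = {}
_LOOKUP_CALLS: dict[str, int] = {}


def _fit_majority(X, y, hp, seed):
    return ConstScore(np.mean(y))


def _fit_col0(X, y, hp, seed):
    x0 = np.asarray(X, dtype=float)[:, 0]
    pos, neg = x0[np.asarray(y) > 0], x0[np.asarray(y) < 0]
    if pos.size == 0:
        return ConstScore(-1.0)
    if neg.size == 0:
        return ConstScore(1.0)
    return Col0Score((pos.mean() + neg.mean()) / 2.0)


def _fit_last(X, y, hp, seed):
    return LastCoordScore()


def _fit_zero(X, y, hp, seed):
    return ConstScore(0.0)


def _fit_lookup(X, y, hp, seed):
    # successive fits within one binary-relevance training walk the label
    # columns in order, so a per-key call counter recovers the column index
    key = hp["key"]
    j = _LOOKUP_CALLS.get(key, 0)
    _LOOKUP_CALLS[key] = j + 1
    return LookupScore(LOOKUP_TABLES[key][:, j])


register_learner("majority", _fit_majority)
register_learner("col0_threshold", _fit_col0)
register_learner("last_coordinate", _fit_last)
register_learner("zero", _fit_zero)
register_learner("lookup", _fit_lookup)


def lookup_spec(key: str, table: np.ndarray) -> BinaryLearnerSpec:
    """Register a score table and reset its fit counter."""
    LOOKUP_TABLES[key] = np.asarray(table, dtype=float)
    _LOOKUP_CALLS[key] = 0
    return BinaryLearnerSpec.make("lookup", key=key)


def small_xgb(max_depth=2, n_estimators=8) -> BinaryLearnerSpec:
    return BinaryLearnerSpec.make("xgboost", max_depth=max_depth, n_estimators=n_estimators)


@pytest.fixture(scope="session")
def disjoint_db():
    """20 pathways x 5 reactions, pairwise-disjoint reaction sets."""
    return generate_toy_db(20, 5, 0.0, seed=1)


@pytest.fixture(scope="session")
def shared_db():
    return generate_toy_db(10, 4, 0.5, seed=3)


@pytest.fixture(scope="session")
def clean_dataset(disjoint_db):
    """Zero-corruption dataset on the disjoint toy db."""
    cfg = GeneratorConfig(
        n_samples=120, lam=5, seed=11, corruption=CorruptionConfig(0.0, 0.0)
    )
    return generate_dataset(disjoint_db, cfg)


@pytest.fixture(scope="session")
def noisy_dataset(disjoint_db):
    cfg = GeneratorConfig(
        n_samples=120, lam=5, seed=12, corruption=CorruptionConfig(0.1, 0.5)
    )
    return generate_dataset(disjoint_db, cfg)
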