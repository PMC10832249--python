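"""Pluggable binary-learner contract.

A :class:`BinaryLearnerSpec` names a registered training backend plus its
hyperparameters.  Training a spec on ``(X, y)`` with y in {-1,+1} yields a
:class:`Scorer`: a callable mapping a feature matrix to real scores whose
*sign* is the predicted class, with the decision rule strictly
``score > 0`` (a score of exactly 0 predicts absent).

The default backend is gradient-boosted decision trees (xgboost's sklearn
API) with the 'hist' tree method.  Its probabilistic output is adapted to
the sign convention as ``score = p - 1/2``, so probability exactly one
half maps to absent, matching the strict inequality.  Default
hyperparameters are max_depth=4 and n_estimators=22 (the values selected
by cross-validated grid search; see docs/methods.md).

A label column that is single-class in training (a pathway never, or
always, present) yields a :class:`ConstantScorer` rather than an error.

Additional backends — including toy learners used in tests — register via
:func:`register_learner`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigError, ValidationError

__all__ = [
    "BinaryLearnerSpec",
    "Scorer",
    "ConstantScorer",
    "XGBScorer",
    "fit_binary",
    "register_learner",
    "default_learner_grid",
]

DEFAULT_XGB_PARAMS = {"max_depth": 4, "n_estimators": 22, "tree_method": "hist"}


@dataclass(frozen=True)
class BinaryLearnerSpec:
    name: str = "xgboost"
    hyperparameters: tuple = ()

    @staticmethod
    def make(name: str = "xgboost", **hyperparameters) -> "BinaryLearnerSpec":
        return BinaryLearnerSpec(name, tuple(sorted(hyperparameters.items())))

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)

    def to_dict(self) -> dict:
        return {"name": self.name, "hyperparameters": self.params}

    @classmethod
    def from_dict(cls, d: dict) -> "BinaryLearnerSpec":
        return cls.make(d["name"], **d.get("hyperparameters", {}))


class Scorer:
    """Base scorer: maps an (n, d) feature matrix to (n,) real scores."""

    kind = "abstract"

    def scores(self, X) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def save(self, directory: Path, stem: str) -> dict:
        raise ValidationError(
            f"scorer of kind {self.kind!r} does not support serialization"
        )


class ConstantScorer(Scorer):
    """Returns a fixed score; used for single-class training targets."""

    kind = "constant"

    def __init__(self, value: float):
        self.value = float(value)

    def scores(self, X) -> np.ndarray:
        return np.full(np.asarray(X).shape[0], self.value)

    def save(self, directory, stem):
        return {"kind": self.kind, "value": self.value}

    @classmethod
    def load(cls, directory, meta):
        return cls(meta["value"])


class XGBScorer(Scorer):
    """Boosted-tree scorer; score = P(y=+1) - 1/2."""

    kind = "xgboost"

    def __init__(self, model):
        self.model = model

    def scores(self, X) -> np.ndarray:
        return self.model.predict_proba(np.asarray(X, dtype=np.float64))[:, 1] - 0.5

    def save(self, directory, stem):
        path = Path(directory) / f"{stem}.xgb.json"
        self.model.get_booster().save_model(str(path))
        return {"kind": self.kind, "file": path.name}

    @classmethod
    def load(cls, directory, meta):
        from xgboost import XGBClassifier

        model = XGBClassifier()
        model.load_model(str(Path(directory) / meta["file"]))
        return cls(model)


def _fit_xgboost(X, y_pm, hyperparameters: dict, seed: int) -> Scorer:
    from xgboost import XGBClassifier

    y01 = (np.asarray(y_pm) > 0).astype(int)
    classes = np.unique(y01)
    if classes.size == 1:
        return ConstantScorer(0.5 if classes[0] == 1 else -0.5)
    params = {**DEFAULT_XGB_PARAMS, **hyperparameters}
    model = XGBClassifier(
        **params, random_state=int(seed) % (2**31), n_jobs=1, verbosity=0
    )
    model.fit(np.asarray(X, dtype=np.float64), y01)
    return XGBScorer(model)


_LEARNER_REGISTRY = {"xgboost": _fit_xgboost}
_SCORER_LOADERS = {"constant": ConstantScorer.load, "xgboost": XGBScorer.load}


def register_learner(name: str, fit_fn, scorer_loader=None):
    """Register a training backend: ``fit_fn(X, y_pm, hyperparameters, seed)
    -> Scorer``.  Optionally register a loader for its scorer kind."""
    _LEARNER_REGISTRY[name] = fit_fn
    if scorer_loader is not None:
        _SCORER_LOADERS[name] = scorer_loader


def load_scorer(directory, meta: dict) -> Scorer:
    kind = meta["kind"]
    if kind not in _SCORER_LOADERS:
        raise ValidationError(f"no loader registered for scorer kind {kind!r}")
    return _SCORER_LOADERS[kind](directory, meta)


def fit_binary(spec: BinaryLearnerSpec, X, y_pm, seed: int = 0) -> Scorer:
    """Train one binary scorer on a +-1 target vector."""
    if spec.name not in _LEARNER_REGISTRY:
        raise ConfigError(f"unknown learner {spec.name!r}")
    y = np.asarray(y_pm)
    bad = np.setdiff1d(np.unique(y), (-1, 1))
    if bad.size:
        raise ValidationError(f"target vector contains values outside {{-1,+1}}: {bad}")
    scorer = _LEARNER_REGISTRY[spec.name](X, y, spec.params, seed)
    return scorer


def default_learner_grid() -> list[BinaryLearnerSpec]:
    """The default tuning grid: max depth {2,4,6,8} x estimators {22,23,24}."""
    return [
        BinaryLearnerSpec.make("xgboost", max_depth=d, n_estimators=ne)
        for d in (2, 4, 6, 8)
        for ne in (22, 23, 24)
    ]
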