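"""Multi-label evaluation: Hamming loss, precision, recall, F1.

Three granularities are supported:

* ``single_sample_over_labels`` — metrics computed from one sample's full
  label-vector confusion (the single-organism evaluation setting, where an
  organism is one sample and its pathway complement is the label vector);
* ``sample_average`` — metrics computed per sample then averaged over
  samples (the community/metagenome evaluation setting);
* ``per_label`` — metrics per label column (used to rank chain orders).

Zero-division conventions (per sample or per label unit): empty truth and
empty prediction score P = R = F1 = 1; an empty prediction against
non-empty truth scores P = 0; empty truth against a non-empty prediction
scores R = 0.  The chain-ranking caller overrides the empty-empty score to
0 so labels with no positive validation support rank last.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "hamming_loss",
    "prf1",
    "evaluate",
]

GRANULARITIES = ("single_sample_over_labels", "sample_average", "per_label")


def _check_pair(true_labels, predicted):
    T = np.asarray(true_labels)
    P = np.asarray(predicted)
    if T.ndim == 1:
        T = T[None, :]
    if P.ndim == 1:
        P = P[None, :]
    if T.shape != P.shape:
        raise ValidationError(f"shape mismatch: true {T.shape} vs predicted {P.shape}")
    for name, M in (("true", T), ("predicted", P)):
        if not np.all(np.isin(M, (-1, 1))):
            raise ValidationError(f"{name} labels must be in {{-1,+1}}")
    return T, P


@dataclass
class ConfusionCounts:
    """TP/FP/FN/TN tallies per sample (length n) and per label (length t)."""

    tp_sample: np.ndarray
    fp_sample: np.ndarray
    fn_sample: np.ndarray
    tn_sample: np.ndarray
    tp_label: np.ndarray
    fp_label: np.ndarray
    fn_label: np.ndarray
    tn_label: np.ndarray

    @property
    def totals(self) -> dict:
        return {
            "TP": int(self.tp_sample.sum()),
            "FP": int(self.fp_sample.sum()),
            "FN": int(self.fn_sample.sum()),
            "TN": int(self.tn_sample.sum()),
        }


def confusion_counts(true_labels, predicted) -> ConfusionCounts:
    T, P = _check_pair(true_labels, predicted)
    tp = (T == 1) & (P == 1)
    fp = (T == -1) & (P == 1)
    fn = (T == 1) & (P == -1)
    tn = (T == -1) & (P == -1)
    return ConfusionCounts(
        tp.sum(1), fp.sum(1), fn.sum(1), tn.sum(1),
        tp.sum(0), fp.sum(0), fn.sum(0), tn.sum(0),
    )


def hamming_loss(true_labels, predicted) -> float:
    """Fraction of (sample, label) cells where prediction differs from truth."""
    T, P = _check_pair(true_labels, predicted)
    return float(np.mean(T != P))


def _prf1_from_counts(tp, fp, fn, empty_both: float):
    """Vectorized P/R/F1 with the documented zero-division conventions."""
    tp = np.asarray(tp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    fn = np.asarray(fn, dtype=float)
    both_empty = (tp + fp == 0) & (tp + fn == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1e-300), 0.0)
        rec = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1e-300), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / np.maximum(prec + rec, 1e-300), 0.0)
    prec = np.where(both_empty, empty_both, prec)
    rec = np.where(both_empty, empty_both, rec)
    f1 = np.where(both_empty, empty_both, f1)
    return prec, rec, f1


def prf1(true_labels, predicted, granularity: str = "sample_average", empty_both: float = 1.0):
    """Precision, recall and F1 at the requested granularity.

    Returns scalars for ``single_sample_over_labels`` and
    ``sample_average``; length-t arrays for ``per_label``.
    """
    if granularity not in GRANULARITIES:
        raise ValidationError(f"granularity must be one of {GRANULARITIES}")
    cc = confusion_counts(true_labels, predicted)
    if granularity == "single_sample_over_labels":
        T, _ = _check_pair(true_labels, predicted)
        if T.shape[0] != 1:
            raise ValidationError(
                "single_sample_over_labels requires exactly one sample "
                f"(got {T.shape[0]})"
            )
        p, r, f = _prf1_from_counts(cc.tp_sample, cc.fp_sample, cc.fn_sample, empty_both)
        return float(p[0]), float(r[0]), float(f[0])
    if granularity == "sample_average":
        p, r, f = _prf1_from_counts(cc.tp_sample, cc.fp_sample, cc.fn_sample, empty_both)
        return float(p.mean()), float(r.mean()), float(f.mean())
    p, r, f = _prf1_from_counts(cc.tp_label, cc.fp_label, cc.fn_label, empty_both)
    return p, r, f


@dataclass
class MetricsReport:
    """Evaluation summary serializable to JSON."""

    granularity: str
    n: int
    t: int
    hamming_loss: float
    precision: float
    recall: float
    f1: float
    counts: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def evaluate(model, features, true_labels, granularity: str = "sample_average") -> MetricsReport:
    """Predict with ``model`` on ``features`` and score against the truth."""
    T = np.asarray(true_labels)
    pred = model.predict(features)
    cc = confusion_counts(T, pred)
    res = prf1(T, pred, granularity=granularity)
    if granularity == "per_label":
        p, r, f = (float(np.mean(v)) for v in res)
    else:
        p, r, f = res
    Tm = T if T.ndim == 2 else T[None, :]
    return MetricsReport(
        granularity=granularity,
        n=int(Tm.shape[0]),
        t=int(Tm.shape[1]),
        hamming_loss=hamming_loss(T, pred),
        precision=p,
        recall=r,
        f1=f,
        counts=cc.totals,
    )
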