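"""Feature engineering: abundance (AB) and reaction-evidence (RE) groups.

The AB transform is the identity embedding of the reaction-abundance
vector in catalog order — the total occurrence count of each enzymatic
reaction.  The RE transform is a small registry of named summary features
describing the sample's reactome (how much of the catalog is present, the
shape of the nonzero abundance distribution, coverage of pathway reaction
sets, prevalence of incomplete EC classes).  The enabled groups are
concatenated, AB first by convention, into the m-dimensional model input.

Per-label feature groups (pathway evidence and friends) are excluded by
design: the binary learners used here take one shared feature vector per
sample, and per-label features do not fit that contract.

Order statistics on an empty support (the all-zero sample) return 0 so
degenerate samples flow through the pipeline rather than erroring.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, ValidationError
from .refdb import ReferenceDatabase
from .synth import MultiLabelDataset

__all__ = [
    "FeatureConfig",
    "FeatureLayout",
    "DEFAULT_RE_FEATURES",
    "abundance_features",
    "reaction_evidence_features",
    "transform_dataset",
    "PathwayFeaturizer",
]


def _nonzero(row: np.ndarray) -> np.ndarray:
    return row[row > 0]


def _re_total_abundance(row, db, ctx):
    return float(row.sum())


def _re_n_distinct(row, db, ctx):
    return float(np.count_nonzero(row))


def _re_fraction_present(row, db, ctx):
    return float(np.count_nonzero(row) / db.r)


def _re_mean_nonzero(row, db, ctx):
    nz = _nonzero(row)
    return float(nz.mean()) if nz.size else 0.0


def _re_max_nonzero(row, db, ctx):
    nz = _nonzero(row)
    return float(nz.max()) if nz.size else 0.0


def _re_median_nonzero(row, db, ctx):
    nz = _nonzero(row)
    return float(np.median(nz)) if nz.size else 0.0


def _re_n_incomplete_present(row, db, ctx):
    return float(sum(1 for i in np.flatnonzero(row) if db.reactions[i].endswith("-")))


def _pathway_coverages(row, db, ctx):
    present = row > 0
    return np.array([present[idx].mean() for idx in ctx["pathway_indices"]])


def _re_pathway_coverage_mean(row, db, ctx):
    return float(_pathway_coverages(row, db, ctx).mean())


def _re_pathway_coverage_max(row, db, ctx):
    return float(_pathway_coverages(row, db, ctx).max())


RE_FEATURE_REGISTRY = {
    "total_abundance": _re_total_abundance,
    "n_distinct_reactions": _re_n_distinct,
    "fraction_present": _re_fraction_present,
    "mean_nonzero_abundance": _re_mean_nonzero,
    "max_nonzero_abundance": _re_max_nonzero,
    "median_nonzero_abundance": _re_median_nonzero,
    "n_incomplete_ec_present": _re_n_incomplete_present,
    "pathway_coverage_mean": _re_pathway_coverage_mean,
    "pathway_coverage_max": _re_pathway_coverage_max,
}

DEFAULT_RE_FEATURES = tuple(RE_FEATURE_REGISTRY)


@dataclass(frozen=True)
class FeatureConfig:
    """Enabled feature groups (ordered; AB is mandatory and first) and the
    enabled RE feature names in output order."""

    groups: tuple[str, ...] = ("AB",)
    re_features: tuple[str, ...] = DEFAULT_RE_FEATURES

    def __post_init__(self):
        if not self.groups:
            raise ConfigError("at least one feature group must be enabled")
        if "AB" not in self.groups:
            raise ConfigError("the AB group is mandatory")
        unknown_groups = set(self.groups) - {"AB", "RE"}
        if unknown_groups:
            raise ConfigError(f"unknown feature groups: {sorted(unknown_groups)}")
        unknown = set(self.re_features) - set(RE_FEATURE_REGISTRY)
        if unknown:
            raise ConfigError(f"unknown RE feature names: {sorted(unknown)}")
        if "RE" in self.groups and not self.re_features:
            raise ConfigError("RE group enabled but no RE features selected")


@dataclass(frozen=True)
class FeatureLayout:
    """Named spans mapping each group to its column range in the output."""

    spans: tuple[tuple[str, int, int], ...]
    feature_names: tuple[str, ...]

    @property
    def m(self) -> int:
        return self.spans[-1][2] if self.spans else 0

    def span(self, group: str) -> tuple[int, int]:
        for g, a, b in self.spans:
            if g == group:
                return a, b
        raise KeyError(group)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for name in self.feature_names:
            h.update(name.encode() + b"\x00")
        return h.hexdigest()


def abundance_features(abundance_row, db: ReferenceDatabase) -> np.ndarray:
    """phi^ab: the abundance vector itself, in catalog order."""
    row = np.asarray(abundance_row, dtype=np.float64)
    if row.ndim != 1 or row.shape[0] != db.r:
        raise ValidationError(f"abundance row must have length r={db.r}, got shape {row.shape}")
    return row.copy()


def reaction_evidence_features(
    abundance_row, db: ReferenceDatabase, config: FeatureConfig | None = None
) -> np.ndarray:
    """phi^re: enabled reaction-evidence summary features, in config order."""
    config = config or FeatureConfig(groups=("AB", "RE"))
    row = np.asarray(abundance_row, dtype=np.float64)
    if row.ndim != 1 or row.shape[0] != db.r:
        raise ValidationError(f"abundance row must have length r={db.r}, got shape {row.shape}")
    ctx = {"pathway_indices": [db.pathway_reaction_indices(j) for j in range(db.t)]}
    return np.array(
        [RE_FEATURE_REGISTRY[name](row, db, ctx) for name in config.re_features],
        dtype=np.float64,
    )


class PathwayFeaturizer:
    """Transformer mapping an (n, r) abundance matrix to the (n, m) model
    input by concatenating the enabled group transforms row-wise.

    scikit-learn transformer conventions: ``fit`` validates and freezes the
    layout, ``transform`` is stateless per row, ``get_params``/``set_params``
    make it pipeline-compatible.
    """

    def __init__(self, db: ReferenceDatabase, groups=("AB",), re_features=DEFAULT_RE_FEATURES):
        self.db = db
        self.groups = tuple(groups)
        self.re_features = tuple(re_features)

    def get_params(self, deep=True):
        return {"db": self.db, "groups": self.groups, "re_features": self.re_features}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None):
        cfg = FeatureConfig(groups=self.groups, re_features=self.re_features)
        spans = []
        names: list[str] = []
        start = 0
        for g in cfg.groups:
            width = self.db.r if g == "AB" else len(cfg.re_features)
            spans.append((g, start, start + width))
            if g == "AB":
                names.extend(f"AB:{rid}" for rid in self.db.reactions)
            else:
                names.extend(f"RE:{f}" for f in cfg.re_features)
            start += width
        self.config_ = cfg
        self.layout_ = FeatureLayout(tuple(spans), tuple(names))
        self._ctx = {
            "pathway_indices": [self.db.pathway_reaction_indices(j) for j in range(self.db.t)]
        }
        return self

    def transform(self, abundances) -> np.ndarray:
        if not hasattr(self, "layout_"):
            self.fit()
        A = np.asarray(abundances, dtype=np.float64)
        if A.ndim != 2 or A.shape[1] != self.db.r:
            raise ValidationError(f"abundance matrix must be (n, r={self.db.r}), got {A.shape}")
        X = np.empty((A.shape[0], self.layout_.m), dtype=np.float64)
        for g, a, b in self.layout_.spans:
            if g == "AB":
                X[:, a:b] = A
            else:
                for i in range(A.shape[0]):
                    X[i, a:b] = [
                        RE_FEATURE_REGISTRY[name](A[i], self.db, self._ctx)
                        for name in self.config_.re_features
                    ]
        return X

    def fit_transform(self, abundances, y=None) -> np.ndarray:
        return self.fit().transform(abundances)


def transform_dataset(
    ds: MultiLabelDataset, db: ReferenceDatabase, config: FeatureConfig | None = None
):
    """Feature-transform a whole dataset; returns ``(X, layout)``.

    Raises :class:`ConsistencyError` if the dataset was generated from a
    different database (fingerprint mismatch).
    """
    config = config or FeatureConfig()
    ds.check_db(db)
    fz = PathwayFeaturizer(db, groups=config.groups, re_features=config.re_features).fit()
    return fz.transform(ds.abundances), fz.layout_
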