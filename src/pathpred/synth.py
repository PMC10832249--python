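"""Synthetic multi-label pathway dataset generation.

Emulates the construction of corrupted synthetic training corpora for
pathway prediction: each sample selects a Poisson-distributed number of
pathways from the reference database, pools their reaction multisets, and
corrupts the pooled evidence to mimic errors introduced by upstream
annotation (missed enzymes, spurious EC assignments).

The corruption model is parametric and deliberately simple: each reaction
occurrence of a selected pathway is independently *removed* with
probability ``p_remove``, and a Poisson(``p_insert``) number of spurious
occurrences per selected pathway is *inserted*, drawn uniformly from a
configurable pool.  The historical corrupted corpora this emulates were
built with constraints defined elsewhere and not restated here; this
scheme is a documented stand-in, not a reproduction (see docs/methods.md).

Randomness uses a single numpy Generator advanced in a fixed, documented
order (sample loop -> pathway selection -> per-pathway corruption in
pathway-index order), so a seed fixes the dataset byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ConsistencyError, ValidationError
from .refdb import ReferenceDatabase

__all__ = [
    "CorruptionConfig",
    "GeneratorConfig",
    "MultiLabelDataset",
    "sample_pathway_set",
    "corrupt_reactions",
    "generate_dataset",
    "dataset_stats",
    "write_dataset",
    "load_dataset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorruptionConfig:
    """Noise applied to each selected pathway's reaction multiset.

    p_remove : probability that a single retained reaction occurrence is
        deleted (independent Bernoulli per occurrence).
    p_insert : expected number of spurious occurrences added per selected
        pathway (rate of a Poisson draw).
    insert_pool : where spurious reactions are drawn from — the catalog
        minus the pathway's own reactions (default), or the whole catalog.
    """

    p_remove: float = 0.1
    p_insert: float = 0.5
    insert_pool: str = "catalog_minus_pathway"

    def __post_init__(self):
        if not (0.0 <= self.p_remove <= 1.0):
            raise ConfigError("p_remove must be in [0, 1]")
        if self.p_insert < 0:
            raise ConfigError("p_insert must be >= 0")
        if self.insert_pool not in ("catalog_minus_pathway", "whole_catalog"):
            raise ConfigError(f"unknown insert_pool {self.insert_pool!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full dataset-generation configuration.

    ``lam`` is the mean of the Poisson distribution governing the number of
    pathways per sample (truncated to [1, t] at draw time).
    """

    n_samples: int
    lam: float
    corruption: CorruptionConfig = field(default_factory=CorruptionConfig)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.lam <= 0:
            raise ConfigError("lambda must be > 0")

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "lambda": self.lam,
            "p_remove": self.corruption.p_remove,
            "p_insert": self.corruption.p_insert,
            "insert_pool": self.corruption.insert_pool,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(
            n_samples=int(d["n_samples"]),
            lam=float(d["lambda"]),
            corruption=CorruptionConfig(
                p_remove=float(d.get("p_remove", 0.1)),
                p_insert=float(d.get("p_insert", 0.5)),
                insert_pool=d.get("insert_pool", "catalog_minus_pathway"),
            ),
            seed=int(d["seed"]),
        )


@dataclass
class MultiLabelDataset:
    """Paired abundance / label matrices over a reference database's orderings.

    abundances : (n, r) non-negative integer reaction-occurrence counts.
    labels : (n, t) matrix over {-1, +1}; +1 marks a present pathway.
    """

    db_fingerprint: str
    abundances: np.ndarray
    labels: np.ndarray
    reaction_ids: list[str]
    pathway_ids: list[str]

    def __post_init__(self):
        self.abundances = np.asarray(self.abundances)
        self.labels = np.asarray(self.labels)
        if self.abundances.ndim != 2 or self.labels.ndim != 2:
            raise ValidationError("abundances and labels must be 2-D")
        if self.abundances.shape[0] != self.labels.shape[0]:
            raise ValidationError("abundances and labels disagree on n")
        if self.abundances.shape[1] != len(self.reaction_ids):
            raise ValidationError("abundance columns != len(reaction_ids)")
        if self.labels.shape[1] != len(self.pathway_ids):
            raise ValidationError("label columns != len(pathway_ids)")
        if np.any(self.abundances < 0):
            raise ValidationError("abundances must be non-negative")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValidationError("labels must be in {-1, +1}")

    @property
    def n(self) -> int:
        return self.abundances.shape[0]

    @property
    def r(self) -> int:
        return self.abundances.shape[1]

    @property
    def t(self) -> int:
        return self.labels.shape[1]

    def check_db(self, db: ReferenceDatabase):
        if db.fingerprint() != self.db_fingerprint:
            raise ConsistencyError(
                "dataset was generated from a different reference database "
                f"(fingerprint {self.db_fingerprint[:12]}... != {db.fingerprint()[:12]}...)"
            )


# ---------------------------------------------------------------------------
# Generation primitives
# ---------------------------------------------------------------------------

def sample_pathway_set(db: ReferenceDatabase, lam: float, rng: np.random.Generator) -> np.ndarray:
    """Draw k ~ Poisson(lam) truncated to [1, t], then k distinct pathway
    indices uniformly without replacement.  Returns sorted indices."""
    if lam <= 0:
        raise ConfigError("lambda must be > 0")
    k = int(rng.poisson(lam))
    k = min(max(k, 1), db.t)
    return np.sort(rng.choice(db.t, size=k, replace=False))


def corrupt_reactions(
    reaction_multiset,
    db: ReferenceDatabase,
    config: CorruptionConfig,
    rng: np.random.Generator,
) -> Counter:
    """Apply removal/insertion noise to one pathway's reaction multiset.

    Occurrences are visited in catalog order (deterministic RNG
    consumption).  When the insertion pool ``catalog_minus_pathway`` is
    empty because the pathway covers the whole catalog, the whole catalog
    is used instead and a warning is logged.
    """
    counts = Counter(reaction_multiset)
    unknown = set(counts) - set(db.reactions)
    if unknown:
        raise ValidationError(f"multiset contains non-catalog reactions: {sorted(unknown)}")
    out: Counter = Counter()
    for rid in sorted(counts, key=db.reaction_index):
        kept = int(rng.binomial(counts[rid], 1.0 - config.p_remove))
        if kept:
            out[rid] = kept
    n_insert = int(rng.poisson(config.p_insert))
    if n_insert:
        if config.insert_pool == "catalog_minus_pathway":
            pool = [r for r in db.reactions if r not in counts]
            if not pool:
                logger.warning(
                    "pathway covers the whole catalog; falling back to whole_catalog insert pool"
                )
                pool = db.reactions
        else:
            pool = db.reactions
        for i in rng.integers(0, len(pool), size=n_insert):
            out[pool[int(i)]] += 1
    return out


def generate_dataset(db: ReferenceDatabase, config: GeneratorConfig) -> MultiLabelDataset:
    """Generate ``config.n_samples`` corrupted samples from ``db``.

    For each sample: select pathways (Poisson(lambda) truncated to [1, t]),
    set those labels to +1, then sum each selected pathway's corrupted
    reaction multiset into the abundance row.  Reactions shared by several
    selected pathways accumulate counts.
    """
    rng = np.random.default_rng(config.seed)
    n, r, t = config.n_samples, db.r, db.t
    A = np.zeros((n, r), dtype=np.int64)
    Y = np.full((n, t), -1, dtype=np.int8)
    for i in range(n):
        selected = sample_pathway_set(db, config.lam, rng)
        Y[i, selected] = 1
        for j in selected:
            corrupted = corrupt_reactions(
                db.pathways[j].reaction_counts, db, config.corruption, rng
            )
            for rid, c in corrupted.items():
                A[i, db.reaction_index(rid)] += c
    return MultiLabelDataset(db.fingerprint(), A, Y, list(db.reactions), list(db.pathway_ids))


def dataset_stats(ds: MultiLabelDataset) -> dict:
    """Shape counts, mean label cardinality and per-pathway prevalence."""
    pos = ds.labels == 1
    return {
        "n": ds.n,
        "r": ds.r,
        "t": ds.t,
        "mean_label_cardinality": float(pos.sum(axis=1).mean()),
        "label_prevalence": pos.mean(axis=0).astype(float),
    }


# ---------------------------------------------------------------------------
# I/O — `<prefix>.features.tsv`, `<prefix>.labels.tsv`, `<prefix>.meta.json`
# ---------------------------------------------------------------------------

def write_dataset(ds: MultiLabelDataset, prefix, config: GeneratorConfig | None = None):
    """Write the dataset as two TSVs sharing row order plus a meta sidecar.

    Labels are written as {0,1} (the +-1 convention is internal and mapped
    at the boundary: 1 <-> +1, 0 <-> -1).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    idx = pd.Index([f"S{i}" for i in range(ds.n)], name="sample_id")
    pd.DataFrame(ds.abundances, index=idx, columns=ds.reaction_ids).to_csv(
        f"{prefix}.features.tsv", sep="\t"
    )
    pd.DataFrame((ds.labels == 1).astype(int), index=idx, columns=ds.pathway_ids).to_csv(
        f"{prefix}.labels.tsv", sep="\t"
    )
    meta = {"db_fingerprint": ds.db_fingerprint, "n": ds.n, "r": ds.r, "t": ds.t}
    if config is not None:
        meta["config"] = config.to_dict()
    Path(f"{prefix}.meta.json").write_text(json.dumps(meta, indent=1) + "\n")
    return prefix


def load_dataset(prefix, db: ReferenceDatabase | None = None) -> MultiLabelDataset:
    """Read a dataset written by :func:`write_dataset`; checks the database
    fingerprint when ``db`` is supplied."""
    prefix = Path(prefix)
    feats = pd.read_csv(f"{prefix}.features.tsv", sep="\t", index_col=0)
    labels = pd.read_csv(f"{prefix}.labels.tsv", sep="\t", index_col=0)
    meta = json.loads(Path(f"{prefix}.meta.json").read_text())
    ds = MultiLabelDataset(
        db_fingerprint=meta["db_fingerprint"],
        abundances=feats.to_numpy(dtype=np.int64),
        labels=np.where(labels.to_numpy(dtype=np.int8) == 1, 1, -1).astype(np.int8),
        reaction_ids=list(feats.columns),
        pathway_ids=list(labels.columns),
    )
    if db is not None:
        ds.check_db(db)
    return ds
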