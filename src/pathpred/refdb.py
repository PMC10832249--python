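"""Reference pathway database: pathways mapped to multisets of enzymatic
reactions (EC-number identifiers).

The database fixes a *stable ordering* of the ``r`` reactions and ``t``
pathways; those orderings define the column indices of every abundance,
feature and label matrix produced downstream, so they are preserved
byte-for-byte through file round trips.  Reaction ids are opaque strings:
EC numbers, including incomplete ones such as ``EC-1.2.3.-``, are used
purely as identifiers and no EC-hierarchy semantics are applied.

Two flat formats are supported:

* TSV — a header block of ``#REACTION<TAB>id`` lines declaring the reaction
  catalog and its order, followed by one pathway per line:
  ``pathway_id<TAB>reaction_id[<TAB>reaction_id...]``.  A pathway that uses
  one reaction class for several steps repeats the id (multiplicity by
  repetition).
* JSON — ``{"reactions": [...], "pathways": [{"id": ..., "reactions": [...]}]}``
  with the arrays carrying the ordering.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ParseError, ValidationError

__all__ = [
    "PathwayDef",
    "ReferenceDatabase",
    "load_reference_db",
    "write_reference_db",
    "generate_toy_db",
    "db_summary",
]


@dataclass(frozen=True)
class PathwayDef:
    """A pathway label and the multiset of reactions it comprises.

    ``reactions`` keeps occurrence order; multiplicity is encoded by
    repetition, matching the TSV dialect.
    """

    id: str
    reactions: tuple[str, ...]

    def __post_init__(self):
        if not self.id:
            raise ValidationError("pathway id must be non-empty")
        if len(self.reactions) == 0:
            raise ValidationError(f"pathway {self.id!r} has no reactions")

    @property
    def reaction_counts(self) -> Counter:
        return Counter(self.reactions)


@dataclass
class ReferenceDatabase:
    """Ordered catalog of reactions and pathway definitions.

    Attributes
    ----------
    reactions : list of str
        The reaction catalog; index in this list is the reaction's column
        index in every abundance/feature matrix.
    pathways : list of PathwayDef
        Pathway definitions; index here is the pathway's label column.
    """

    reactions: list[str]
    pathways: list[PathwayDef]
    _reaction_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.reactions) < 1:
            raise ValidationError("reaction catalog must be non-empty (r >= 1)")
        if len(self.pathways) < 1:
            raise ValidationError("pathway list must be non-empty (t >= 1)")
        if any(not rid for rid in self.reactions):
            raise ValidationError("reaction ids must be non-empty")
        if len(set(self.reactions)) != len(self.reactions):
            dupes = [r for r, c in Counter(self.reactions).items() if c > 1]
            raise ValidationError(f"duplicate reaction ids: {dupes}")
        pw_ids = [p.id for p in self.pathways]
        if len(set(pw_ids)) != len(pw_ids):
            dupes = [p for p, c in Counter(pw_ids).items() if c > 1]
            raise ValidationError(f"duplicate pathway ids: {dupes}")
        catalog = set(self.reactions)
        for p in self.pathways:
            unknown = set(p.reactions) - catalog
            if unknown:
                raise ValidationError(
                    f"pathway {p.id!r} references reactions absent from the "
                    f"catalog: {sorted(unknown)}"
                )
        self._reaction_index = {r: i for i, r in enumerate(self.reactions)}

    # -- stable orderings ---------------------------------------------------
    @property
    def r(self) -> int:
        return len(self.reactions)

    @property
    def t(self) -> int:
        return len(self.pathways)

    @property
    def pathway_ids(self) -> list[str]:
        return [p.id for p in self.pathways]

    def reaction_index(self, reaction_id: str) -> int:
        return self._reaction_index[reaction_id]

    def pathway_reaction_indices(self, j: int) -> np.ndarray:
        """Distinct catalog indices of pathway ``j``'s reactions, sorted."""
        idx = {self._reaction_index[r] for r in self.pathways[j].reactions}
        return np.array(sorted(idx), dtype=np.intp)

    def pathway_count_vector(self, j: int) -> np.ndarray:
        """Length-r integer vector of pathway ``j``'s reaction multiplicities."""
        v = np.zeros(self.r, dtype=np.int64)
        for rid in self.pathways[j].reactions:
            v[self._reaction_index[rid]] += 1
        return v

    def fingerprint(self) -> str:
        """SHA-256 over the orderings and multiset contents; identifies the
        database across files so mismatched artifacts are rejected early."""
        h = hashlib.sha256()
        for rid in self.reactions:
            h.update(rid.encode() + b"\x00")
        h.update(b"\x01")
        for p in self.pathways:
            h.update(p.id.encode() + b"\x00")
            for rid in p.reactions:
                h.update(rid.encode() + b"\x02")
        return h.hexdigest()

    def __eq__(self, other):
        return (
            isinstance(other, ReferenceDatabase)
            and self.reactions == other.reactions
            and self.pathways == other.pathways
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("tsv", "json"):
            raise ValidationError(f"unknown format {format!r}; use 'tsv' or 'json'")
        return format
    return "json" if path.suffix.lower() == ".json" else "tsv"


def load_reference_db(path, format: str | None = None) -> ReferenceDatabase:
    """Read a reference database from ``path`` (TSV or JSON dialect).

    Reaction and pathway order equal file order.  Malformed lines raise
    :class:`ParseError` naming the line; invariant violations raise
    :class:`ValidationError`.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            try:
                obj = json.load(fh)
            except json.JSONDecodeError as e:
                raise ParseError(f"invalid JSON: {e}", line=e.lineno) from e
        if not isinstance(obj, dict) or "reactions" not in obj or "pathways" not in obj:
            raise ParseError("JSON database must have 'reactions' and 'pathways' keys")
        pathways = []
        for p in obj["pathways"]:
            if not isinstance(p, dict) or "id" not in p or "reactions" not in p:
                raise ParseError("each pathway must be {'id':..., 'reactions':[...]}")
            pathways.append(PathwayDef(str(p["id"]), tuple(map(str, p["reactions"]))))
        return ReferenceDatabase([str(r) for r in obj["reactions"]], pathways)

    reactions: list[str] = []
    pathways: list[PathwayDef] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if fields[0] == "#REACTION":
                if len(fields) != 2 or not fields[1]:
                    raise ParseError(
                        "#REACTION line must be '#REACTION<TAB>reaction_id'",
                        line=lineno,
                    )
                reactions.append(fields[1])
            elif fields[0].startswith("#"):
                continue  # comment
            else:
                if len(fields) < 2 or not fields[0]:
                    raise ParseError(
                        "pathway line must be 'pathway_id<TAB>reaction_id[...]'",
                        line=lineno,
                    )
                pathways.append(PathwayDef(fields[0], tuple(fields[1:])))
    return ReferenceDatabase(reactions, pathways)


def write_reference_db(db: ReferenceDatabase, path, format: str | None = None):
    """Write ``db`` so that :func:`load_reference_db` reproduces it exactly."""
    if not isinstance(db, ReferenceDatabase):
        raise ValidationError("db must be a ReferenceDatabase")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        obj = {
            "reactions": db.reactions,
            "pathways": [{"id": p.id, "reactions": list(p.reactions)} for p in db.pathways],
        }
        path.write_text(json.dumps(obj, indent=1) + "\n", encoding="utf-8")
    else:
        lines = [f"#REACTION\t{rid}" for rid in db.reactions]
        for p in db.pathways:
            lines.append("\t".join([p.id, *p.reactions]))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Fixture generator
# ---------------------------------------------------------------------------

def generate_toy_db(
    n_pathways: int,
    reactions_per_pathway: int,
    shared_fraction: float = 0.0,
    seed: int = 0,
) -> ReferenceDatabase:
    """Generate a small synthetic reference database.

    With ``shared_fraction == 0`` the pathway reaction sets are pairwise
    disjoint and ``r == n_pathways * reactions_per_pathway``.  With a
    positive fraction, ``round(shared_fraction * reactions_per_pathway)``
    of each pathway's reactions are drawn (without replacement, per
    pathway) from a common pool of promiscuous reaction classes; pool
    members carry truncated EC ids (trailing ``-``) so downstream features
    sensitive to incomplete EC numbers are exercised.  The catalog lists
    exactly the reactions in use, ordered by first appearance.
    Deterministic given ``seed``.
    """
    if n_pathways < 1 or reactions_per_pathway < 1:
        raise ValidationError("n_pathways and reactions_per_pathway must be >= 1")
    if not (0.0 <= shared_fraction <= 1.0):
        raise ValidationError("shared_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_shared = int(round(shared_fraction * reactions_per_pathway))
    n_unique = reactions_per_pathway - n_shared
    pool = [f"EC-9.{j + 1}.1.-" for j in range(max(2 * n_shared, n_shared))]
    pathways = []
    for p in range(n_pathways):
        shared: list[str] = []
        if n_shared:
            pick = np.sort(rng.choice(len(pool), size=n_shared, replace=False))
            shared = [pool[i] for i in pick]
        unique = [f"EC-{p + 1}.{q + 1}.1.1" for q in range(n_unique)]
        pathways.append(PathwayDef(f"PWY-{p + 1:04d}", tuple(shared + unique)))
    catalog: list[str] = []
    seen: set[str] = set()
    for p in pathways:
        for rid in p.reactions:
            if rid not in seen:
                seen.add(rid)
                catalog.append(rid)
    return ReferenceDatabase(catalog, pathways)


def db_summary(db: ReferenceDatabase) -> dict:
    """Counts of reactions (r), pathways (t) and the distribution of
    reactions-per-pathway (multiset sizes; values sum to t)."""
    sizes = Counter(len(p.reactions) for p in db.pathways)
    return {
        "r": db.r,
        "t": db.t,
        "reactions_per_pathway": {int(k): int(v) for k, v in sorted(sizes.items())},
    }
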