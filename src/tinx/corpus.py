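"""Readers for the tagged-mention corpus and the target metadata catalog.

The mention table is a 3-column TSV (``pub_id``, ``entity_kind``,
``entity_id``) in the style of text-mining tagger output: one row per tagged
entity occurrence, ``#``-prefixed comment lines allowed, no header. The
target catalog is a headered TSV carrying the gene symbol, Target Development
Level (TDL) and IDG protein-family annotation per target accession.

Publication identifiers are opaque strings (typically PubMed ids, but PMC ids
and synthetic ids work identically).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

logger = logging.getLogger(__name__)


class EntityKind(str, Enum):
    TARGET = "target"
    DISEASE = "disease"


#: Target Development Level categories (Tclin > Tchem > Tbio > Tdark by
#: decreasing knowledge); values outside this set map to "unknown".
TDL_VALUES = frozenset({"Tclin", "Tchem", "Tbio", "Tdark", "unknown"})

#: IDG protein family groupings.
IDG_FAMILY_VALUES = frozenset(
    {"GPCR", "Kinase", "IonChannel", "NuclearReceptor", "Other", "unknown"}
)


@dataclass(frozen=True)
class MentionRow:
    """One tagged entity occurrence in one publication."""

    pub_id: str
    entity_kind: EntityKind
    entity_id: str

    def __post_init__(self) -> None:
        if not self.pub_id:
            raise ValueError("pub_id must be non-empty")
        if not self.entity_id:
            raise ValueError("entity_id must be non-empty")


@dataclass
class Publication:
    """One publication with its duplicate-free sets of tagged entities.

    ``n_targets`` and ``n_diseases`` are the fractional-counting denominators
    T_k and D_k: the numbers of distinct targets and diseases tagged in this
    publication.
    """

    pub_id: str
    targets: set[str] = field(default_factory=set)
    diseases: set[str] = field(default_factory=set)
    date: Optional[str] = None
    title: Optional[str] = None

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)


@dataclass(frozen=True)
class TargetRecord:
    """A protein/gene target with TDL and IDG-family annotation."""

    target_id: str
    symbol: str
    tdl: str = "unknown"
    idg_family: str = "unknown"


@dataclass
class PublicationIndex:
    """Mutually consistent maps from publications, targets and diseases.

    Invariant: ``p in by_target[t]`` iff ``t in by_pub[p].targets`` and
    symmetrically for diseases.
    """

    by_pub: dict[str, Publication] = field(default_factory=dict)
    by_target: dict[str, set[str]] = field(default_factory=dict)
    by_disease: dict[str, set[str]] = field(default_factory=dict)

    def check_consistency(self) -> None:
        """Raise AssertionError if the three maps disagree."""
        for t, pubs in self.by_target.items():
            assert all(t in self.by_pub[p].targets for p in pubs)
        for d, pubs in self.by_disease.items():
            assert all(d in self.by_pub[p].diseases for p in pubs)
        for p, pub in self.by_pub.items():
            assert all(p in self.by_target[t] for t in pub.targets)
            assert all(p in self.by_disease[d] for d in pub.diseases)


def read_mentions(path: str | Path, strict: bool = True) -> list[MentionRow]:
    """Read a mention TSV into a list of rows; no aggregation or dedup.

    Blank lines and lines starting with ``#`` are ignored. In strict mode
    (default) a malformed line -- wrong column count or unknown entity kind --
    is fatal; in lenient mode it is logged and skipped.
    """
    path = Path(path)
    rows: list[MentionRow] = []
    n_skipped = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            problem = None
            if len(parts) != 3:
                problem = f"expected 3 tab-separated columns, got {len(parts)}"
            else:
                pub_id, kind, entity_id = (p.strip() for p in parts)
                if kind not in (EntityKind.TARGET.value, EntityKind.DISEASE.value):
                    problem = f"unknown entity kind {kind!r}"
                elif not pub_id or not entity_id:
                    problem = "empty pub_id or entity_id"
            if problem is not None:
                msg = f"{path}:{lineno}: {problem}"
                if strict:
                    raise ValueError(msg)
                logger.warning("skipping malformed mention row: %s", msg)
                n_skipped += 1
                continue
            rows.append(MentionRow(pub_id, EntityKind(kind), entity_id))
    if n_skipped:
        logger.warning("%s: skipped %d malformed rows", path, n_skipped)
    return rows


def write_mentions(rows: Iterable[MentionRow], path: str | Path) -> None:
    """Write mention rows in the same TSV dialect ``read_mentions`` accepts."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for r in rows:
            fh.write(f"{r.pub_id}\t{r.entity_kind.value}\t{r.entity_id}\n")


def read_pubmeta(path: str | Path) -> dict[str, tuple[Optional[str], Optional[str]]]:
    """Read the optional publication metadata table (pub_id, date, title)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"pub_id", "date", "title"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    meta: dict[str, tuple[Optional[str], Optional[str]]] = {}
    for row in df.itertuples(index=False):
        meta[row.pub_id] = (row.date or None, row.title or None)
    return meta


def build_publications(
    rows: Iterable[MentionRow],
    pub_meta: Optional[Mapping[str, tuple[Optional[str], Optional[str]]]] = None,
) -> PublicationIndex:
    """Aggregate mention rows into a consistent :class:`PublicationIndex`.

    Duplicate (pub_id, kind, entity_id) rows collapse into one set member.
    Publications left with zero targets AND zero diseases are dropped (their
    count is logged); publications mentioning only one entity kind are kept
    because they still enter the novelty denominators.
    """
    index = PublicationIndex()
    for row in rows:
        pub = index.by_pub.get(row.pub_id)
        if pub is None:
            pub = Publication(row.pub_id)
            index.by_pub[row.pub_id] = pub
        if row.entity_kind is EntityKind.TARGET:
            pub.targets.add(row.entity_id)
            index.by_target.setdefault(row.entity_id, set()).add(row.pub_id)
        else:
            pub.diseases.add(row.entity_id)
            index.by_disease.setdefault(row.entity_id, set()).add(row.pub_id)

    empty = [p for p, pub in index.by_pub.items() if not pub.targets and not pub.diseases]
    if empty:
        logger.info("dropping %d publications with no tagged entities", len(empty))
        for p in empty:
            del index.by_pub[p]

    if pub_meta:
        for pub_id, (date, title) in pub_meta.items():
            pub = index.by_pub.get(pub_id)
            if pub is not None:
                pub.date = date
                pub.title = title
    return index


def read_targets(path: str | Path) -> dict[str, TargetRecord]:
    """Read the target catalog TSV into a dict keyed by target_id.

    TDL or IDG-family strings outside the known vocabularies fall back to
    ``"unknown"`` with a warning. Duplicate target ids and missing required
    columns are fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"target_id", "symbol", "tdl", "idg_family"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    dupes = df["target_id"][df["target_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate target ids {sorted(set(dupes))}")

    catalog: dict[str, TargetRecord] = {}
    for row in df.itertuples(index=False):
        tdl, fam = row.tdl or "unknown", row.idg_family or "unknown"
        if tdl not in TDL_VALUES:
            logger.warning("target %s: unknown TDL %r, using 'unknown'", row.target_id, tdl)
            tdl = "unknown"
        if fam not in IDG_FAMILY_VALUES:
            logger.warning(
                "target %s: unknown IDG family %r, using 'unknown'", row.target_id, fam
            )
            fam = "unknown"
        catalog[row.target_id] = TargetRecord(row.target_id, row.symbol, tdl, fam)
    return catalog
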