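"""Disease Ontology parsing and publication-support propagation.

Disease associations are browsed hierarchically: selecting a parent term must
surface everything published about its descendants. We therefore propagate
*publication sets*, not scores, up the ``is_a`` DAG: a publication that
directly mentions disease ``d`` supports (t, a) for every target t it mentions
and every ancestor a of d, counted once per publication. Set-union
propagation guarantees that an abstract mentioning two siblings contributes a
single unit of support to their shared parent rather than two.

Only ``is_a`` edges are traversed; other OBO relationship types are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import obonet

from tinx.corpus import PublicationIndex

logger = logging.getLogger(__name__)


@dataclass
class DiseaseTerm:
    """One Disease Ontology term (is_a parents only)."""

    doid: str
    name: str = ""
    parents: frozenset[str] = frozenset()
    obsolete: bool = False
    alt_ids: frozenset[str] = frozenset()
    replaced_by: Optional[str] = None


class OntologyGraph:
    """The is_a DAG over non-obsolete Disease Ontology terms.

    ``terms`` maps every loaded doid (including obsolete ones) to its
    :class:`DiseaseTerm`; the traversable DAG is restricted to non-obsolete
    terms. Ancestor queries are memoized.
    """

    def __init__(self, terms: dict[str, DiseaseTerm]):
        self.terms = terms
        self._alt: dict[str, str] = {}
        for t in terms.values():
            for alt in t.alt_ids:
                self._alt.setdefault(alt, t.doid)
        self.children: dict[str, set[str]] = {
            d: set() for d, t in terms.items() if not t.obsolete
        }
        for t in terms.values():
            for p in t.parents:
                self.children.setdefault(p, set()).add(t.doid)
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def resolve(self, doid: str) -> Optional[str]:
        """Map an id to its primary, non-obsolete term id.

        alt_ids resolve to their primary term; an obsolete term with a
        ``replaced_by`` follows the replacement once. Returns None for ids
        not in the ontology at all.
        """
        primary = doid if doid in self.terms else self._alt.get(doid)
        if primary is None:
            return None
        term = self.terms[primary]
        if term.obsolete:
            if term.replaced_by is not None and term.replaced_by in self.terms:
                repl = self.terms[term.replaced_by]
                return None if repl.obsolete else repl.doid
            return None
        return primary

    def ancestors(self, doid: str) -> frozenset[str]:
        """All terms reachable from ``doid`` via is_a edges, excluding itself."""
        resolved = self.resolve(doid)
        if resolved is None:
            raise KeyError(f"unknown or unresolvable disease term: {doid!r}")
        cached = self._ancestor_cache.get(resolved)
        if cached is not None:
            return cached
        seen: set[str] = set()
        stack = list(self.terms[resolved].parents)
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(self.terms[cur].parents)
        result = frozenset(seen)
        self._ancestor_cache[resolved] = result
        return result

    def name_of(self, doid: str) -> str:
        term = self.terms.get(doid)
        return term.name if term is not None else ""


def parse_obo(path: str | Path) -> OntologyGraph:
    """Parse an OBO 1.2 flat file into an :class:`OntologyGraph`.

    Obsolete terms are loaded (so ``replaced_by`` redirects work) but carry no
    parents and are excluded from the DAG. A dangling is_a reference or a
    cycle among non-obsolete terms is fatal.
    """
    graph = obonet.read_obo(str(path), ignore_obsolete=False)

    dangling = [n for n, data in graph.nodes(data=True) if "name" not in data]
    if dangling:
        raise ValueError(f"{path}: is_a references to undefined terms: {sorted(dangling)}")

    terms: dict[str, DiseaseTerm] = {}
    for doid, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        replaced = data.get("replaced_by") or []
        parents = frozenset() if obsolete else frozenset(data.get("is_a", []))
        terms[doid] = DiseaseTerm(
            doid=doid,
            name=data.get("name", ""),
            parents=parents,
            obsolete=obsolete,
            alt_ids=frozenset(data.get("alt_id", [])),
            replaced_by=replaced[0] if replaced else None,
        )

    dag = nx.DiGraph(
        (t.doid, p) for t in terms.values() if not t.obsolete for p in t.parents
    )
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        path_str = " -> ".join(a for a, _ in cycle) + f" -> {cycle[-1][1]}"
        raise ValueError(f"{path}: cycle in is_a hierarchy: {path_str}")

    return OntologyGraph(terms)


def _resolved_terms_with_ancestors(
    diseases: set[str], graph: Optional[OntologyGraph]
) -> set[str]:
    """Direct disease mentions mapped to primary ids plus all their ancestors.

    Ids unknown to the ontology degrade gracefully to hierarchy-less leaves
    and are kept under their original id.
    """
    out: set[str] = set()
    for d in diseases:
        if graph is None:
            out.add(d)
            continue
        rid = graph.resolve(d)
        if rid is None:
            logger.debug("disease id %s not in ontology; kept as leaf", d)
            out.add(d)
        else:
            out.add(rid)
            out |= graph.ancestors(rid)
    return out


def propagate_support(
    index: PublicationIndex, graph: Optional[OntologyGraph] = None
) -> dict[tuple[str, str], frozenset[str]]:
    """Build the (target, disease) -> supporting-publication-set map.

    Every publication supports each of its targets paired with each directly
    mentioned disease *and* every ancestor of that disease. Because supports
    are sets, propagation is idempotent and a publication mentioning several
    descendants of one ancestor counts once for that ancestor. With
    ``graph=None`` the map reduces to direct co-mention pairs.
    """
    support: dict[tuple[str, str], set[str]] = {}
    for pub in index.by_pub.values():
        if not pub.targets or not pub.diseases:
            continue
        disease_terms = _resolved_terms_with_ancestors(pub.diseases, graph)
        for t in pub.targets:
            for a in disease_terms:
                support.setdefault((t, a), set()).add(pub.pub_id)
    return {pair: frozenset(pubs) for pair, pubs in support.items()}


def disease_publication_sets(
    index: PublicationIndex, graph: Optional[OntologyGraph] = None
) -> dict[str, frozenset[str]]:
    """Publications mentioning each disease term, directly or via descendants.

    Unlike :func:`propagate_support` this includes publications without any
    target mention, since a disease's novelty is a property of everything
    published about the disease, not only of target co-mentions.
    """
    pubs_of: dict[str, set[str]] = {}
    for pub in index.by_pub.values():
        for a in _resolved_terms_with_ancestors(pub.diseases, graph):
            pubs_of.setdefault(a, set()).add(pub.pub_id)
    return {d: frozenset(p) for d, p in pubs_of.items()}
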