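"""Fractional-counting bibliometric scores: novelty and importance.

For target i over the publications k that mention it::

    N_i = 1 / sum_k (1 / T_k)

where T_k is the number of distinct targets tagged in publication k. A paper
that mentions many targets says less about each of them, so it contributes a
smaller fraction to the denominator; a target mentioned only in crowded
papers keeps a high novelty. High novelty = little published about the target.

For a (target i, disease j) association over its supporting publications k::

    I_ij = sum_k 1 / (T_k * D_k)

with D_k the number of distinct *directly mentioned* disease terms in k.
Ontology propagation changes which pairs a publication supports, never its
D_k. High importance = much published tying the target to the disease.

A useful consequence: for any target whose every publication mentions at
least one disease, sum_j I_ij over its directly co-mentioned diseases equals
1/N_i exactly (each publication's 1/T_k splits across its D_k diseases).
Publications with no disease mention break that identity by design, since
the novelty denominator has no disease requirement.

All sums accumulate in publication-id-sorted order so results are
bit-reproducible regardless of input ordering.
"""

from __future__ import annotations

from typing import Mapping, Optional

import pandas as pd

from tinx.corpus import PublicationIndex, TargetRecord
from tinx.ontology import OntologyGraph, disease_publication_sets

#: Column order of the association table and associations.tsv export.
ASSOCIATION_COLUMNS = [
    "target_id",
    "symbol",
    "tdl",
    "idg_family",
    "disease_id",
    "disease_name",
    "importance",
    "target_novelty",
    "disease_novelty",
    "n_pubs",
]


def _novelty_from_pubs(pub_ids, counts: Mapping[str, int], what: str) -> float:
    pubs = sorted(pub_ids)
    if not pubs:
        raise ValueError(f"novelty undefined: {what} has no publications")
    return 1.0 / sum(1.0 / counts[p] for p in pubs)


def novelty(target_id: str, index: PublicationIndex) -> float:
    """N_i over all publications mentioning the target (disease not required)."""
    pubs = index.by_target.get(target_id)
    if not pubs:
        raise KeyError(f"target {target_id!r} has no publications")
    counts = {p: index.by_pub[p].n_targets for p in pubs}
    return _novelty_from_pubs(pubs, counts, f"target {target_id!r}")


def disease_novelty(
    disease_id: str,
    index: PublicationIndex,
    graph: Optional[OntologyGraph] = None,
) -> float:
    """Symmetric novelty for a disease term, N_j = 1 / sum_k (1/D_k).

    With an ontology, the sum runs over publications mentioning the term or
    any of its descendants (matching how support is propagated), while D_k
    stays the direct-mention count of each publication. Without an ontology
    only direct mentions count.
    """
    if graph is None:
        pubs = index.by_disease.get(disease_id)
    else:
        pubs = disease_publication_sets(index, graph).get(disease_id)
    if not pubs:
        raise KeyError(f"disease {disease_id!r} has no publications")
    counts = {p: index.by_pub[p].n_diseases for p in pubs}
    return _novelty_from_pubs(pubs, counts, f"disease {disease_id!r}")


def importance(
    target_id: str,
    disease_id: str,
    support: Mapping[tuple[str, str], frozenset[str]],
    index: PublicationIndex,
) -> float:
    """I_ij summed over the association's supporting publications."""
    pubs = support.get((target_id, disease_id))
    if not pubs:
        raise KeyError(f"no supporting publications for ({target_id!r}, {disease_id!r})")
    total = 0.0
    for p in sorted(pubs):
        pub = index.by_pub[p]
        total += 1.0 / (pub.n_targets * pub.n_diseases)
    return total


def score_all(
    index: PublicationIndex,
    support: Mapping[tuple[str, str], frozenset[str]],
    catalog: Optional[Mapping[str, TargetRecord]] = None,
    graph: Optional[OntologyGraph] = None,
) -> pd.DataFrame:
    """Score every supported (target, disease) pair into one association table.

    Returns a DataFrame with :data:`ASSOCIATION_COLUMNS` plus a ``pub_ids``
    column holding each association's supporting publication ids (sorted
    tuple). Rows are sorted by (target_id, disease_id). TDL and family
    annotations default to "unknown" for targets absent from the catalog.
    ``graph`` must be the same ontology the support map was propagated with
    (or None for a direct co-mention support map).
    """
    catalog = catalog or {}
    target_novelty_cache: dict[str, float] = {}
    disease_pub_sets = disease_publication_sets(index, graph)
    disease_novelty_cache: dict[str, float] = {}

    rows = []
    for (t, d) in sorted(support):
        pubs = support[(t, d)]
        if not pubs:
            continue
        if t not in target_novelty_cache:
            target_novelty_cache[t] = novelty(t, index)
        if d not in disease_novelty_cache:
            dpubs = disease_pub_sets[d]
            counts = {p: index.by_pub[p].n_diseases for p in dpubs}
            disease_novelty_cache[d] = _novelty_from_pubs(dpubs, counts, f"disease {d!r}")
        rec = catalog.get(t)
        rows.append(
            {
                "target_id": t,
                "symbol": rec.symbol if rec else t,
                "tdl": rec.tdl if rec else "unknown",
                "idg_family": rec.idg_family if rec else "unknown",
                "disease_id": d,
                "disease_name": graph.name_of(d) if graph else "",
                "importance": importance(t, d, support, index),
                "target_novelty": target_novelty_cache[t],
                "disease_novelty": disease_novelty_cache[d],
                "n_pubs": len(pubs),
                "pub_ids": tuple(sorted(pubs)),
            }
        )
    return pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS + ["pub_ids"])
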