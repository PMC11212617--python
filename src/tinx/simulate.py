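"""Synthetic tagged-literature corpora with known ground truth.

Two generators:

* :func:`make_golden_fixture` writes a fixed 4-publication corpus ("corpus G")
  whose novelty and importance values are small enough to evaluate by hand.
* :func:`simulate_corpus` draws random corpora — Zipf-weighted target
  popularity (so corpora contain both heavily studied and dark targets, the
  skew the tool exists to expose), truncated-Poisson entities per publication,
  and a random-tree disease ontology — and returns a :class:`GroundTruth`
  whose scores are computed by a naive double-loop oracle that shares no code
  with the scoring or ontology modules.

All randomness flows from a single seeded generator; outputs are
byte-identical for a given configuration.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# ---------------------------------------------------------------------------
# golden fixture (corpus G)
# ---------------------------------------------------------------------------

GOLDEN_X = "DOID:0000011"
GOLDEN_Y = "DOID:0000012"
GOLDEN_Z = "DOID:0000010"

#: publication -> (targets, diseases) of the golden corpus. P4 mentions a
#: target but no disease, which deliberately breaks the conservation identity
#: sum_j I_Cj == 1/N_C for target C.
GOLDEN_PUBLICATIONS = {
    "P1": ({"A"}, {GOLDEN_X}),
    "P2": ({"A", "B"}, {GOLDEN_X, GOLDEN_Y}),
    "P3": ({"B", "C"}, {GOLDEN_Y}),
    "P4": ({"C"}, set()),
}

_GOLDEN_MENTIONS = """\
# golden corpus G: 4 publications, 3 targets, 2 leaf diseases
# the duplicated first row exercises duplicate-collapse downstream
P1\ttarget\tA
P1\ttarget\tA
P1\tdisease\t{X}
P2\ttarget\tA
P2\ttarget\tB
P2\tdisease\t{X}
P2\tdisease\t{Y}
P3\ttarget\tB
P3\ttarget\tC
P3\tdisease\t{Y}
P4\ttarget\tC
""".format(X=GOLDEN_X, Y=GOLDEN_Y)

_GOLDEN_TARGETS = """\
target_id\tsymbol\ttdl\tidg_family
A\tGENE1\tTclin\tGPCR
B\tGENE2\tTbio\tKinase
C\tGENE3\tTdark\tIonChannel
"""

_GOLDEN_OBO = """\
format-version: 1.2
ontology: synthetic-disease-ontology

[Term]
id: {Z}
name: disease Z

[Term]
id: {X}
name: disease X
is_a: {Z} ! disease Z

[Term]
id: {Y}
name: disease Y
is_a: {Z} ! disease Z
""".format(X=GOLDEN_X, Y=GOLDEN_Y, Z=GOLDEN_Z)

_GOLDEN_PUBMETA = """\
pub_id\tdate\ttitle
P1\t2001-01-15\tTarget A in disease X
P2\t2005-06-01\tTargets A and B across diseases X and Y
P3\t2010-03-20\tTargets B and C in disease Y
P4\t2015-11-30\tTarget C characterization
"""


def make_golden_fixture(outdir: str | Path) -> dict[str, Path]:
    """Write corpus G (mentions, targets, obo, pubmeta) and return the paths.

    The fixture is fully deterministic: byte-identical on every call.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "mentions": (outdir / "mentions.tsv", _GOLDEN_MENTIONS),
        "targets": (outdir / "targets.tsv", _GOLDEN_TARGETS),
        "obo": (outdir / "disease.obo", _GOLDEN_OBO),
        "pubmeta": (outdir / "pubmeta.tsv", _GOLDEN_PUBMETA),
    }
    paths = {}
    for key, (path, content) in files.items():
        path.write_text(content, encoding="utf-8")
        paths[key] = path
    return paths


# ---------------------------------------------------------------------------
# random corpora
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Knobs of the random corpus generator.

    ``targets_per_pub_mean`` / ``diseases_per_pub_mean`` parameterize Poisson
    draws truncated above at the respective pool size (zero realizations are
    allowed: publications mentioning only one entity kind occur in real
    corpora and matter for the novelty/importance interplay).
    ``target_popularity`` is the Zipf exponent of the target-selection
    weights: 0 = uniform, larger = a few heavily studied targets and a long
    dark tail. ``ontology_depth`` is the number of levels of the random is_a
    tree below its root.
    """

    seed: int
    n_targets: int = 50
    n_diseases: int = 30
    n_pubs: int = 500
    targets_per_pub_mean: float = 1.5
    diseases_per_pub_mean: float = 1.5
    target_popularity: float = 1.0
    ontology_depth: int = 3

    def __post_init__(self) -> None:
        if self.n_targets < 1 or self.n_diseases < 1:
            raise ValueError("n_targets and n_diseases must be >= 1")
        if self.n_pubs < 0:
            raise ValueError("n_pubs must be >= 0")
        if self.targets_per_pub_mean <= 0 or self.diseases_per_pub_mean <= 0:
            raise ValueError("per-publication means must be positive")
        if self.ontology_depth < 1:
            raise ValueError("ontology_depth must be >= 1")
        if self.target_popularity < 0:
            raise ValueError("target_popularity must be >= 0")


@dataclass
class GroundTruth:
    """Oracle view of a simulated corpus, computed by naive enumeration."""

    publications: dict[str, tuple[frozenset[str], frozenset[str]]]
    parents: dict[str, str]  # child doid -> parent doid (tree)
    target_pub_counts: dict[str, int] = field(default_factory=dict)
    novelty: dict[str, float] = field(default_factory=dict)
    disease_novelty: dict[str, float] = field(default_factory=dict)
    importance_direct: dict[tuple[str, str], float] = field(default_factory=dict)
    support: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    importance_propagated: dict[tuple[str, str], float] = field(default_factory=dict)


def _oracle_ancestors(doid: str, parents: dict[str, str]) -> set[str]:
    out: set[str] = set()
    cur = doid
    while cur in parents:
        cur = parents[cur]
        out.add(cur)
    return out


def _compute_ground_truth(
    publications: dict[str, tuple[frozenset[str], frozenset[str]]],
    parents: dict[str, str],
) -> GroundTruth:
    """Naive double-loop evaluation of both scores and the propagated support."""
    gt = GroundTruth(publications=publications, parents=parents)

    all_targets = sorted({t for ts, _ in publications.values() for t in ts})
    for t in all_targets:
        denom = 0.0
        count = 0
        for pid in sorted(publications):
            ts, _ = publications[pid]
            if t in ts:
                denom += 1.0 / len(ts)
                count += 1
        gt.target_pub_counts[t] = count
        gt.novelty[t] = 1.0 / denom

    # propagated support and disease publication sets
    d_pubs: dict[str, set[str]] = {}
    sup: dict[tuple[str, str], set[str]] = {}
    for pid in sorted(publications):
        ts, ds = publications[pid]
        terms: set[str] = set()
        for d in ds:
            terms.add(d)
            terms |= _oracle_ancestors(d, parents)
        for a in terms:
            d_pubs.setdefault(a, set()).add(pid)
        for t in ts:
            for a in terms:
                sup.setdefault((t, a), set()).add(pid)
    gt.support = {k: frozenset(v) for k, v in sup.items()}

    for d, pubs in d_pubs.items():
        denom = sum(1.0 / len(publications[p][1]) for p in sorted(pubs))
        gt.disease_novelty[d] = 1.0 / denom

    for pid in sorted(publications):
        ts, ds = publications[pid]
        if not ts or not ds:
            continue
        w = 1.0 / (len(ts) * len(ds))
        for t in ts:
            for d in ds:
                gt.importance_direct[(t, d)] = gt.importance_direct.get((t, d), 0.0) + w

    for (t, a), pubs in gt.support.items():
        total = 0.0
        for p in sorted(pubs):
            ts, ds = publications[p]
            total += 1.0 / (len(ts) * len(ds))
        gt.importance_propagated[(t, a)] = total

    return gt


def _write_obo(path: Path, root: str, parents: dict[str, str], names: dict[str, str]) -> None:
    blocks = ["format-version: 1.2", "ontology: synthetic-disease-ontology", ""]
    for doid in [root] + sorted(d for d in names if d != root):
        blocks.append("[Term]")
        blocks.append(f"id: {doid}")
        blocks.append(f"name: {names[doid]}")
        if doid in parents:
            blocks.append(f"is_a: {parents[doid]} ! {names[parents[doid]]}")
        blocks.append("")
    path.write_text("\n".join(blocks), encoding="utf-8")


def simulate_corpus(
    cfg: SimulationConfig, outdir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Generate a random corpus file set plus its oracle ground truth.

    Returns (paths, ground_truth). Every disease id written to the mention
    table exists in the generated OBO. Reproducible: the same config always
    yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    target_ids = [f"T{i:05d}" for i in range(1, cfg.n_targets + 1)]
    disease_ids = [f"DOID:{i:07d}" for i in range(11, 11 + cfg.n_diseases)]
    root = "DOID:0000001"
    names = {root: "disease"}
    names.update({d: f"disease {i + 1}" for i, d in enumerate(disease_ids)})

    # random tree: terms are spread over levels 1..depth; each term's parent
    # is drawn uniformly from the level above (level-1 parents are the root)
    levels = rng.integers(1, cfg.ontology_depth + 1, size=cfg.n_diseases)
    parents: dict[str, str] = {}
    by_level: dict[int, list[str]] = {}
    for d, lvl in sorted(zip(disease_ids, levels)):
        by_level.setdefault(int(lvl), []).append(d)
    for lvl in sorted(by_level):
        pool = by_level.get(lvl - 1, [])
        for d in by_level[lvl]:
            parents[d] = root if not pool else pool[rng.integers(0, len(pool))]

    ranks = np.arange(1, cfg.n_targets + 1)
    weights = 1.0 / np.power(ranks, cfg.target_popularity)
    weights /= weights.sum()

    publications: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    base_date = datetime.date(2000, 1, 1)
    pubmeta: list[tuple[str, str, str]] = []
    for k in range(cfg.n_pubs):
        pid = f"{10000001 + k}"
        n_t = min(int(rng.poisson(cfg.targets_per_pub_mean)), cfg.n_targets)
        n_d = min(int(rng.poisson(cfg.diseases_per_pub_mean)), cfg.n_diseases)
        ts = (
            frozenset(rng.choice(target_ids, size=n_t, replace=False, p=weights))
            if n_t
            else frozenset()
        )
        ds = (
            frozenset(rng.choice(disease_ids, size=n_d, replace=False))
            if n_d
            else frozenset()
        )
        if not ts and not ds:
            continue  # nothing tagged; such a publication never enters the corpus
        publications[pid] = (ts, ds)
        date = base_date + datetime.timedelta(days=int(rng.integers(0, 9000)))
        pubmeta.append((pid, date.isoformat(), f"Synthetic article {k + 1}"))

    mentions_path = outdir / "mentions.tsv"
    with mentions_path.open("w", encoding="utf-8") as fh:
        fh.write("# synthetic corpus\n")
        for pid in sorted(publications):
            ts, ds = publications[pid]
            for t in sorted(ts):
                fh.write(f"{pid}\ttarget\t{t}\n")
            for d in sorted(ds):
                fh.write(f"{pid}\tdisease\t{d}\n")

    targets_path = outdir / "targets.tsv"
    tdls = ["Tclin", "Tchem", "Tbio", "Tdark"]
    fams = ["GPCR", "Kinase", "IonChannel", "NuclearReceptor", "Other"]
    with targets_path.open("w", encoding="utf-8") as fh:
        fh.write("target_id\tsymbol\ttdl\tidg_family\n")
        for i, t in enumerate(target_ids):
            tdl = tdls[int(rng.integers(0, len(tdls)))]
            fam = fams[int(rng.integers(0, len(fams)))]
            fh.write(f"{t}\tGENE{i + 1}\t{tdl}\t{fam}\n")

    obo_path = outdir / "disease.obo"
    _write_obo(obo_path, root, parents, names)

    pubmeta_path = outdir / "pubmeta.tsv"
    with pubmeta_path.open("w", encoding="utf-8") as fh:
        fh.write("pub_id\tdate\ttitle\n")
        for pid, date, title in pubmeta:
            fh.write(f"{pid}\t{date}\t{title}\n")

    paths = {
        "mentions": mentions_path,
        "targets": targets_path,
        "obo": obo_path,
        "pubmeta": pubmeta_path,
    }
    return paths, _compute_ground_truth(publications, parents)
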