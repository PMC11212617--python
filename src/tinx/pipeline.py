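"""End-to-end compute pipeline and artifact export.

``compute`` reads the corpus inputs, scores and ranks every supported
(target, disease) association, and writes a self-contained artifact directory:

* ``associations.tsv`` — the scored association table
* ``ranked.tsv`` / ``ranked.csv`` — associations with per-disease NDS rank
  and within-rank order (identical values, different delimiter)
* ``support.json`` — supporting publication ids per association
* ``publications.tsv`` — publication dates/titles (when metadata was given)
* ``manifest.json`` — input checksums, configuration, tool and schema version

Scores are precomputed once and queried many times, so browse-style queries
(:func:`query`) and the JSON export (:func:`export_json`) operate on the
artifact directory, not on the raw inputs. All writers emit byte-identical
output for identical inputs: floats are serialized with ``repr`` (shortest
round-trip form) and all orderings are total.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from tinx import __version__
from tinx.corpus import build_publications, read_mentions, read_pubmeta, read_targets
from tinx.ontology import parse_obo, propagate_support
from tinx.ranking import order_table
from tinx.scoring import ASSOCIATION_COLUMNS, score_all

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_FLOAT_COLUMNS = ["importance", "target_novelty", "disease_novelty"]


@dataclass
class RunConfig:
    """Paths and knobs of one compute run."""

    mentions: Path
    obo: Path
    targets: Path
    outdir: Path
    pubmeta: Optional[Path] = None
    k: int = 300
    dominance_mode: str = "weak"  # weak | strict
    log_base: str = "10"  # "10" | "e", affects exported plot coordinates only
    strictness: str = "strict"  # strict | lenient mention parsing

    def __post_init__(self) -> None:
        self.mentions = Path(self.mentions)
        self.obo = Path(self.obo)
        self.targets = Path(self.targets)
        self.outdir = Path(self.outdir)
        if self.pubmeta is not None:
            self.pubmeta = Path(self.pubmeta)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.dominance_mode not in ("weak", "strict"):
            raise ValueError("dominance_mode must be 'weak' or 'strict'")
        if self.log_base not in ("10", "e"):
            raise ValueError("log_base must be '10' or 'e'")
        if self.strictness not in ("strict", "lenient"):
            raise ValueError("strictness must be 'strict' or 'lenient'")

    def validate_inputs(self) -> None:
        paths = [self.mentions, self.obo, self.targets]
        if self.pubmeta is not None:
            paths.append(self.pubmeta)
        missing = [str(p) for p in paths if not p.is_file()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stringify_floats(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in _FLOAT_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map(repr)
    return out


def _write_table(df: pd.DataFrame, path: Path, sep: str) -> None:
    _stringify_floats(df).to_csv(path, sep=sep, index=False, lineterminator="\n")


def _log(x: float, base: str) -> float:
    return math.log10(x) if base == "10" else math.log(x)


def compute(cfg: RunConfig) -> dict[str, Path]:
    """Run the full pipeline and write the artifact directory.

    All inputs are read and the whole result is built in memory before any
    artifact is written, so a failing input never leaves partial outputs.
    """
    cfg.validate_inputs()

    rows = read_mentions(cfg.mentions, strict=cfg.strictness == "strict")
    pub_meta = read_pubmeta(cfg.pubmeta) if cfg.pubmeta is not None else None
    index = build_publications(rows, pub_meta)
    graph = parse_obo(cfg.obo)
    catalog = read_targets(cfg.targets)
    support = propagate_support(index, graph)
    associations = score_all(index, support, catalog, graph)

    # per-disease ranking of targets: the primary browse mode
    ranked_parts = []
    for _, group in associations.groupby("disease_id", sort=True):
        ranked_parts.append(
            order_table(group, k=len(group), novelty_col="target_novelty",
                        mode=cfg.dominance_mode)
        )
    ranked = (
        pd.concat(ranked_parts, ignore_index=True)
        if ranked_parts
        else associations.assign(nds_rank=pd.Series(dtype="int64"),
                                 within_rank_order=pd.Series(dtype="int64"))
    )
    ranked = ranked.sort_values(
        by=["disease_id", "nds_rank", "within_rank_order"], kind="mergesort"
    ).reset_index(drop=True)

    cfg.outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["associations"] = cfg.outdir / "associations.tsv"
    _write_table(associations[ASSOCIATION_COLUMNS], paths["associations"], "\t")

    ranked_cols = ASSOCIATION_COLUMNS + ["nds_rank", "within_rank_order"]
    paths["ranked_tsv"] = cfg.outdir / "ranked.tsv"
    paths["ranked_csv"] = cfg.outdir / "ranked.csv"
    _write_table(ranked[ranked_cols], paths["ranked_tsv"], "\t")
    _write_table(ranked[ranked_cols], paths["ranked_csv"], ",")

    paths["support"] = cfg.outdir / "support.json"
    support_doc = {
        f"{t}|{d}": sorted(pubs) for (t, d), pubs in sorted(support.items())
    }
    paths["support"].write_text(
        json.dumps(support_doc, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    pubs_df = pd.DataFrame(
        [
            {"pub_id": p, "date": pub.date or "", "title": pub.title or ""}
            for p, pub in sorted(index.by_pub.items())
        ],
        columns=["pub_id", "date", "title"],
    )
    paths["publications"] = cfg.outdir / "publications.tsv"
    pubs_df.to_csv(paths["publications"], sep="\t", index=False, lineterminator="\n")

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": __version__,
        "inputs": {
            "mentions": {"path": str(cfg.mentions), "sha256": _sha256(cfg.mentions)},
            "obo": {"path": str(cfg.obo), "sha256": _sha256(cfg.obo)},
            "targets": {"path": str(cfg.targets), "sha256": _sha256(cfg.targets)},
            **(
                {"pubmeta": {"path": str(cfg.pubmeta), "sha256": _sha256(cfg.pubmeta)}}
                if cfg.pubmeta is not None
                else {}
            ),
        },
        "config": {
            k: str(v) if isinstance(v, Path) else v for k, v in asdict(cfg).items()
        },
        "n_publications": len(index.by_pub),
        "n_associations": int(len(associations)),
    }
    paths["manifest"] = cfg.outdir / "manifest.json"
    paths["manifest"].write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths


class Artifacts:
    """Read access to a computed artifact directory."""

    def __init__(self, outdir: str | Path):
        self.outdir = Path(outdir)
        manifest_path = self.outdir / "manifest.json"
        if not manifest_path.is_file():
            raise FileNotFoundError(
                f"no manifest in {self.outdir}; run compute first"
            )
        self.manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
        self.associations = pd.read_csv(
            self.outdir / "associations.tsv", sep="\t",
            dtype={"target_id": str, "disease_id": str},
        )
        self.support = {
            tuple(key.split("|", 1)): pubs
            for key, pubs in json.loads(
                (self.outdir / "support.json").read_text(encoding="utf-8")
            ).items()
        }
        pubs = pd.read_csv(
            self.outdir / "publications.tsv", sep="\t", dtype=str, keep_default_na=False
        )
        self.pub_meta = {r.pub_id: (r.date, r.title) for r in pubs.itertuples(index=False)}


def query(
    outdir: str | Path,
    disease: Optional[str] = None,
    target: Optional[str] = None,
    k: int = 300,
    dominance_mode: str = "weak",
    log_base: str = "10",
) -> tuple[pd.DataFrame, dict[str, list[dict[str, str]]]]:
    """One browse query against computed artifacts.

    Exactly one of ``disease`` / ``target`` must be given. Returns the ranked
    table (with log plot coordinates) and, per association key
    ``"target|disease"``, its supporting articles sorted newest first.
    """
    if (disease is None) == (target is None):
        raise ValueError("give exactly one of disease= or target=")
    art = Artifacts(outdir)
    df = art.associations
    if disease is not None:
        sel = df[df["disease_id"] == disease]
        novelty_col = "target_novelty"
        if sel.empty:
            raise KeyError(f"unknown disease id {disease!r}")
    else:
        sel = df[df["target_id"] == target]
        novelty_col = "disease_novelty"
        if sel.empty:
            raise KeyError(f"unknown target id {target!r}")

    ranked = order_table(sel, k=k, novelty_col=novelty_col, mode=dominance_mode)
    ranked = ranked.assign(
        log_novelty=[_log(v, log_base) for v in ranked[novelty_col]],
        log_importance=[_log(v, log_base) for v in ranked["importance"]],
    )

    articles: dict[str, list[dict[str, str]]] = {}
    for row in ranked.itertuples(index=False):
        key = f"{row.target_id}|{row.disease_id}"
        entries = []
        for pid in art.support[(row.target_id, row.disease_id)]:
            date, title = art.pub_meta.get(pid, ("", ""))
            entries.append({"pub_id": pid, "date": date, "title": title})
        entries.sort(key=lambda e: (e["date"], e["pub_id"]), reverse=True)
        articles[key] = entries
    return ranked, articles


def export_json(outdir: str | Path) -> dict[str, Path]:
    """Write targets.json, diseases.json and associations.json from artifacts."""
    art = Artifacts(outdir)
    df = art.associations
    outdir = Path(outdir)

    targets = [
        {
            "target_id": tid,
            "symbol": grp["symbol"].iloc[0],
            "tdl": grp["tdl"].iloc[0],
            "idg_family": grp["idg_family"].iloc[0],
            "novelty": float(grp["target_novelty"].iloc[0]),
        }
        for tid, grp in df.groupby("target_id", sort=True)
    ]
    diseases = [
        {
            "disease_id": did,
            "name": grp["disease_name"].iloc[0] if pd.notna(grp["disease_name"].iloc[0]) else "",
            "novelty": float(grp["disease_novelty"].iloc[0]),
        }
        for did, grp in df.groupby("disease_id", sort=True)
    ]
    associations = [
        {
            "target_id": row.target_id,
            "disease_id": row.disease_id,
            "importance": float(row.importance),
            "target_novelty": float(row.target_novelty),
            "disease_novelty": float(row.disease_novelty),
            "n_pubs": int(row.n_pubs),
            "pub_ids": art.support[(row.target_id, row.disease_id)],
        }
        for row in df.sort_values(["target_id", "disease_id"]).itertuples(index=False)
    ]

    paths = {}
    for name, doc in (
        ("targets", targets),
        ("diseases", diseases),
        ("associations", associations),
    ):
        path = outdir / f"{name}.json"
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        paths[name] = path
    return paths
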