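"""End-to-end orchestration: per-disease DE, pairwise overlap statistics,
diseasome export, enrichment and shared-term statistics, catalog
cross-validation, co-expression clustering, and a JSON/TSV report bundle.

The report mirrors the two summary tables of the analysis: for every
disease pair a gene-level row (N, M, s, k, hypergeometric tail/pmf,
Jaccard) and, when GMT collections are configured, a pathway-level row.
A "counts-only" comparison mode accepts (N, M, s, k) and (A, B, C)
directly so published table rows can be recomputed without expression
data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd
import yaml

from . import coexpression as coex
from . import enrichment as enr
from . import io as cio
from . import overlap as ov
from . import variants as var
from .diffexpr import SignificantGeneSet, filter_significant, nb_wald_de, qn_ttest_de

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "write_report"]

log = logging.getLogger("comolink")

DEFAULT_THRESHOLDS = {
    "de_p": 0.05,
    "de_lfc": 1.0,
    "gwas_p": 1.0e-5,
    "enrich_alpha": 0.05,
    "coexpr_r": 0.7,
    "top_k": 25,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    diseases: list[dict] = field(default_factory=list)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    de_method: str = "nb_wald"
    collections: list[str] = field(default_factory=list)
    catalogs: list[dict] = field(default_factory=list)
    counts_only: list[dict] = field(default_factory=list)
    background_n: dict[str, int] = field(default_factory=dict)
    coexpression: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "comolink_out"
    extra_keys: list[str] = field(default_factory=list)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: str | Path = ".") -> "PipelineConfig":
        known = {
            "diseases", "thresholds", "de", "collections", "catalogs",
            "counts_only", "background_n", "coexpression", "seed", "output_dir",
        }
        cfg = cls(
            diseases=list(raw.get("diseases", [])),
            collections=list(raw.get("collections", [])),
            catalogs=list(raw.get("catalogs", [])),
            counts_only=list(raw.get("counts_only", [])),
            background_n={str(k): int(v) for k, v in (raw.get("background_n") or {}).items()},
            coexpression=dict(raw.get("coexpression") or {}),
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "comolink_out")),
            extra_keys=sorted(set(raw) - known),
        )
        cfg.thresholds = {**DEFAULT_THRESHOLDS, **(raw.get("thresholds") or {})}
        cfg.de_method = str((raw.get("de") or {}).get("method", "nb_wald"))
        base = Path(base_dir)
        for d in cfg.diseases:
            for key in ("counts", "conditions", "de_table"):
                if key in d and isinstance(d[key], str):
                    d[key] = str((base / d[key]).resolve()) if not Path(d[key]).is_absolute() else d[key]
        cfg.collections = [
            str((base / p).resolve()) if not Path(p).is_absolute() else p for p in cfg.collections
        ]
        for c in cfg.catalogs:
            if "path" in c and not Path(c["path"]).is_absolute():
                c["path"] = str((base / c["path"]).resolve())
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw, base_dir=path.parent)


def validate_config(config: PipelineConfig) -> list[tuple[str, str]]:
    """Enumerate configuration findings as (severity, message) pairs.

    Severity ``fatal`` should abort before any compute; ``warning`` is
    informational (e.g. unknown keys).
    """
    findings: list[tuple[str, str]] = []
    for key in config.extra_keys:
        findings.append(("warning", f"unknown config key ignored: {key!r}"))
    seen_ids: set[str] = set()
    for d in config.diseases:
        did = d.get("disease_id")
        if not did:
            findings.append(("fatal", "disease entry without disease_id"))
            continue
        if did in seen_ids:
            findings.append(("fatal", f"duplicate disease_id {did!r}"))
        seen_ids.add(did)
        if "counts" not in d and "de_table" not in d:
            findings.append(("fatal", f"{did}: needs 'counts' or 'de_table'"))
        for key in ("counts", "conditions", "de_table"):
            if key in d and isinstance(d[key], str) and not Path(d[key]).exists():
                findings.append(("fatal", f"{did}: missing file {d[key]}"))
    if len(config.diseases) == 1:
        findings.append(("fatal", "overlap analysis needs at least two diseases"))
    th = config.thresholds
    for key in ("de_p", "de_lfc", "gwas_p", "enrich_alpha", "coexpr_r"):
        v = th.get(key)
        if not isinstance(v, (int, float)) or v <= 0:
            findings.append(("fatal", f"threshold {key} must be positive, got {v!r}"))
    if isinstance(th.get("coexpr_r"), (int, float)) and not 0 < th["coexpr_r"] < 1:
        findings.append(("fatal", f"coexpr_r must lie in (0, 1), got {th['coexpr_r']}"))
    if th.get("top_k", 25) < 1:
        findings.append(("fatal", "top_k must be >= 1"))
    if config.de_method not in ("nb_wald", "qn_ttest"):
        findings.append(("fatal", f"unknown de.method {config.de_method!r}"))
    for p in config.collections:
        if not Path(p).exists():
            findings.append(("fatal", f"missing GMT collection {p}"))
    for c in config.catalogs:
        if "disease_id" not in c or "path" not in c:
            findings.append(("fatal", "catalog entry needs disease_id and path"))
        elif not Path(c["path"]).exists():
            findings.append(("fatal", f"missing catalog file {c['path']}"))
    for row in config.counts_only:
        for key in ("disease_a", "disease_b", "N", "M", "s", "k"):
            if key not in row:
                findings.append(("fatal", f"counts_only entry missing {key!r}"))
    return findings


def _pair_key(a: str, b: str) -> str:
    return "|".join(sorted((a, b)))


def _load_disease(d: dict, method: str, thresholds: dict) -> tuple[SignificantGeneSet, int, pd.DataFrame]:
    """DE table + significant set for one disease (raw gene count = tested genes)."""
    if "de_table" in d:
        de = cio.read_de_table(d["de_table"])
        log.info("%s: loaded precomputed DE table (%d genes)", d["disease_id"], len(de))
    else:
        cm = cio.read_counts_tsv(d["counts"], d.get("conditions"))
        test = nb_wald_de if method == "nb_wald" else qn_ttest_de
        de = test(cm)
        log.info("%s: tested %d genes with %s", d["disease_id"], len(de), method)
    sig = filter_significant(de, d["disease_id"], thresholds["de_p"], thresholds["de_lfc"])
    return sig, len(de), de


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages and return the report bundle.

    Stage order: DE -> gene-level overlap + diseasome -> enrichment +
    shared terms -> catalog cross-validation -> co-expression.  Any fatal
    validation finding raises before compute; a stage failure raises a
    stage-named RuntimeError.
    """
    findings = validate_config(config)
    fatal = [msg for lvl, msg in findings if lvl == "fatal"]
    for lvl, msg in findings:
        log.log(logging.ERROR if lvl == "fatal" else logging.WARNING, "%s: %s", lvl, msg)
    if fatal:
        raise ValueError("configuration invalid: " + "; ".join(fatal))

    report: dict = {
        "thresholds": dict(config.thresholds),
        "de_method": config.de_method,
        "seed": config.seed,
        "diseases": {},
        "pairs": {},
        "counts_only": {},
        "warnings": [msg for lvl, msg in findings if lvl == "warning"],
    }

    # --- differential expression -------------------------------------
    sig_sets: dict[str, SignificantGeneSet] = {}
    raw_counts: dict[str, int] = {}
    try:
        for d in config.diseases:
            sig, n_raw, _ = _load_disease(d, config.de_method, config.thresholds)
            sig_sets[d["disease_id"]] = sig
            raw_counts[d["disease_id"]] = n_raw
            report["diseases"][d["disease_id"]] = {
                "raw_genes": n_raw,
                "significant_genes": len(sig.genes),
                "up": len(sig.up),
                "down": len(sig.down),
            }
    except Exception as exc:
        raise RuntimeError(f"stage 'differential_expression' failed: {exc}") from exc

    # --- enrichment per disease ---------------------------------------
    enrichments: dict[str, list[enr.EnrichmentRecord]] = {}
    if config.collections and sig_sets:
        try:
            colls = [enr.read_gmt(p) for p in config.collections]
            for did, sig in sig_sets.items():
                records: list[enr.EnrichmentRecord] = []
                for coll in colls:
                    records.extend(enr.enrich(set(sig.genes), coll))
                enrichments[did] = records
                report["diseases"][did]["terms_tested"] = len(records)
        except Exception as exc:
            raise RuntimeError(f"stage 'enrichment' failed: {exc}") from exc

    # --- catalogs ------------------------------------------------------
    catalog_genes: dict[str, set[str]] = {}
    if config.catalogs:
        try:
            for c in config.catalogs:
                records = var.read_association_table(
                    c["path"], c.get("columns", {"gene": "gene", "p": "p_value"}),
                    sep=c.get("sep", "\t"),
                    trait=c.get("trait"), source=c.get("source"),
                )
                genes = var.filter_associations(records, config.thresholds["gwas_p"])
                catalog_genes.setdefault(c["disease_id"], set()).update(genes)
            for did, genes in catalog_genes.items():
                report["diseases"].setdefault(did, {})["catalog_significant_genes"] = len(genes)
        except Exception as exc:
            raise RuntimeError(f"stage 'variant_catalog' failed: {exc}") from exc

    # --- pairwise comparisons -----------------------------------------
    try:
        for a, b in combinations(sorted(sig_sets), 2):
            key = _pair_key(a, b)
            summary = ov.shared_gene_overlap(sig_sets[a], sig_sets[b])
            N = config.background_n.get(key, raw_counts[a] + raw_counts[b])
            hyp = ov.hypergeom_overlap(N, len(sig_sets[a].genes), len(sig_sets[b].genes),
                                       summary.n_shared)
            jac = ov.jaccard(len(sig_sets[a].genes), len(sig_sets[b].genes), summary.n_shared)
            entry: dict = {
                "overlap": summary.to_dict(),
                "gene_level": {"hypergeom": hyp.to_dict(), "jaccard": jac.to_dict()},
            }
            if a in enrichments and b in enrichments:
                shared = enr.shared_terms(
                    enrichments[a], enrichments[b],
                    alpha=config.thresholds["enrich_alpha"], by="p_value",
                )
                entry["pathway_level"] = shared.to_dict()
            if a in catalog_genes and b in catalog_genes:
                cat_shared = catalog_genes[a] & catalog_genes[b]
                entry["catalog"] = {
                    "shared_genes": sorted(cat_shared),
                    "count": len(cat_shared),
                    "consensus_genes": sorted(var.cross_modal_consensus(summary, cat_shared)),
                }
            report["pairs"][key] = entry
    except Exception as exc:
        raise RuntimeError(f"stage 'overlap' failed: {exc}") from exc

    # --- diseasome -----------------------------------------------------
    if len(sig_sets) >= 2:
        report["diseasome"] = {
            "nodes": len(
                g := ov.build_diseasome(list(sig_sets.values()), restrict_to_shared=True)
            ),
            "gene_nodes": sum(1 for _, t in g.nodes(data="type") if t == "gene"),
            "edges": g.number_of_edges(),
        }
        report["_diseasome_graph"] = g  # stripped before serialization

    # --- counts-only comparisons ---------------------------------------
    for row in config.counts_only:
        name = row.get("name") or _pair_key(row["disease_a"], row["disease_b"])
        hyp = ov.hypergeom_overlap(int(row["N"]), int(row["M"]), int(row["s"]), int(row["k"]))
        entry = {"hypergeom": hyp.to_dict()}
        if "jaccard" in row:
            j = row["jaccard"]
            entry["jaccard"] = ov.jaccard(int(j["A"]), int(j["B"]), int(j["C"])).to_dict()
        report["counts_only"][name] = entry

    # --- co-expression --------------------------------------------------
    if config.coexpression:
        try:
            did = config.coexpression["disease_id"]
            spec = next(d for d in config.diseases if d["disease_id"] == did)
            cm = cio.read_counts_tsv(spec["counts"], spec.get("conditions"))
            panel = config.coexpression.get("genes")
            if isinstance(panel, str):
                panel = sorted(cio.read_gene_list(panel))
            elif panel is None:
                shared: set[str] = set()
                for entry in report["pairs"].values():
                    o = entry["overlap"]
                    shared |= set(o["shared_up"]) | set(o["shared_down"]) | set(o["discordant"])
                panel = sorted(shared & set(cm.gene_ids))
            if panel and len(panel) >= 2:
                result = coex.coexpression_analysis(
                    cm, panel,
                    r_threshold=config.thresholds["coexpr_r"],
                    condition=config.coexpression.get("condition", "case"),
                )
                report["coexpression"] = result.to_dict()
            else:
                report["coexpression"] = {"clusters": [], "note": "panel too small"}
        except Exception as exc:
            raise RuntimeError(f"stage 'coexpression' failed: {exc}") from exc

    return report


def write_report(report: dict, out_dir: str | Path) -> list[Path]:
    """Persist the bundle: report.json, per-table TSVs, diseasome exports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    graph = report.pop("_diseasome_graph", None)
    if graph is not None:
        ov.write_graph(graph, out / "diseasome.graphml", "graphml")
        ov.write_graph(graph, out / "diseasome.sif", "sif")
        written += [out / "diseasome.graphml", out / "diseasome.sif"]

    cio.write_json(report, out / "report.json")
    written.append(out / "report.json")

    gene_rows, path_rows = [], []
    for key, entry in report.get("pairs", {}).items():
        h = entry["gene_level"]["hypergeom"]
        j = entry["gene_level"]["jaccard"]
        gene_rows.append(
            {
                "pair": key, "N": h["N"], "M": h["M"], "s": h["s"],
                "shared_significant_genes": h["k"],
                "hypergeometric_value": h["upper_tail_decimal"],
                "pmf": h["pmf_decimal"], "jaccard": round(j["J"], 4),
            }
        )
        if "pathway_level" in entry:
            ph, pj = entry["pathway_level"]["hypergeom"], entry["pathway_level"]["jaccard"]
            path_rows.append(
                {
                    "pair": key, "N": ph["N"], "M": ph["M"], "s": ph["s"],
                    "shared_significant_pathways": ph["k"],
                    "hypergeometric_value": ph["upper_tail_decimal"],
                    "pmf": ph["pmf_decimal"], "jaccard": round(pj["J"], 4),
                }
            )
    if gene_rows:
        p = out / "gene_level.tsv"
        pd.DataFrame(gene_rows).to_csv(p, sep="\t", index=False, lineterminator="\n")
        written.append(p)
    if path_rows:
        p = out / "pathway_level.tsv"
        pd.DataFrame(path_rows).to_csv(p, sep="\t", index=False, lineterminator="\n")
        written.append(p)
    return written
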