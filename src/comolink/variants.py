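"""GWAS/WGS gene-trait association catalogs and cross-modal consensus.

Catalog exports (GWAS Catalog, PheGenI, dbGaP, UK-Biobank, ClinVar style)
arrive as delimited tables with at least a gene symbol and a p-value.
Genes are retained when any of their records is below the genome-wide
suggestive threshold p < 1e-5 (strict), catalogs merge by gene-level
union with per-source provenance, and the surviving sets are intersected
across disorders and against the transcriptomic overlap to yield
dual-evidence consensus genes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd

from .diffexpr import normalize_symbol

__all__ = [
    "AssociationRecord",
    "read_association_table",
    "filter_associations",
    "merge_sources",
    "catalog_overlap",
    "cross_modal_consensus",
]

#: Genome-wide suggestive significance threshold used throughout.
DEFAULT_P_THRESHOLD = 1.0e-5

_MULTI_GENE_SPLIT = re.compile(r"[;,]")


@dataclass(frozen=True)
class AssociationRecord:
    """One gene-trait association row from a catalog export."""

    gene_id: str
    p_value: float
    trait: str = ""
    source: str = ""
    variant_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_id", normalize_symbol(self.gene_id))
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value must lie in (0, 1], got {self.p_value}")


def read_association_table(
    path: str | Path,
    column_map: dict[str, str],
    sep: str = "\t",
    trait: str | None = None,
    source: str | None = None,
) -> list[AssociationRecord]:
    """Read a delimited catalog export into association records.

    ``column_map`` maps the roles ``gene`` and ``p`` (required) and
    ``trait``, ``source``, ``variant`` (optional) to column names in the
    file.  Cells listing several genes separated by ``,`` or ``;`` are
    exploded into one record per gene.  ``trait``/``source`` arguments
    override per-row values with a single caller-declared label.
    """
    path = Path(path)
    for role in ("gene", "p"):
        if role not in column_map:
            raise ValueError(f"column_map must map the {role!r} role")
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = {col for col in column_map.values() if col not in df.columns}
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")

    records: list[AssociationRecord] = []
    for _, row in df.iterrows():
        raw_genes = str(row[column_map["gene"]])
        try:
            p = float(row[column_map["p"]])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path.name}: unparseable p-value {row[column_map['p']]!r}") from exc
        row_trait = trait if trait is not None else str(row.get(column_map.get("trait", ""), ""))
        row_source = source if source is not None else str(row.get(column_map.get("source", ""), ""))
        variant_col = column_map.get("variant")
        variant = str(row[variant_col]) if variant_col and pd.notna(row.get(variant_col)) else None
        for gene in _MULTI_GENE_SPLIT.split(raw_genes):
            gene = gene.strip()
            if gene:
                records.append(AssociationRecord(gene, p, row_trait, row_source, variant))
    return records


def filter_associations(
    records: list[AssociationRecord], p_threshold: float = DEFAULT_P_THRESHOLD
) -> set[str]:
    """Genes with any record strictly below the threshold.

    A record at exactly the threshold does not qualify; duplicates
    collapse to one gene.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    return {r.gene_id for r in records if r.p_value < p_threshold}


def merge_sources(
    records: list[AssociationRecord], p_threshold: float = DEFAULT_P_THRESHOLD
) -> dict[str, set[str]]:
    """Gene-level union across catalogs with provenance.

    Returns gene -> set of source names in which the gene passed the
    filter.  The key set equals :func:`filter_associations` on the pooled
    records.
    """
    out: dict[str, set[str]] = {}
    for r in records:
        if r.p_value < p_threshold:
            out.setdefault(r.gene_id, set()).add(r.source)
    return out


def catalog_overlap(named_sets: dict[str, set[str]]) -> dict[str, dict]:
    """Pairwise and full intersections of per-disease gene sets.

    Returns a report keyed ``"a&b"`` (lexicographic) for every pair plus
    ``"all"`` when three or more sets are given, each with the member
    list and its count — the Venn-diagram numbers.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two gene sets to intersect")
    normalized = {
        name: {normalize_symbol(g) for g in genes} for name, genes in named_sets.items()
    }
    report: dict[str, dict] = {}
    for a, b in combinations(sorted(normalized), 2):
        inter = normalized[a] & normalized[b]
        report[f"{a}&{b}"] = {"genes": sorted(inter), "count": len(inter)}
    if len(normalized) >= 3:
        inter = set.intersection(*normalized.values())
        report["all"] = {"genes": sorted(inter), "count": len(inter)}
    return report


def cross_modal_consensus(transcriptomic, catalog_shared: set[str]) -> set[str]:
    """Genes supported by both expression and variant evidence.

    Intersects a pair's transcriptomic :class:`~comolink.overlap.OverlapSummary`
    shared genes (up, down and discordant alike) with the pair's shared
    catalog genes.
    """
    catalog = {normalize_symbol(g) for g in catalog_shared}
    return set(transcriptomic.shared_genes) & catalog
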