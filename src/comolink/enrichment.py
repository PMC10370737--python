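"""Gene-set over-representation analysis against GMT collections.

A local stand-in for web enrichment services: for each term of a GMT
collection the overlap of a query gene list with the term is scored with
an upper-tail hypergeometric p-value (N = background size, M = term size,
s = query size, k = overlap), Benjamini-Hochberg adjusted across the
collection, ranked, and intersected across disorders to quantify shared
pathway biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .diffexpr import normalize_symbol
from . import overlap as _overlap

__all__ = [
    "GeneSetCollection",
    "EnrichmentRecord",
    "SharedTermResult",
    "read_gmt",
    "write_gmt",
    "enrich",
    "bh_adjust",
    "significant_terms",
    "top_k",
    "shared_terms",
]


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (terms) with an analysis universe.

    ``universe`` defaults to the union of all term members.
    """

    collection_id: str
    terms: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"collection {self.collection_id!r} has no terms")
        for term, members in self.terms.items():
            if not members:
                raise ValueError(f"term {term!r} is empty")
        if self.universe is None:
            self.universe = frozenset().union(*self.terms.values())
        else:
            self.universe = frozenset(self.universe)
            stray = frozenset().union(*self.terms.values()) - self.universe
            if stray:
                raise ValueError(
                    f"term members outside the declared universe: {sorted(stray)[:5]}"
                )


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term's over-representation result."""

    term_id: str
    term_size: int
    overlap_k: int
    query_size: int
    background_N: int
    p_value: float
    p_adjusted: float
    overlap_genes: frozenset[str] = frozenset()

    def to_dict(self) -> dict:
        return {
            "term_id": self.term_id,
            "term_size": self.term_size,
            "overlap_k": self.overlap_k,
            "query_size": self.query_size,
            "background_N": self.background_N,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
            "overlap_genes": sorted(self.overlap_genes),
        }


def read_gmt(path: str | Path, collection_id: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: ``term<TAB>description<TAB>member...`` per line.

    Member symbols are uppercased and deduplicated within a term.

    Raises
    ------
    ValueError
        Naming the offending line number for lines with fewer than three
        fields, and for files with no terms at all.
    """
    path = Path(path)
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path.name}:{lineno}: GMT line needs >=3 tab-separated fields")
        term, desc, *members = fields
        members = [normalize_symbol(m) for m in members if m.strip()]
        if not members:
            raise ValueError(f"{path.name}:{lineno}: term {term!r} has no members")
        if term in terms:
            raise ValueError(f"{path.name}:{lineno}: duplicate term {term!r}")
        terms[term] = frozenset(members)
        descriptions[term] = desc
    if not terms:
        raise ValueError(f"{path}: no terms found")
    return GeneSetCollection(collection_id or path.stem, terms, descriptions)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    """Write a collection in GMT format (members sorted for stable output)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for term in sorted(coll.terms):
            desc = coll.descriptions.get(term, "")
            members = "\t".join(sorted(coll.terms[term]))
            fh.write(f"{term}\t{desc}\t{members}\n")


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    q_(i) = p_(i) * m / i on the ascending order statistics, monotonicity
    enforced from the largest rank down, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def enrich(
    query: set[str],
    coll: GeneSetCollection,
    background: set[str] | str = "auto",
) -> list[EnrichmentRecord]:
    """Score every term of a collection against a query gene set.

    ``background="auto"`` uses the collection universe unioned with the
    query; pass an explicit set to pin N to a chosen convention.  Records
    are sorted by (p, term_size descending, term_id).
    """
    query = {normalize_symbol(g) for g in query}
    if background == "auto":
        bg = frozenset(coll.universe) | query
    else:
        bg = frozenset(normalize_symbol(g) for g in background)
    q = query & bg
    if not q:
        raise ValueError("query does not intersect the background")
    N = len(bg)
    s = len(q)

    term_ids = sorted(coll.terms)
    M = np.array([len(coll.terms[t] & bg) for t in term_ids])
    overlaps = [coll.terms[t] & q for t in term_ids]
    k = np.array([len(o) for o in overlaps])
    # P(X >= k) = sf(k-1); harmless for M=0 (p=1 unless k>0, impossible)
    p = stats.hypergeom.sf(k - 1, N, M, s)
    p = np.clip(p, 0.0, 1.0)
    padj = bh_adjust(p)
    records = [
        EnrichmentRecord(
            term_id=t,
            term_size=int(M[i]),
            overlap_k=int(k[i]),
            query_size=s,
            background_N=N,
            p_value=float(p[i]),
            p_adjusted=float(padj[i]),
            overlap_genes=frozenset(overlaps[i]),
        )
        for i, t in enumerate(term_ids)
    ]
    records.sort(key=_rank_key)
    return records


def _rank_key(r: EnrichmentRecord):
    return (r.p_value, -r.term_size, r.term_id)


def significant_terms(
    records: list[EnrichmentRecord], alpha: float = 0.05, by: str = "p_adjusted"
) -> list[EnrichmentRecord]:
    """Records with the chosen p-value field <= alpha, in rank order."""
    if by not in ("p_value", "p_adjusted"):
        raise ValueError("by must be 'p_value' or 'p_adjusted'")
    return sorted((r for r in records if getattr(r, by) <= alpha), key=_rank_key)


def top_k(records: list[EnrichmentRecord], k: int = 25) -> list[EnrichmentRecord]:
    """Best min(k, len) records with deterministic tie-breaking."""
    return sorted(records, key=_rank_key)[: max(k, 0)]


@dataclass(frozen=True)
class SharedTermResult:
    """Cross-disorder shared significant terms and the counts they induce.

    ``jaccard`` is None when neither disorder has a significant term
    (the index is undefined at A = B = C = 0).
    """

    shared: frozenset[str]
    jaccard: _overlap.JaccardResult | None
    hypergeom: _overlap.HypergeomResult

    def to_dict(self) -> dict:
        return {
            "shared_terms": sorted(self.shared),
            "jaccard": self.jaccard.to_dict() if self.jaccard is not None else None,
            "hypergeom": self.hypergeom.to_dict(),
        }


def shared_terms(
    records_a: list[EnrichmentRecord],
    records_b: list[EnrichmentRecord],
    alpha: float = 0.05,
    by: str = "p_value",
    background_n: int | None = None,
) -> SharedTermResult:
    """Shared significant terms of two disorders, with pathway-level stats.

    A = significant terms for disorder A, B for disorder B, C = shared by
    term_id; the hypergeometric uses N = background_n or, by default, the
    total number of terms tested for A plus the total tested for B.

    Raises
    ------
    ValueError
        If the two record lists were computed against different term
        universes (no term_id in common while both are nonempty).
    """
    ids_a = {r.term_id for r in records_a}
    ids_b = {r.term_id for r in records_b}
    if records_a and records_b and not (ids_a & ids_b):
        raise ValueError("record lists share no terms; were they run on the same collections?")
    sig_a = {r.term_id for r in significant_terms(records_a, alpha, by)}
    sig_b = {r.term_id for r in significant_terms(records_b, alpha, by)}
    shared = frozenset(sig_a & sig_b)
    A, B, C = len(sig_a), len(sig_b), len(shared)
    N = background_n if background_n is not None else len(records_a) + len(records_b)
    jac = _overlap.jaccard(A, B, C) if A + B - C > 0 else None
    hyp = _overlap.hypergeom_overlap(N, A, B, C)
    return SharedTermResult(shared, jac, hyp)
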