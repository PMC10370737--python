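"""Shared-gene overlap statistics between disease gene sets.

The comorbidity question is reduced to set overlap: given N genes in the
combined background, M significant in disease A, s significant in disease
B, and k shared, how surprising is k?  The hypergeometric law answers it:

    h(k; N, s, M) = C(M, k) C(N-M, s-k) / C(N, s)

with mean s*M/N and variance s*M*(N-M)*(N-s) / (N^2*(N-1)).  Everything is
computed in log space via log-gamma so that probabilities far below the
double-precision underflow threshold (observed values reach 1e-88 and
smaller) remain exact in their exponent.  Both the point probability and
the two tails are reported; the upper tail P(X >= k) is the headline value
because it is what a significance statement about "at least this much
overlap" means.  The Jaccard index J = C/(A+B-C) complements it as a
scale-free similarity.

The diseasome is the bipartite disease-gene graph whose gene nodes carry
an up/down/discordant regulation attribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.special import gammaln, logsumexp

from .diffexpr import SignificantGeneSet

__all__ = [
    "OverlapSummary",
    "HypergeomResult",
    "JaccardResult",
    "shared_gene_overlap",
    "hypergeom_overlap",
    "jaccard",
    "build_diseasome",
    "write_graph",
    "read_graph",
    "decimal_from_log",
]

LN10 = math.log(10.0)


def decimal_from_log(log_p: float, digits: int = 2) -> str:
    """Render exp(log_p) as a decimal string ``m.mm e EXP``.

    Survives double underflow: only the base-10 exponent and mantissa are
    materialized, so log_p = -1400 renders as e.g. ``"2.34e-608"``.
    """
    if log_p == -math.inf:
        return "0"
    log10p = log_p / LN10
    exponent = math.floor(log10p)
    mantissa = 10.0 ** (log10p - exponent)
    if round(mantissa, digits) >= 10.0:  # e.g. 9.999 rounding up
        mantissa /= 10.0
        exponent += 1
    return f"{mantissa:.{digits}f}e{exponent:d}"


@dataclass(frozen=True)
class HypergeomResult:
    """Hypergeometric overlap of k shared among (N, M, s).

    All probabilities are stored as natural logs; ``-inf`` encodes zero.
    """

    N: int
    M: int
    s: int
    k: int
    log_pmf: float
    upper_tail: float  # log P(X >= k)
    lower_tail: float  # log P(X <= k)
    mean: float
    variance: float

    @property
    def pmf(self) -> float:
        return math.exp(self.log_pmf)

    @property
    def pmf_decimal(self) -> str:
        return decimal_from_log(self.log_pmf)

    @property
    def p_upper(self) -> float:
        return math.exp(self.upper_tail)

    @property
    def upper_tail_decimal(self) -> str:
        return decimal_from_log(self.upper_tail)

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "M": self.M,
            "s": self.s,
            "k": self.k,
            "log_pmf": self.log_pmf,
            "pmf_decimal": self.pmf_decimal,
            "upper_tail_log": self.upper_tail,
            "upper_tail_decimal": self.upper_tail_decimal,
            "lower_tail_log": self.lower_tail,
            "mean": self.mean,
            "variance": self.variance,
        }


@dataclass(frozen=True)
class JaccardResult:
    """Jaccard similarity from counts: J = C / (A + B - C)."""

    A: int
    B: int
    C: int
    J: float

    def to_dict(self) -> dict:
        return {"A": self.A, "B": self.B, "C": self.C, "J": self.J}


@dataclass(frozen=True)
class OverlapSummary:
    """Direction-stratified shared genes of a disease pair."""

    disease_a: str
    disease_b: str
    shared_up: frozenset[str]
    shared_down: frozenset[str]
    discordant: frozenset[str]

    @property
    def n_shared(self) -> int:
        return len(self.shared_up) + len(self.shared_down) + len(self.discordant)

    @property
    def shared_genes(self) -> frozenset[str]:
        return self.shared_up | self.shared_down | self.discordant

    def to_dict(self) -> dict:
        return {
            "disease_a": self.disease_a,
            "disease_b": self.disease_b,
            "n_shared": self.n_shared,
            "shared_up": sorted(self.shared_up),
            "shared_down": sorted(self.shared_down),
            "discordant": sorted(self.discordant),
        }


def shared_gene_overlap(a: SignificantGeneSet, b: SignificantGeneSet) -> OverlapSummary:
    """Intersect two significant gene sets, stratified by regulation direction.

    ``discordant`` holds genes significant in both diseases but regulated
    in opposite directions; they still count toward ``n_shared``.
    """
    return OverlapSummary(
        disease_a=a.disease_id,
        disease_b=b.disease_id,
        shared_up=frozenset(a.up & b.up),
        shared_down=frozenset(a.down & b.down),
        discordant=frozenset((a.up & b.down) | (a.down & b.up)),
    )


def _check_int(name: str, value) -> int:
    if isinstance(value, bool) or (
        not isinstance(value, (int, np.integer))
        and not (isinstance(value, float) and value.is_integer())
    ):
        raise ValueError(f"{name} must be a nonnegative integer, got {value!r}")
    value = int(value)
    if value < 0:
        raise ValueError(f"{name} must be nonnegative, got {value}")
    return value


def _log_pmf(k: np.ndarray, N: int, M: int, s: int) -> np.ndarray:
    """log h(k; N, s, M) via log-gamma, vectorized over k inside the support."""
    k = np.asarray(k, dtype=float)
    return (
        gammaln(M + 1) - gammaln(k + 1) - gammaln(M - k + 1)
        + gammaln(N - M + 1) - gammaln(s - k + 1) - gammaln(N - M - s + k + 1)
        - (gammaln(N + 1) - gammaln(s + 1) - gammaln(N - s + 1))
    )


def hypergeom_overlap(N: int, M: int, s: int, k: int) -> HypergeomResult:
    """Point probability, tails and moments of the overlap distribution.

    Out-of-support k is allowed and yields pmf 0 with the tails set by
    side: k below the support means P(X >= k) = 1, above means
    P(X <= k) = 1.
    """
    N = _check_int("N", N)
    M = _check_int("M", M)
    s = _check_int("s", s)
    k = _check_int("k", k)
    if M > N or s > N:
        raise ValueError(f"M={M} and s={s} must not exceed N={N}")
    if N == 0:
        raise ValueError("population size N must be positive")

    lo = max(0, M + s - N)
    hi = min(M, s)
    mean = s * M / N
    variance = s * M * (N - M) * (N - s) / (N**2 * (N - 1)) if N > 1 else 0.0

    if k < lo:
        return HypergeomResult(N, M, s, k, -math.inf, 0.0, -math.inf, mean, variance)
    if k > hi:
        return HypergeomResult(N, M, s, k, -math.inf, -math.inf, 0.0, mean, variance)

    support = np.arange(lo, hi + 1)
    logs = _log_pmf(support, N, M, s)
    log_pmf = float(logs[k - lo])
    upper = float(logsumexp(logs[k - lo :]))
    lower = float(logsumexp(logs[: k - lo + 1]))
    # clamp tiny positive drift from summation
    upper = min(upper, 0.0)
    lower = min(lower, 0.0)
    return HypergeomResult(N, M, s, k, log_pmf, upper, lower, mean, variance)


def jaccard(A: int, B: int, C: int) -> JaccardResult:
    """Jaccard index from set cardinalities; exact rational before rounding."""
    A = _check_int("A", A)
    B = _check_int("B", B)
    C = _check_int("C", C)
    if C > min(A, B):
        raise ValueError(f"shared count C={C} exceeds min(A={A}, B={B})")
    denom = A + B - C
    if denom == 0:
        raise ValueError("Jaccard undefined for A = B = C = 0")
    return JaccardResult(A, B, C, float(Fraction(C, denom)))


# ---------------------------------------------------------------------------
# Diseasome graph


def build_diseasome(
    sets: list[SignificantGeneSet], restrict_to_shared: bool = True
) -> nx.Graph:
    """Bipartite disease-gene graph from per-disease significant sets.

    Gene nodes carry ``regulation``: ``up``/``down`` when every incident
    disease regulates the gene the same way, ``discordant`` otherwise.
    With ``restrict_to_shared`` only genes significant in >=2 diseases
    become nodes (the molecular-comorbidity view).
    """
    if len(sets) < 2:
        raise ValueError("a diseasome needs at least two disease sets")
    g = nx.Graph()
    for s in sets:
        g.add_node(s.disease_id, type="disease")
    membership: dict[str, list[tuple[str, str]]] = {}
    for s in sets:
        for gene in s.up:
            membership.setdefault(gene, []).append((s.disease_id, "up"))
        for gene in s.down:
            membership.setdefault(gene, []).append((s.disease_id, "down"))
    for gene, hits in membership.items():
        if restrict_to_shared and len(hits) < 2:
            continue
        directions = {d for _, d in hits}
        regulation = directions.pop() if len(directions) == 1 else "discordant"
        g.add_node(gene, type="gene", regulation=regulation)
        for disease, _ in hits:
            g.add_edge(disease, gene, interaction="associates")
    return g


def write_graph(g: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Export the diseasome as GraphML (attributes kept) or SIF (structure).

    SIF lines read ``disease<TAB>associates<TAB>gene``.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            for u, v in sorted(g.edges()):
                disease, gene = (u, v) if g.nodes[u].get("type") == "disease" else (v, u)
                fh.write(f"{disease}\tassociates\t{gene}\n")
    else:
        raise ValueError(f"unknown graph format: {fmt!r} (use 'graphml' or 'sif')")


def read_graph(path: str | Path, fmt: str = "graphml") -> nx.Graph:
    """Re-read a graph written by :func:`write_graph`."""
    path = Path(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "sif":
        g = nx.Graph()
        for line in path.read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed SIF line: {line!r}")
            disease, interaction, gene = parts
            g.add_node(disease, type="disease")
            g.add_node(gene, type="gene")
            g.add_edge(disease, gene, interaction=interaction)
        return g
    raise ValueError(f"unknown graph format: {fmt!r}")
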