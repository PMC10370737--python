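"""Synthetic inputs with planted ground truth for the overlap pipeline.

Every input the analysis consumes can be generated here with known truth:

* two-group RNA-seq count matrices — gene-wise negative binomial in the
  mean/dispersion parameterisation ``Var = mu + a*mu^2``, with a chosen
  fraction of genes planted as differentially expressed (group-2 mean
  multiplied by ``2**(+-lfc)``);
* disease *pairs* whose planted DE genes overlap by an exact count, for
  testing shared-gene statistics against truth;
* block-structured co-expression — genes in a block share a latent
  Gaussian factor on the log-mean scale, giving tunable pairwise Pearson
  correlation of log counts;
* gene-trait association catalogs with an exact number of sub-threshold
  (p < 1e-5) genes;
* GMT collections with terms over-sampled from a designated query set.

All randomness flows from the explicit ``seed`` through one
``numpy.random.Generator``; identical config + seed reproduces identical
output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix
from .enrichment import GeneSetCollection
from .variants import AssociationRecord

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_count_dataset",
    "simulate_disease_pair",
    "simulate_coexpression_blocks",
    "simulate_association_catalog",
    "simulate_geneset_collection",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one two-group count dataset.

    Defaults describe a moderately powered iPSC-style comparison: 1000
    genes, 10 samples per group, 10% of genes differentially expressed at
    |log2FC| = 2, baseline means log-uniform between 5 and 500 counts,
    NB dispersion 0.1.
    """

    n_genes: int = 1000
    n_samples_per_group: int = 10
    de_fraction: float = 0.1
    lfc_magnitude: float = 2.0
    nb_mean_log_range: tuple[float, float] = (5.0, 500.0)
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_group <= 0:
            raise ValueError("n_genes and n_samples_per_group must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.lfc_magnitude <= 0:
            raise ValueError("lfc_magnitude must be positive")
        lo, hi = self.nb_mean_log_range
        if lo <= 0 or hi < lo:
            raise ValueError("nb_mean_log_range must be positive with low <= high")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    @property
    def n_de_genes(self) -> int:
        return int(round(self.de_fraction * self.n_genes))


@dataclass
class SyntheticTruth:
    """Ground truth planted into a simulated dataset.

    ``de_genes`` maps gene -> true signed log2FC (union over datasets for
    a pair; ``de_genes_by_dataset`` keeps the per-dataset maps).
    """

    de_genes: dict[str, float] = field(default_factory=dict)
    de_genes_by_dataset: dict[str, dict[str, float]] = field(default_factory=dict)
    shared_genes: set[str] = field(default_factory=set)
    cluster_blocks: list[set[str]] = field(default_factory=list)
    enriched_terms: set[str] = field(default_factory=set)
    sub_threshold_assoc_genes: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shared_genes"] = sorted(self.shared_genes)
        d["cluster_blocks"] = [sorted(b) for b in self.cluster_blocks]
        d["enriched_terms"] = sorted(self.enriched_terms)
        d["sub_threshold_assoc_genes"] = sorted(self.sub_threshold_assoc_genes)
        return d


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB counts with mean mu and Var = mu + dispersion*mu^2."""
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _sample_counts(
    rng: np.random.Generator,
    base_mu: np.ndarray,
    lfc: np.ndarray,
    n1: int,
    n2: int,
    dispersion: float,
) -> np.ndarray:
    """Genes x (control, case) counts; case means scaled by 2**lfc."""
    mu_ctrl = np.tile(base_mu[:, None], (1, n1))
    mu_case = np.tile((base_mu * np.exp2(lfc))[:, None], (1, n2))
    ctrl = _nb_draw(rng, mu_ctrl, dispersion)
    case = _nb_draw(rng, mu_case, dispersion)
    return np.hstack([ctrl, case])


def _assemble_matrix(
    counts: np.ndarray, genes: list[str], n_ctrl: int, n_case: int, sample_prefix: str = "S"
) -> CountMatrix:
    samples = [f"{sample_prefix}_ctrl_{i+1}" for i in range(n_ctrl)] + [
        f"{sample_prefix}_case_{i+1}" for i in range(n_case)
    ]
    condition = {s: ("control" if "_ctrl_" in s else "case") for s in samples}
    df = pd.DataFrame(counts, index=genes, columns=samples)
    return CountMatrix(df, condition)


def simulate_count_dataset(config: SimulationConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """One two-group NB count dataset with planted DE genes.

    Planted genes get their case-group mean multiplied by
    ``2**(+-lfc_magnitude)``, the sign Bernoulli(1/2) per gene.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    base_mu = _baseline_means(rng, config)
    lfc = np.zeros(config.n_genes)
    n_de = config.n_de_genes
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc[de_idx] = signs * config.lfc_magnitude
    n = config.n_samples_per_group
    counts = _sample_counts(rng, base_mu, lfc, n, n, config.nb_dispersion)
    cm = _assemble_matrix(counts, genes, n, n)
    truth = SyntheticTruth(de_genes={genes[i]: float(lfc[i]) for i in de_idx})
    return cm, truth


def _baseline_means(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    lo, hi = config.nb_mean_log_range
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))


def simulate_disease_pair(
    config_a: SimulationConfig,
    config_b: SimulationConfig,
    shared_fraction: float,
    concordant_fraction: float = 1.0,
) -> tuple[CountMatrix, CountMatrix, SyntheticTruth]:
    """Two diseases over one gene universe with an exact planted overlap.

    Exactly ``round(shared_fraction * n_planted_A)`` of A's planted DE
    genes are also planted in B; a ``concordant_fraction`` of the shared
    genes keeps A's effect sign in B, the rest flips.

    Both configs must declare the same ``n_genes``.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    if not 0.0 <= concordant_fraction <= 1.0:
        raise ValueError("concordant_fraction must lie in [0, 1]")
    if config_a.n_genes != config_b.n_genes:
        raise ValueError("both configs must share the same gene universe")

    n_genes = config_a.n_genes
    genes = _gene_names(n_genes)
    rng = np.random.default_rng(config_a.seed)
    rng_b = np.random.default_rng(config_b.seed + 1)

    n_a, n_b = config_a.n_de_genes, config_b.n_de_genes
    n_shared = int(round(shared_fraction * n_a))
    if n_shared > n_b:
        raise ValueError("shared overlap exceeds the number of genes planted in B")

    idx_a = rng.choice(n_genes, size=n_a, replace=False)
    shared_idx = rng.choice(idx_a, size=n_shared, replace=False)
    rest = np.setdiff1d(np.arange(n_genes), idx_a, assume_unique=False)
    b_only = rng_b.choice(rest, size=n_b - n_shared, replace=False)
    idx_b = np.concatenate([shared_idx, b_only])

    lfc_a = np.zeros(n_genes)
    lfc_a[idx_a] = rng.choice([-1.0, 1.0], size=n_a) * config_a.lfc_magnitude
    lfc_b = np.zeros(n_genes)
    lfc_b[b_only] = rng_b.choice([-1.0, 1.0], size=len(b_only)) * config_b.lfc_magnitude
    concordant = rng_b.random(n_shared) < concordant_fraction
    sign_a = np.sign(lfc_a[shared_idx])
    lfc_b[shared_idx] = np.where(concordant, sign_a, -sign_a) * config_b.lfc_magnitude

    na, nb = config_a.n_samples_per_group, config_b.n_samples_per_group
    counts_a = _sample_counts(rng, _baseline_means(rng, config_a), lfc_a, na, na,
                              config_a.nb_dispersion)
    counts_b = _sample_counts(rng_b, _baseline_means(rng_b, config_b), lfc_b, nb, nb,
                              config_b.nb_dispersion)
    cm_a = _assemble_matrix(counts_a, genes, na, na, sample_prefix="A")
    cm_b = _assemble_matrix(counts_b, genes, nb, nb, sample_prefix="B")

    de_a = {genes[i]: float(lfc_a[i]) for i in idx_a}
    de_b = {genes[i]: float(lfc_b[i]) for i in idx_b}
    truth = SyntheticTruth(
        de_genes={**de_b, **de_a},
        de_genes_by_dataset={"A": de_a, "B": de_b},
        shared_genes={genes[i] for i in shared_idx},
    )
    return cm_a, cm_b, truth


def simulate_coexpression_blocks(
    n_genes: int,
    block_sizes: list[int],
    factor_strength: float,
    n_samples: int,
    seed: int,
    base_mean: float = 2000.0,
    log_sd: float = 1.0,
    nb_dispersion: float = 0.01,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Counts whose log scale carries block-structured correlation.

    Genes of one block share a latent standard-normal factor per sample;
    gene *i* in a block has log-mean
    ``log(base) + log_sd * (sqrt(rho) f_b + sqrt(1-rho) eps_i)`` with
    ``rho = factor_strength``, so the expected Pearson correlation of log
    counts within a block is rho, and background genes are uncorrelated.
    The default count scale is deliberately quiet (large baseline mean,
    small dispersion) so that counting noise does not attenuate the
    planted correlation: the latent log-scale variance dominates
    ``dispersion + 1/mu`` by two orders of magnitude.
    """
    if not 0.0 < factor_strength < 1.0:
        raise ValueError("factor_strength must lie in (0, 1)")
    if sum(block_sizes) > n_genes:
        raise ValueError("block sizes exceed the number of genes")
    if any(b <= 0 for b in block_sizes):
        raise ValueError("block sizes must be positive")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    rho = factor_strength

    z = rng.standard_normal((n_genes, n_samples))  # idiosyncratic part
    latent = np.sqrt(1.0 - rho) * z
    blocks: list[set[str]] = []
    start = 0
    for size in block_sizes:
        f = rng.standard_normal(n_samples)
        f = (f - f.mean()) / f.std()  # unit realized variance: planted corr is rho, not rho*Var(f)
        latent[start : start + size] += np.sqrt(rho) * f
        blocks.append(set(genes[start : start + size]))
        start += size
    latent[start:] = z[start:]  # background: pure noise, unit variance

    log_mu = np.log(base_mean) + log_sd * latent - 0.5 * log_sd**2
    counts = _nb_draw(rng, np.exp(log_mu), nb_dispersion)
    samples = [f"S{i+1:03d}" for i in range(n_samples)]
    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples),
        {s: "case" for s in samples},
    )
    return cm, SyntheticTruth(cluster_blocks=blocks)


def simulate_association_catalog(
    n_genes: int,
    n_significant: int,
    p_floor: float = 1e-30,
    seed: int = 0,
    trait: str = "trait",
    sources: tuple[str, ...] = ("gwas_catalog", "phegeni", "dbgap", "ukbiobank", "clinvar"),
    p_threshold: float = 1e-5,
) -> tuple[list[AssociationRecord], SyntheticTruth]:
    """Gene-trait association records with an exact sub-threshold subset.

    Exactly ``n_significant`` genes get a p-value log-uniform on
    ``[p_floor, p_threshold)``; the rest are uniform on
    ``[p_threshold, 1]``.  Sources cycle through the given catalog names.
    """
    if n_significant > n_genes:
        raise ValueError("n_significant cannot exceed n_genes")
    if p_floor <= 0:
        raise ValueError("p_floor must be positive")
    if p_floor >= p_threshold:
        raise ValueError("p_floor must be below the significance threshold")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    sig_idx = set(rng.choice(n_genes, size=n_significant, replace=False).tolist())
    records: list[AssociationRecord] = []
    for i, gene in enumerate(genes):
        if i in sig_idx:
            p = float(np.exp(rng.uniform(np.log(p_floor), np.log(p_threshold))))
            p = min(p, np.nextafter(p_threshold, 0))
        else:
            p = float(rng.uniform(p_threshold, 1.0))
        records.append(
            AssociationRecord(
                gene_id=gene,
                p_value=p,
                trait=trait,
                source=sources[i % len(sources)],
                variant_id=f"rs{seed}_{i}",
            )
        )
    truth = SyntheticTruth(sub_threshold_assoc_genes={genes[i] for i in sig_idx})
    return records, truth


def simulate_geneset_collection(
    universe: list[str] | set[str],
    n_terms: int,
    term_size_range: tuple[int, int],
    planted: dict[str, float] | None = None,
    seed: int = 0,
    query: set[str] | None = None,
    collection_id: str = "synthetic_gmt",
) -> tuple[GeneSetCollection, SyntheticTruth]:
    """GMT-style collection with terms over-sampled from a query set.

    ``planted`` maps term_id -> enrichment rate: that fraction of the
    term's members is drawn from ``query`` (required when planting), the
    rest from the remainder of the universe.  Unplanted terms are uniform
    draws from the universe.
    """
    universe = sorted(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    lo, hi = term_size_range
    if lo < 1 or hi < lo or hi > len(universe):
        raise ValueError("term sizes must satisfy 1 <= low <= high <= |universe|")
    planted = planted or {}
    if planted and query is None:
        raise ValueError("planting enrichment requires a designated query set")
    query = set(query or ())
    stray = query - set(universe)
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")

    rng = np.random.default_rng(seed)
    uni = np.array(universe)
    non_query = np.array(sorted(set(universe) - query))
    query_arr = np.array(sorted(query))

    terms: dict[str, frozenset[str]] = {}
    names = [f"TERM_{i+1:04d}" for i in range(n_terms)]
    for extra in planted:
        if extra not in names:
            names.append(extra)
    for name in names[: max(n_terms, len(names))]:
        size = int(rng.integers(lo, hi + 1))
        rate = planted.get(name)
        if rate is None:
            members = rng.choice(uni, size=size, replace=False)
        else:
            if not 0.0 <= rate <= 1.0:
                raise ValueError("enrichment rates must lie in [0, 1]")
            n_from_query = min(int(round(rate * size)), len(query_arr))
            picked_q = rng.choice(query_arr, size=n_from_query, replace=False)
            picked_bg = rng.choice(non_query, size=size - n_from_query, replace=False)
            members = np.concatenate([picked_q, picked_bg])
        terms[name] = frozenset(members.tolist())
    coll = GeneSetCollection(collection_id, terms, universe=frozenset(universe))
    return coll, SyntheticTruth(enriched_terms=set(planted))
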