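"""Two-group differential expression for RNA-seq count matrices.

Implements the transcriptomic front end of the cross-disorder overlap
pipeline: median-of-ratios library-size normalization, quantile
normalization, a negative-binomial Wald test (a documented simplification
of the DESeq2 model), an ordinary t-test path on quantile-normalized
log counts, and the two-condition significance filter
(p < 0.05 and |log2FC| > 1, both strict) that defines each disorder's
significant up/down gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "SignificantGeneSet",
    "normalize_symbol",
    "size_factors_median_of_ratios",
    "quantile_normalize",
    "nb_wald_de",
    "qn_ttest_de",
    "filter_significant",
]

#: Pseudocount added to normalized group means before taking log2 ratios.
PSEUDOCOUNT = 0.5

#: Floor applied to method-of-moments dispersion estimates.
DISPERSION_FLOOR = 0.01


def normalize_symbol(symbol: str) -> str:
    """Canonical gene identifier: uppercased, surrounding whitespace removed."""
    return str(symbol).strip().upper()


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample count matrix with condition labels.

    Parameters
    ----------
    counts
        DataFrame of raw counts, genes in rows (index = gene symbols),
        samples in columns.
    condition
        Map sample_id -> ``"case"`` or ``"control"``. May cover only a
        subset of samples; differential testing requires >=2 samples per
        level among the covered ones.
    """

    counts: pd.DataFrame
    condition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.counts
        if c.shape[0] == 0 or c.shape[1] == 0:
            raise ValueError("count matrix must be non-empty")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        c.index = pd.Index([normalize_symbol(g) for g in c.index], name="gene")
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols after normalization: {dups[:5]}")
        unknown = set(self.condition) - set(c.columns)
        if unknown:
            raise ValueError(f"condition labels for unknown samples: {sorted(unknown)[:5]}")
        bad = {v for v in self.condition.values()} - {"case", "control"}
        if bad:
            raise ValueError(f"condition levels must be case/control, got {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, level: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition.get(s) == level]


@dataclass(frozen=True)
class SignificantGeneSet:
    """Filtered significant genes of one disorder, stratified by direction."""

    disease_id: str
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up- and down-regulated")

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down


def size_factors_median_of_ratios(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Per-sample size factors by the median-of-ratios method.

    For each gene present (nonzero) in every sample, compute the ratio of
    its count in sample *j* to its geometric mean across samples; the size
    factor of sample *j* is the median of those ratios.

    Raises
    ------
    ValueError
        If no gene has nonzero counts in all samples.
    """
    c = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = c.to_numpy(dtype=float)
    eligible = (arr > 0).all(axis=1)
    if not eligible.any():
        raise ValueError("no gene with nonzero counts in every sample; cannot normalize")
    sub = arr[eligible]
    log_geo_mean = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geo_mean)
    return pd.Series(np.median(ratios, axis=0), index=c.columns, name="size_factor")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common cross-column rank-mean distribution.

    The reference distribution is the mean across columns of the
    column-sorted values.  Ties within a column receive the mean of the
    reference values over their rank span, so the output of a column with
    ties is still a function of the input ranks only.
    """
    if matrix.size == 0:
        raise ValueError("cannot quantile-normalize an empty matrix")
    arr = matrix.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("matrix contains missing values")
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        normalized = ref.copy()
        # average the reference over each block of tied input values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        for lo, hi in zip(np.r_[0, boundaries], np.r_[boundaries, len(col)]):
            if hi - lo > 1:
                normalized[lo:hi] = ref[lo:hi].mean()
        out[order, j] = normalized
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _group_columns(cm: CountMatrix) -> tuple[list[str], list[str]]:
    case = cm.samples_of("case")
    control = cm.samples_of("control")
    if len(case) < 2 or len(control) < 2:
        raise ValueError(
            f"need >=2 samples per condition, got {len(case)} case / {len(control)} control"
        )
    return case, control


def nb_wald_de(cm: CountMatrix, min_count_filter: int = 1) -> pd.DataFrame:
    """Negative-binomial Wald test of case vs control, one gene at a time.

    A deliberately simple NB model: counts are normalized by
    median-of-ratios size factors; each gene's dispersion ``a`` in
    ``Var = mu + a*mu^2`` is estimated by method of moments from the
    within-group sample variances (floored at 0.01); the Wald statistic is
    the difference of log normalized group means over its delta-method
    standard error, referred two-sided to a Student t with n1+n2-2 degrees
    of freedom (the t reference absorbs the variance-estimation noise at
    the small group sizes typical of iPSC studies, keeping the nominal
    type-I level honest where a normal reference is anti-conservative).
    No shrinkage, no covariates.

    Parameters
    ----------
    min_count_filter
        Genes whose total raw count across all samples is below this are
        dropped before testing (default 1: drop all-zero genes only).

    Returns
    -------
    DataFrame with columns ``gene, base_mean, log2fc, p_value, p_adjusted``
    (BH-adjusted p is informational; the significance filter uses raw p).
    """
    case, control = _group_columns(cm)
    totals = cm.counts.sum(axis=1)
    kept = cm.counts.loc[totals >= max(min_count_filter, 1)]
    if kept.shape[0] == 0:
        raise ValueError("no gene passes the minimum count filter")
    sf = size_factors_median_of_ratios(kept)
    norm = kept.to_numpy(dtype=float) / sf.to_numpy()
    norm_df = pd.DataFrame(norm, index=kept.index, columns=kept.columns)

    x1 = norm_df[case].to_numpy()
    x2 = norm_df[control].to_numpy()
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        d1 = np.where(m1 > 0, (v1 - m1) / np.square(m1), np.nan)
        d2 = np.where(m2 > 0, (v2 - m2) / np.square(m2), np.nan)
    disp = np.nanmean(np.stack([d1, d2]), axis=0)
    disp = np.where(np.isfinite(disp), disp, DISPERSION_FLOOR)
    disp = np.maximum(disp, DISPERSION_FLOOR)

    pc = PSEUDOCOUNT
    log2fc = np.log2((m1 + pc) / (m2 + pc))
    var_mean1 = (m1 + disp * np.square(m1)) / n1
    var_mean2 = (m2 + disp * np.square(m2)) / n2
    var_log = var_mean1 / np.square(m1 + pc) + var_mean2 / np.square(m2 + pc)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.log(m1 + pc) - np.log(m2 + pc)) / np.sqrt(var_log)
    z = np.where(var_log > 0, z, 0.0)
    p = 2.0 * stats.t.sf(np.abs(z), df=n1 + n2 - 2)
    p = np.clip(p, 0.0, 1.0)

    out = pd.DataFrame(
        {
            "gene": kept.index,
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "p_value": p,
        }
    ).reset_index(drop=True)
    from .enrichment import bh_adjust  # local import to avoid cycle at import time

    out["p_adjusted"] = bh_adjust(out["p_value"].tolist())
    return out


def qn_ttest_de(cm: CountMatrix, min_count_filter: int = 1) -> pd.DataFrame:
    """Alternative DE path: quantile-normalized log2 counts + two-sample t-test.

    Counts are size-factor normalized, log2(x+1)-transformed, quantile
    normalized across samples, and compared between conditions with an
    ordinary two-sided two-sample t-test.  ``log2fc`` is the difference of
    group means on the transformed scale.
    """
    case, control = _group_columns(cm)
    totals = cm.counts.sum(axis=1)
    kept = cm.counts.loc[totals >= max(min_count_filter, 1)]
    if kept.shape[0] == 0:
        raise ValueError("no gene passes the minimum count filter")
    sf = size_factors_median_of_ratios(kept)
    logn = np.log2(kept.to_numpy(dtype=float) / sf.to_numpy() + 1.0)
    qn = quantile_normalize(pd.DataFrame(logn, index=kept.index, columns=kept.columns))
    x1 = qn[case].to_numpy()
    x2 = qn[control].to_numpy()
    t, p = stats.ttest_ind(x1, x2, axis=1)
    p = np.where(np.isfinite(p), p, 1.0)
    out = pd.DataFrame(
        {
            "gene": kept.index,
            "base_mean": (kept.to_numpy(dtype=float) / sf.to_numpy()).mean(axis=1),
            "log2fc": x1.mean(axis=1) - x2.mean(axis=1),
            "p_value": p,
        }
    ).reset_index(drop=True)
    from .enrichment import bh_adjust

    out["p_adjusted"] = bh_adjust(out["p_value"].tolist())
    return out


def filter_significant(
    de: pd.DataFrame,
    disease_id: str,
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> SignificantGeneSet:
    """Apply the two-condition significance filter, both inequalities strict.

    A gene is significant iff ``p_value < p_threshold`` and
    ``|log2fc| > lfc_threshold``; the sign of log2fc assigns it to the up-
    or down-regulated set.  Boundary values (p exactly at the threshold,
    |log2fc| exactly at the threshold) are excluded.
    """
    if p_threshold <= 0 or lfc_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if de.empty:
        return SignificantGeneSet(disease_id, frozenset(), frozenset())
    keep = (de["p_value"] < p_threshold) & (de["log2fc"].abs() > lfc_threshold)
    sig = de.loc[keep]
    up = frozenset(normalize_symbol(g) for g in sig.loc[sig["log2fc"] > 0, "gene"])
    down = frozenset(normalize_symbol(g) for g in sig.loc[sig["log2fc"] < 0, "gene"])
    return SignificantGeneSet(disease_id, up, down)
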