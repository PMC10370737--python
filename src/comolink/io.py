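"""File formats: counts (TSV / MatrixMarket), conditions, DE tables,
gene lists and JSON reports.

All tables are UTF-8, tab-delimited, LF-terminated.  Counts TSV has genes
in rows, a header of sample ids, and the gene symbol as the first column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .diffexpr import CountMatrix, normalize_symbol

__all__ = [
    "write_counts_tsv",
    "read_counts_tsv",
    "write_counts_mtx",
    "read_counts_mtx",
    "write_conditions",
    "read_conditions",
    "write_de_table",
    "read_de_table",
    "write_gene_list",
    "read_gene_list",
    "write_json",
    "read_json",
]

DE_COLUMNS = ["gene", "base_mean", "log2fc", "p_value"]


def write_counts_tsv(cm: CountMatrix, path: str | Path) -> None:
    df = cm.counts.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_counts_tsv(
    path: str | Path, conditions: dict[str, str] | str | Path | None = None
) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    cond = (
        read_conditions(conditions)
        if isinstance(conditions, (str, Path))
        else dict(conditions or {})
    )
    return CountMatrix(df, cond)


def write_counts_mtx(cm: CountMatrix, prefix: str | Path) -> None:
    """MatrixMarket triplet + ``<prefix>.rows.txt`` / ``<prefix>.cols.txt``."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(cm.counts.to_numpy()))
    prefix.with_suffix(".rows.txt").write_text("\n".join(cm.gene_ids) + "\n", encoding="utf-8")
    prefix.with_suffix(".cols.txt").write_text("\n".join(cm.sample_ids) + "\n", encoding="utf-8")


def read_counts_mtx(
    prefix: str | Path, conditions: dict[str, str] | str | Path | None = None
) -> CountMatrix:
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx")))
    genes = prefix.with_suffix(".rows.txt").read_text(encoding="utf-8").split()
    samples = prefix.with_suffix(".cols.txt").read_text(encoding="utf-8").split()
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    df = pd.DataFrame(dense.astype(np.int64), index=genes, columns=samples)
    cond = (
        read_conditions(conditions)
        if isinstance(conditions, (str, Path))
        else dict(conditions or {})
    )
    return CountMatrix(df, cond)


def write_conditions(condition: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample\tcondition\n")
        for sample, level in condition.items():
            fh.write(f"{sample}\t{level}\n")


def read_conditions(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "condition"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'sample' and 'condition'")
    return dict(zip(df["sample"], df["condition"]))


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    cols = DE_COLUMNS + [c for c in de.columns if c not in DE_COLUMNS]
    de[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: DE table missing columns {sorted(missing)}")
    df["gene"] = df["gene"].map(normalize_symbol)
    return df


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{g}\n" for g in sorted({normalize_symbol(g) for g in genes})),
        encoding="utf-8",
    )


def read_gene_list(path: str | Path) -> set[str]:
    return {
        normalize_symbol(line)
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    }


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
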