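"""TSV readers/writers for expression matrices, phenotypes and annotations."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples matrix; first column is named ``gene``."""
    out = matrix.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return df


def write_phenotype(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotype(path: str | Path) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cohort", "group"}
    missing = required - set(pheno.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    return pheno


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "gene_symbol", "status"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    return ann
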