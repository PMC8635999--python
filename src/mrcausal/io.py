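"""TSV dialects for GWAS summary statistics and derived tables.

The package exchanges data as plain tab-separated text:

* GWAS tables: ``snp, effect_allele, other_allele, eaf, beta, se, pval, n``
* truth tables from the simulator: ``snp, gamma_true*, alpha_true, is_valid``
* harmonized tables: :data:`mrcausal.harmonize.HARMONIZED_COLUMNS`
* LD matrices: square, SNP identifiers as header row and first column
* LDSC inputs: ``snp, z1, z2, l2, n1, n2``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .harmonize import HARMONIZED_COLUMNS, HarmonizedSet
from .simulate import GWAS_COLUMNS

__all__ = [
    "read_gwas",
    "write_gwas",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_harmonized",
    "write_harmonized",
    "read_ldsc_input",
]


def read_gwas(path: str | Path) -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV, validating the dialect."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in GWAS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing GWAS columns {missing}")
    table = table[GWAS_COLUMNS].copy()
    if (table["se"] <= 0).any():
        raise ValueError(f"{path}: standard errors must be positive")
    if ((table["eaf"] <= 0) | (table["eaf"] >= 1)).any():
        raise ValueError(f"{path}: allele frequencies must be in (0, 1)")
    return table


def write_gwas(table: pd.DataFrame, path: str | Path) -> None:
    table[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    """Read a square SNP x SNP r^2 matrix with identifier header row/column."""
    ld = pd.read_csv(path, sep="\t", index_col=0)
    if list(ld.index) != list(ld.columns):
        raise ValueError(f"{path}: LD matrix row and column identifiers differ")
    vals = ld.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T):
        raise ValueError(f"{path}: LD matrix is not symmetric")
    if not np.allclose(np.diag(vals), 1.0):
        raise ValueError(f"{path}: LD matrix diagonal must be 1")
    return ld


def write_ld_matrix(ld: pd.DataFrame, path: str | Path) -> None:
    ld.to_csv(path, sep="\t")


def write_harmonized(hset: HarmonizedSet, path: str | Path) -> None:
    hset.table[HARMONIZED_COLUMNS].to_csv(path, sep="\t", index=False)


def read_harmonized(path: str | Path) -> HarmonizedSet:
    """Read a harmonized TSV back into a :class:`HarmonizedSet`."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in HARMONIZED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing harmonized columns {missing}")
    return HarmonizedSet(
        table=table[HARMONIZED_COLUMNS].copy(),
        dropped=pd.DataFrame(columns=["snp", "reason"]),
        n_input=len(table),
        n_dropped_palindromic=0,
        n_unmatched=0,
    )


def read_ldsc_input(path: str | Path):
    """Read an LDSC TSV (snp, z1, z2, l2, n1, n2) into an LdscInput."""
    from .ldsc import LdscInput

    table = pd.read_csv(path, sep="\t")
    needed = ["snp", "z1", "z2", "l2", "n1", "n2"]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing LDSC columns {missing}")
    return LdscInput(
        z1=table["z1"].to_numpy(dtype=float),
        z2=table["z2"].to_numpy(dtype=float),
        ld_scores=table["l2"].to_numpy(dtype=float),
        n1=int(table["n1"].iloc[0]),
        n2=int(table["n2"].iloc[0]),
    )
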