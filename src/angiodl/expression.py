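"""RNA Angioscore computation from gene-expression tables.

The Angioscore of a sample is the mean log-transformed TPM of six
angiogenesis signature genes (VEGFA, KDR, ESM1, PECAM1, ANGPTL4, CD34).
FPKM input is first renormalized to TPM (per-sample rescaling to a column
sum of 10^6), then log(x + 1)-transformed, then averaged over the signature.
The natural log is used; any fixed base gives the same sample ranking.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SIGNATURE_GENES",
    "ExpressionTable",
    "DegenerateSampleError",
    "MissingGeneError",
    "fpkm_to_tpm",
    "log_transform",
    "compute_angioscore",
]

SIGNATURE_GENES = ("VEGFA", "KDR", "ESM1", "PECAM1", "ANGPTL4", "CD34")

_UNITS = ("FPKM", "TPM", "logTPM")


class DegenerateSampleError(ValueError):
    """A sample column has no expressed gene, so it cannot be normalized."""


class MissingGeneError(KeyError):
    """A required signature gene is absent from the table."""


class ExpressionTable:
    """A genes-by-samples expression matrix with an explicit unit.

    Thin wrapper over a pandas DataFrame (index = gene symbols, columns =
    sample ids) that enforces non-negativity, unique gene symbols, and —
    for TPM — columns summing to 10^6 within 1e-3 relative.
    """

    def __init__(self, df: pd.DataFrame, unit: str):
        if unit not in _UNITS:
            raise ValueError(f"unit must be one of {_UNITS}, got {unit!r}")
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene symbols: {dupes}")
        values = df.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("expression values must be non-negative")
        if unit == "TPM":
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1e6, rtol=1e-3):
                raise ValueError("TPM columns must sum to 10^6 within 1e-3 relative")
        self.df = df.astype(float)
        self.unit = unit

    @classmethod
    def from_array(cls, values, genes: Sequence[str], samples: Sequence[str],
                   unit: str) -> "ExpressionTable":
        return cls(pd.DataFrame(np.asarray(values, dtype=float),
                                index=list(genes), columns=list(samples)), unit)

    @classmethod
    def read_csv(cls, path: str | Path, unit: str, sep: str = ",") -> "ExpressionTable":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(df, unit)

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.df.to_csv(path, sep=sep, index_label="gene")

    @property
    def genes(self) -> pd.Index:
        return self.df.index

    @property
    def samples(self) -> pd.Index:
        return self.df.columns

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionTable({self.df.shape[0]} genes x {self.df.shape[1]} samples, {self.unit})"


def fpkm_to_tpm(table: ExpressionTable) -> ExpressionTable:
    """Renormalize FPKM to TPM: TPM_ij = FPKM_ij / sum_i FPKM_ij * 10^6.

    Per-sample scale-invariant: multiplying a column by any c > 0 leaves the
    result unchanged. A column with no expressed gene is an error (there is
    nothing to normalize against).
    """
    if table.unit != "FPKM":
        raise ValueError(f"expected an FPKM table, got {table.unit}")
    sums = table.df.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise DegenerateSampleError(f"all-zero sample column(s): {zero}")
    return ExpressionTable(table.df.div(sums, axis=1) * 1e6, "TPM")


def log_transform(table: ExpressionTable) -> ExpressionTable:
    """Elementwise natural log(x + 1); the +1 keeps zeros finite."""
    if table.unit != "TPM":
        raise ValueError(f"expected a TPM table, got {table.unit}")
    return ExpressionTable(np.log1p(table.df), "logTPM")


def compute_angioscore(
    table: ExpressionTable,
    signature: Iterable[str] = SIGNATURE_GENES,
    uppercase: bool = False,
) -> pd.Series:
    """Mean logTPM of the signature genes, one score per sample.

    Gene matching is exact (optionally after uppercasing both sides); a
    missing or duplicated signature gene is an error rather than a silent
    subset.
    """
    if table.unit != "logTPM":
        raise ValueError(f"expected a logTPM table, got {table.unit}")
    signature = list(signature)
    df = table.df
    if uppercase:
        df = df.copy()
        df.index = df.index.str.upper()
        signature = [g.upper() for g in signature]
        if df.index.duplicated().any():
            raise ValueError("uppercasing collapsed distinct gene symbols")
    missing = [g for g in signature if g not in df.index]
    if missing:
        raise MissingGeneError(f"signature genes absent from table: {missing}")
    scores = df.loc[signature].mean(axis=0)
    scores.name = "angioscore"
    return scores


def angioscore_from_fpkm(table: ExpressionTable,
                         signature: Iterable[str] = SIGNATURE_GENES) -> pd.Series:
    """Convenience composition: FPKM -> TPM -> logTPM -> Angioscore."""
    return compute_angioscore(log_transform(fpkm_to_tpm(table)), signature)
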