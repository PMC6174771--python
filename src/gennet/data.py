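"""Expression and methylation data containers.

Both containers wrap pandas DataFrames with features on the rows and
samples on the columns, mirroring the TSV layout used throughout the
package (first column = feature identifier, header row = sample
identifiers).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionData", "MethylationData", "read_matrix_tsv", "write_matrix_tsv"]

# fixed float format so that identical data always serializes identically
_FLOAT_FMT = "%.10g"


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a feature-by-sample TSV matrix (first column = feature id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


@dataclass
class ExpressionData:
    """mRNA and miRNA abundance matrices over a shared set of samples.

    ``mrna`` holds one row per gene/protein (the two share an identifier
    space: mRNA abundance proxies protein abundance), ``mirna`` one row
    per miRNA.  Columns are sample identifiers and must agree between the
    two matrices.
    """

    mrna: pd.DataFrame
    mirna: pd.DataFrame

    def __post_init__(self) -> None:
        if self.mrna.shape[1] < 2:
            raise ValueError("expression data needs at least 2 samples")
        if not self.mrna.columns.equals(self.mirna.columns):
            raise ValueError("mRNA and miRNA sample columns are not aligned")
        if not np.isfinite(self.mrna.to_numpy()).all():
            raise ValueError("non-finite mRNA expression values")
        if self.mirna.shape[0] and not np.isfinite(self.mirna.to_numpy()).all():
            raise ValueError("non-finite miRNA expression values")

    @property
    def n_samples(self) -> int:
        return self.mrna.shape[1]

    @property
    def samples(self) -> list[str]:
        return list(self.mrna.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.mrna.index)

    @property
    def mirnas(self) -> list[str]:
        return list(self.mirna.index)

    def subset_samples(self, samples) -> "ExpressionData":
        return ExpressionData(self.mrna[list(samples)], self.mirna[list(samples)])

    def write(self, mrna_path: str | Path, mirna_path: str | Path) -> None:
        write_matrix_tsv(self.mrna, mrna_path)
        write_matrix_tsv(self.mirna, mirna_path)

    @classmethod
    def read(cls, mrna_path: str | Path, mirna_path: str | Path) -> "ExpressionData":
        return cls(read_matrix_tsv(mrna_path), read_matrix_tsv(mirna_path))


@dataclass
class MethylationData:
    """Per-gene DNA methylation beta values (fraction methylated, in [0,1]).

    Genes without probe coverage are simply absent from ``beta``; lookups
    for such genes report no coverage and downstream models treat them as
    unmethylated-equivalent (attenuation factor 1).
    """

    beta: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.beta.to_numpy()
        if values.size:
            if not np.isfinite(values).all():
                raise ValueError("non-finite methylation beta values")
            if values.min() < 0 or values.max() > 1:
                raise ValueError("methylation beta values must lie in [0,1]")

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    def covers(self, gene: str) -> bool:
        return gene in self.beta.index

    def profile(self, gene: str) -> np.ndarray:
        return self.beta.loc[gene].to_numpy(dtype=float)

    def subset_samples(self, samples) -> "MethylationData":
        return MethylationData(self.beta[list(samples)])

    def write(self, path: str | Path) -> None:
        write_matrix_tsv(self.beta, path)

    @classmethod
    def read(cls, path: str | Path) -> "MethylationData":
        return cls(read_matrix_tsv(path))
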