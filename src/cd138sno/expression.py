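"""Gene-level expression container (TPM, genes x samples) with gene metadata.

The matrix is the common currency of the differential-expression screen and
the signature scoring: rows are genes carrying an Ensembl-style identifier, a
symbol (the placeholder ``"0"`` marks an absent symbol) and a biotype; columns
are samples. Values are transcripts per million (TPM), nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ["gene_id", "symbol", "biotype"]


@dataclass
class ExpressionMatrix:
    """TPM values (genes x samples) plus per-gene id/symbol/biotype metadata.

    Parameters
    ----------
    tpm
        DataFrame of nonnegative TPM values indexed by gene_id, one column
        per sample. Column order defines the sample order.
    meta
        DataFrame indexed by gene_id with columns ``symbol`` and ``biotype``,
        aligned with ``tpm``.
    """

    tpm: pd.DataFrame
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        values = self.tpm.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("TPM matrix contains non-finite values")
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative TPM at gene {self.tpm.index[bad[0]]!r}, "
                f"sample {self.tpm.columns[bad[1]]!r}"
            )
        if self.tpm.index.has_duplicates:
            dupes = self.tpm.index[self.tpm.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_ids: {dupes}")
        if not self.tpm.index.equals(self.meta.index):
            raise ValueError("tpm and meta must share an identical gene_id index")
        for col in ("symbol", "biotype"):
            if col not in self.meta.columns:
                raise ValueError(f"meta is missing required column {col!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.tpm.index

    @property
    def samples(self) -> pd.Index:
        return self.tpm.columns

    @property
    def symbols(self) -> pd.Series:
        return self.meta["symbol"]

    @property
    def biotypes(self) -> pd.Series:
        return self.meta["biotype"]

    @property
    def n_genes(self) -> int:
        return self.tpm.shape[0]

    @property
    def n_samples(self) -> int:
        return self.tpm.shape[1]

    def log2p1(self) -> pd.DataFrame:
        """Return log2(TPM + 1), the scale on which effects are defined."""
        return np.log2(self.tpm + 1.0)

    def to_tsv(self, path) -> None:
        """Write a TSV with gene_id, symbol, biotype then one column per sample."""
        out = pd.concat([self.meta[["symbol", "biotype"]], self.tpm], axis=1)
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        missing = [c for c in ("symbol", "biotype") if c not in df.columns]
        if missing:
            raise ValueError(f"expression TSV missing columns: {missing}")
        meta = df[["symbol", "biotype"]].astype(str)
        tpm = df.drop(columns=["symbol", "biotype"]).astype(float)
        return cls(tpm=tpm, meta=meta)

    @classmethod
    def from_arrays(cls, gene_ids, symbols, biotypes, samples, values) -> "ExpressionMatrix":
        index = pd.Index(gene_ids, name="gene_id")
        tpm = pd.DataFrame(np.asarray(values, dtype=float), index=index, columns=samples)
        meta = pd.DataFrame({"symbol": list(symbols), "biotype": list(biotypes)}, index=index)
        return cls(tpm=tpm, meta=meta)
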