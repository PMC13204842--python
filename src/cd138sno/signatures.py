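"""Single-sample signature scoring: ssGSEA, snoRNA module score, z-scores.

Two kinds of per-sample summaries are computed from the expression matrix:

* ssGSEA enrichment scores for the CD138-positive (S100A7, CD24, GLYATL2) and
  CD138-negative (RERG, SLC39A6, NAT1, SCUBE2, PIP, NPY1R, SLC7A2, GRIA2,
  FSIP1, PTPRT, SERPINA3) transcriptional programs, evaluated on
  log2(TPM + 1). The score is a rank-based running-sum: with genes ranked
  1..N by increasing expression (average ranks on ties) and walked in
  decreasing-rank order,

      ES = sum_i [ P_in(i) - P_out(i) ]
      P_in(i)  = sum_{j<=i, j in S} r_j^alpha / sum_{j in S} r_j^alpha
      P_out(i) = #{non-members at position <= i} / (N - |S|)

  with weight alpha = 0.25 by default. Being rank-based, ES is invariant to
  any strictly increasing transform of a sample's expression values.

* the snoRNA module score: the arithmetic mean of raw TPM (not log) over the
  Group-1-enriched snoRNA signature set.

Continuous scores are standardized to z-scores (mean 0, sample SD 1) before
multivariable survival modeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_EXPONENT = 0.25


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


def read_gmt(path) -> dict[str, GeneSet]:
    """Read a GMT file (name, description, member genes, tab-separated)."""
    from gseapy import read_gmt as _gseapy_read_gmt

    raw = _gseapy_read_gmt(str(path))
    return {name: GeneSet(name, tuple(members)) for name, members in raw.items()}


def write_gmt(sets: Mapping[str, GeneSet], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for gs in sets.values():
            fh.write("\t".join([gs.name, description, *gs.members]) + "\n")


def ssgsea_score(
    sample_values: Sequence[float],
    member_mask: Sequence[bool],
    exponent: float = DEFAULT_EXPONENT,
) -> float:
    """ssGSEA enrichment score of one gene set in one sample.

    Parameters
    ----------
    sample_values
        Per-gene expression for one sample (any monotone scale; the score
        depends on ranks only).
    member_mask
        Boolean per-gene membership of the set, aligned with sample_values.
    exponent
        Rank weight alpha applied inside the set.
    """
    values = np.asarray(sample_values, dtype=float)
    mask = np.asarray(member_mask, dtype=bool)
    if values.shape != mask.shape or values.ndim != 1:
        raise ValueError("sample_values and member_mask must be 1-D and aligned")
    n = len(values)
    n_in = int(mask.sum())
    if n_in == 0:
        raise ValueError("no signature genes measured")
    if n_in == n:
        raise ValueError("complement empty: the set covers every measured gene")

    ranks = rankdata(values)  # 1..N increasing, average ranks on ties
    # Decreasing-rank walk; tied ranks visited in input gene order.
    order = np.argsort(-ranks, kind="stable")
    ordered_mask = mask[order]
    ordered_weights = np.where(ordered_mask, ranks[order] ** exponent, 0.0)

    p_in = np.cumsum(ordered_weights) / ordered_weights.sum()
    p_out = np.cumsum(~ordered_mask) / (n - n_in)
    return float(np.sum(p_in - p_out))


def match_set(symbols: pd.Series, gene_set: GeneSet) -> np.ndarray:
    """Case-sensitive symbol match of a gene set against the matrix symbols.

    Returns the boolean per-gene mask. Raises if nothing matches or if a
    matched symbol is carried by more than one gene row (ambiguous match).
    """
    wanted = set(gene_set.members)
    mask = symbols.isin(wanted).to_numpy()
    if not mask.any():
        raise ValueError(f"gene set {gene_set.name!r} matches no measured genes")
    matched = symbols[mask]
    dupes = matched[matched.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(
            f"gene set {gene_set.name!r}: ambiguous match, duplicate symbol rows {dupes}"
        )
    return mask


def score_cohort(
    matrix,
    sets: Mapping[str, GeneSet],
    exponent: float = DEFAULT_EXPONENT,
) -> pd.DataFrame:
    """ssGSEA scores for every sample and gene set, on log2(TPM + 1).

    Returns a DataFrame indexed by sample with one column per gene set.
    """
    if matrix.n_samples == 0 or matrix.n_genes == 0:
        raise ValueError("expression matrix is empty")
    log = matrix.log2p1().to_numpy()
    out = {}
    for name, gs in sets.items():
        mask = match_set(matrix.symbols, gs)
        out[name] = [
            ssgsea_score(log[:, j], mask, exponent) for j in range(matrix.n_samples)
        ]
    return pd.DataFrame(out, index=pd.Index(matrix.samples, name="sample_id"))


def snorna_module_score(matrix, snorna_set: GeneSet) -> pd.Series:
    """Per-sample mean of raw TPM over the snoRNA signature set."""
    mask = match_set(matrix.symbols, snorna_set)
    scores = matrix.tpm.to_numpy()[mask].mean(axis=0)
    return pd.Series(scores, index=pd.Index(matrix.samples, name="sample_id"), name="snorna_module")


def zscore(values: Sequence[float]) -> np.ndarray:
    """Standardize to mean 0 and sample SD 1 (ddof=1)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("zscore requires at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zscore undefined for zero spread")
    return (v - v.mean()) / sd
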