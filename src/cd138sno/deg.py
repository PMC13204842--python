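"""Differential-expression screen on log2(TPM + 1).

The screen contrasts the aggressive tumor-positive/stroma-negative phenotype
(Group 1) against the pooled remaining groups. A gene is called differentially
expressed when the absolute difference of group means on the log2(TPM + 1)
scale is at least ``delta_threshold`` (default 1) and the two-sided per-gene
p-value is below ``alpha`` (default 0.05). The raw p drives the exploratory
call; Benjamini-Hochberg FDR is computed across all tested genes for the
volcano plot and downstream enrichment use.

The per-gene test is Welch's unequal-variance t-test, pluggable via the
``test`` argument of :func:`screen_degs` for rank-based alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

#: -log10(FDR) value reported when FDR underflows to exactly 0.
VOLCANO_Y_CAP = 300.0


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    symbol: str
    biotype: str
    delta: float  # mean log2(TPM+1) in Group 1 minus mean in the others
    p_value: float
    fdr: float
    direction: str  # "up" | "down"
    is_deg: bool


def log_transform(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Elementwise log2(TPM + 1); zeros map to zero."""
    return matrix.log2p1()


def welch_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch t-test (unequal variances, Welch-Satterthwaite df).

    Degenerate convention when both groups have zero variance: p = 1 if the
    means are equal, else p = 0 (the difference is then seen without noise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_test requires at least 2 values per group")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return np.inf if x.mean() > y.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_degs(
    matrix: ExpressionMatrix,
    group1_mask: Sequence[bool],
    delta_threshold: float = 1.0,
    alpha: float = 0.05,
    test: Callable[[np.ndarray, np.ndarray], tuple[float, float]] = welch_test,
) -> list[DEGRecord]:
    """Screen every gene for differential expression, Group 1 vs the rest.

    Parameters
    ----------
    matrix
        TPM expression matrix; the test runs on log2(TPM + 1).
    group1_mask
        Boolean per-sample membership of the contrast's positive group,
        aligned with ``matrix.samples``.
    """
    mask = np.asarray(group1_mask, dtype=bool)
    if mask.shape != (matrix.n_samples,):
        raise ValueError("group1_mask length must equal the number of samples")
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each pooled group needs at least 2 samples")

    log = matrix.log2p1().to_numpy()
    g1 = log[:, mask]
    rest = log[:, ~mask]
    deltas = g1.mean(axis=1) - rest.mean(axis=1)
    p_values = np.array([test(g1[i], rest[i])[1] for i in range(matrix.n_genes)])
    fdrs = bh_adjust(p_values)

    records = []
    for i, gene_id in enumerate(matrix.gene_ids):
        delta = float(deltas[i])
        records.append(
            DEGRecord(
                gene_id=str(gene_id),
                symbol=str(matrix.symbols.iloc[i]),
                biotype=str(matrix.biotypes.iloc[i]),
                delta=delta,
                p_value=float(p_values[i]),
                fdr=float(fdrs[i]),
                direction="up" if delta >= 0 else "down",
                is_deg=bool(abs(delta) >= delta_threshold and p_values[i] < alpha),
            )
        )
    return records


def records_to_frame(records: Sequence[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def volcano_table(records: Sequence[DEGRecord]) -> pd.DataFrame:
    """Plot-ready volcano rows: per gene, delta vs -log10(FDR).

    FDR values of exactly 0 are reported at the cap ``VOLCANO_Y_CAP`` and
    flagged in the ``capped`` column.
    """
    if not records:
        raise ValueError("volcano_table requires at least one record")
    rows = []
    for r in records:
        capped = r.fdr == 0.0
        y = VOLCANO_Y_CAP if capped else -np.log10(r.fdr)
        rows.append(
            {
                "gene_id": r.gene_id,
                "symbol": r.symbol,
                "delta": r.delta,
                "neg_log10_fdr": float(y),
                "is_deg": r.is_deg,
                "capped": capped,
            }
        )
    return pd.DataFrame(rows)
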