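"""snoRNA host-gene annotation and over-representation testing.

Small nucleolar RNAs guide chemical modification of rRNA — the H/ACA box
class directs pseudouridylation (Ψ), the C/D box class 2'-O-methylation —
and are usually processed from introns of a host gene. Differentially
expressed snoRNAs are mapped to host genes and attributes through an
annotation table (columns: sno_symbol, host_gene, box_type, target_rrna,
positions, modification, family_status; the bundled table covers the
Group-1-enriched snoRNA set with snoDB 2.0-style attributes, paralog
families expanded to their member symbols). Host genes are deduplicated
before enrichment so paralogous snoRNAs sharing a host do not double-count.

Over-representation of a query gene list in user-supplied GMT collections is
scored with the upper-tail hypergeometric test and Benjamini-Hochberg FDR;
the GO/KEGG term databases themselves are inputs, not bundled.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence
import warnings

import pandas as pd
from scipy import stats

from .deg import bh_adjust
from .signatures import GeneSet

ANNOTATION_COLUMNS = [
    "sno_symbol",
    "host_gene",
    "box_type",
    "target_rrna",
    "positions",
    "modification",
    "family_status",
]

# Box class determines the guided modification chemistry.
_EXPECTED_MODIFICATION = {"H/ACA": "Ψ", "C/D": "2'-O-Me"}


@dataclass(frozen=True)
class SnoRNAAnnotation:
    sno_symbol: str
    host_gene: str
    box_type: str  # "H/ACA" | "C/D"
    target_rrna: str  # "18S" | "28S"
    positions: str  # comma-separated nucleotide positions
    modification: str  # "Ψ" | "2'-O-Me"
    family_status: str  # "family" | "single"


@dataclass(frozen=True)
class OraResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    background_size: int
    p_value: float
    fdr: float


def load_annotation_table(path=None) -> list[SnoRNAAnnotation]:
    """Load an annotation TSV; defaults to the bundled snoRNA table."""
    if path is None:
        ref = resources.files("cd138sno").joinpath("data/snorna_annotation.tsv")
        with ref.open("r", encoding="utf-8") as fh:
            df = pd.read_csv(fh, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    records = [SnoRNAAnnotation(**{c: row[c] for c in ANNOTATION_COLUMNS}) for _, row in df.iterrows()]
    for rec in records:
        expected = _EXPECTED_MODIFICATION.get(rec.box_type)
        if expected is not None and rec.modification != expected:
            warnings.warn(
                f"{rec.sno_symbol}: box {rec.box_type} usually guides {expected}, "
                f"table says {rec.modification}",
                stacklevel=2,
            )
    return records


def write_annotation_table(records: Sequence[SnoRNAAnnotation], path) -> None:
    pd.DataFrame([r.__dict__ for r in records], columns=ANNOTATION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def annotate_snornas(
    symbols: Sequence[str], table: Sequence[SnoRNAAnnotation]
) -> tuple[list[SnoRNAAnnotation], list[str]]:
    """Look up snoRNA symbols in the annotation table.

    Returns (matched records in query order, unmatched symbols). Unmatched
    symbols are reported, never silently dropped.
    """
    by_symbol = {rec.sno_symbol: rec for rec in table}
    matched, unmatched = [], []
    for sym in symbols:
        rec = by_symbol.get(sym)
        if rec is None:
            unmatched.append(sym)
        else:
            matched.append(rec)
    return matched, unmatched


def unique_host_genes(records: Sequence[SnoRNAAnnotation]) -> list[str]:
    """Order-stable deduplicated host-gene list (for enrichment input)."""
    seen: dict[str, None] = {}
    for rec in records:
        seen.setdefault(rec.host_gene, None)
    return list(seen)


def hypergeom_ora(
    query: Sequence[str],
    collection: Mapping[str, GeneSet],
    background: Sequence[str],
) -> list[OraResult]:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    Each set is intersected with the background universe before testing;
    p = P(X >= overlap) with X ~ Hypergeom(N=|background|, K=|set|, n=|query|).
    FDR is Benjamini-Hochberg across all tested sets.
    """
    bg = set(background)
    if len(bg) != len(list(background)):
        raise ValueError("background contains duplicates")
    q = set(query)
    if not q:
        raise ValueError("query is empty")
    outside = q - bg
    if outside:
        raise ValueError(f"query genes missing from background: {sorted(outside)}")

    rows = []
    for name, gs in collection.items():
        members = set(gs.members) & bg
        overlap = len(q & members)
        # sf(k-1) = P(X >= k); overlap 0 gives p = 1 by the tail convention.
        p = float(stats.hypergeom.sf(overlap - 1, len(bg), len(members), len(q)))
        rows.append((name, overlap, len(members), p))

    fdrs = bh_adjust([r[3] for r in rows]) if rows else []
    return [
        OraResult(
            set_name=name,
            overlap=overlap,
            set_size=set_size,
            query_size=len(q),
            background_size=len(bg),
            p_value=p,
            fdr=float(fdr),
        )
        for (name, overlap, set_size, p), fdr in zip(rows, fdrs)
    ]
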