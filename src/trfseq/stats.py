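"""Correlation analyses and summary statistics over tRF count tables.

The biological question behind the correlations: is tRF5 abundance per
amino-acid category explained by how often the amino acid is encoded
(codon count) or by tRNA gene copy number? Pearson r over the 21
categories, with a two-sided p-value from the exact t transform
t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom — appropriate at
n = 21, where a normal approximation would be optimistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .classify import TRF1, TRF3, TRF5
from .quantify import CountTable, dominance_ratio, proportion_by_length
from .reference import AMINO_ACIDS, CODON_COUNTS


@dataclass
class CorrelationInput:
    """Label-aligned vectors over the 21 amino-acid categories."""

    categories: tuple[str, ...]
    y: np.ndarray          # normalized tRF5 totals
    x_codons: np.ndarray   # codons per category (standard genetic code)
    x_genes: np.ndarray    # tRNA gene counts per category

    def __post_init__(self) -> None:
        n = len(self.categories)
        if not (len(self.y) == len(self.x_codons) == len(self.x_genes) == n):
            raise ValueError("correlation vectors must be label-aligned")


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_two_sided: float


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson correlation with exact-t two-sided p-value.

    Requires at least 3 paired observations and two non-constant vectors
    (r is undefined otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("pearson needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson undefined for a constant vector")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=len(x),
                             p_two_sided=float(res.pvalue))


def correlation_input(
    table2: CountTable,
    gene_counts: Mapping[str, int],
    codon_counts: Mapping[str, int] = CODON_COUNTS,
) -> CorrelationInput:
    """Assemble the aligned vectors from a per-sample tRF5 table.

    All 21 categories enter, zero-count ones included; a missing row or
    gene count raises.
    """
    totals = table2.row_totals
    missing = [aa for aa in AMINO_ACIDS
               if aa not in totals.index or aa not in gene_counts]
    if missing:
        raise KeyError(f"categories missing from inputs: {missing}")
    return CorrelationInput(
        categories=AMINO_ACIDS,
        y=np.array([totals[aa] for aa in AMINO_ACIDS], dtype=float),
        x_codons=np.array([codon_counts[aa] for aa in AMINO_ACIDS], dtype=float),
        x_genes=np.array([gene_counts[aa] for aa in AMINO_ACIDS], dtype=float),
    )


def correlation_report(
    table2: CountTable,
    gene_counts: Mapping[str, int],
    codon_counts: Mapping[str, int] = CODON_COUNTS,
) -> tuple[CorrelationResult, CorrelationResult]:
    """(codons vs tRF5 totals, gene counts vs tRF5 totals), n = 21 each."""
    ci = correlation_input(table2, gene_counts, codon_counts)
    return (pearson(ci.x_codons, ci.y), pearson(ci.x_genes, ci.y))


def summary_report(
    length_tables: Mapping[str, CountTable] | None = None,
    per_sample_tables: Mapping[str, CountTable] | None = None,
) -> dict:
    """Headline statistics: class totals, per-animal ranges, length structure.

    ``length_tables`` / ``per_sample_tables`` map class names (``TRF5`` ...)
    to their tables; either may be absent. Dominance ratios are reported for
    rows with at least two occupied length bins.
    """
    report: dict = {"classes": {}}
    per_sample_tables = per_sample_tables or {}
    length_tables = length_tables or {}

    for cls in (TRF5, TRF3, TRF1):
        entry: dict = {}
        if cls in per_sample_tables:
            t = per_sample_tables[cls]
            col = t.col_totals
            entry["total"] = float(t.grand_total)
            entry["per_sample_mean"] = float(col.mean()) if len(col) else 0.0
            entry["per_sample_range"] = ([float(col.min()), float(col.max())]
                                         if len(col) else [0.0, 0.0])
        if cls in length_tables:
            t = length_tables[cls]
            entry.setdefault("total", float(t.grand_total))
            if t.grand_total > 0:
                props = t.proportions
                entry["length_proportions"] = {
                    int(k): float(v) for k, v in props.items()}
                entry["modal_length"] = int(props.idxmax())
                entry["dominance_ratios"] = {
                    aa: dominance_ratio(row)
                    for aa, row in t.data.iterrows()
                    if (np.asarray(row) > 0).sum() >= 2}
        report["classes"][cls] = entry
    return report


def write_summary_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")


def write_correlations_tsv(codons: CorrelationResult, genes: CorrelationResult,
                           path) -> None:
    with open(path, "w") as fh:
        fh.write("comparison\tr\tn\tp_two_sided\n")
        fh.write(f"codons_vs_trf5\t{codons.r:.4f}\t{codons.n}\t{codons.p_two_sided:.4f}\n")
        fh.write(f"genes_vs_trf5\t{genes.r:.4f}\t{genes.n}\t{genes.p_two_sided:.4f}\n")
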