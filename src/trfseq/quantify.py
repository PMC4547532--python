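"""Aggregation of per-sample counts into tables and library-size normalization.

Three table shapes cover the reporting needs of a serum tRF survey:

- a category x fragment-length table per class, summed over samples;
- a category x sample table per class, with recomputed margins;
- normalized variants of either, after scaling each sample by
  mean library size / its own library size.

Margins (totals, means, proportions) are always recomputed from cells and
never stored, so a table cannot go internally inconsistent. Normalized
values stay floating-point; rounding to whole counts happens only at
presentation (half-up, the convention of the printed tables).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import AMBIGUOUS, SampleCounts, TRF5
from .reference import AMINO_ACIDS

# Presentation defaults: fragments outside 28-40 nt each represent well
# under 0.2% of a serum library and are left out of the headline table;
# the full preprocessing window remains available via length_window.
REPORTING_WINDOW = (28, 40)
MASK_PROPORTION = 0.002


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (presentation only)."""
    return int(decimal.Decimal(x).quantize(0, rounding=decimal.ROUND_HALF_UP))


@dataclass
class CountTable:
    """A labelled category table with margins recomputed on demand."""

    data: pd.DataFrame          # rows: categories; columns: lengths or samples
    normalized: bool = False
    kind: str = ""              # "length" or "per_sample"
    trf_class: str = TRF5

    @property
    def row_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.data.to_numpy().sum())

    @property
    def proportions(self) -> pd.Series:
        """Column totals as a fraction of the grand total."""
        total = self.grand_total
        if total == 0:
            raise ValueError("proportions undefined for an all-zero table")
        return self.col_totals / total

    def row_means(self) -> pd.Series:
        return self.data.mean(axis=1)

    def masked(self, threshold: float = MASK_PROPORTION) -> "CountTable":
        """Drop columns whose share of the grand total is below ``threshold``."""
        keep = self.proportions >= threshold
        return replace(self, data=self.data.loc[:, keep])

    def to_tsv(self, path, provenance: str | None = None) -> None:
        with open(path, "w") as fh:
            if provenance:
                fh.write(f"# {provenance}\n")
            out = self.data.copy()
            if self.normalized:
                out = out.map(round_half_up)
            out["Total"] = self.row_totals.map(round_half_up) if self.normalized \
                else self.row_totals
            out.to_csv(fh, sep="\t")
            totals = self.col_totals
            fh.write("Total\t" + "\t".join(
                str(round_half_up(v) if self.normalized else v) for v in totals)
                + f"\t{round_half_up(self.grand_total) if self.normalized else self.grand_total}\n")
            if self.kind == "length" and self.grand_total > 0:
                fh.write("Proportion\t" + "\t".join(
                    f"{p:.3f}" for p in self.proportions) + "\t1.000\n")


@dataclass
class NormalizationSpec:
    """Per-sample library sizes; the mean is derived, never stored."""

    library_sizes: dict[str, float]

    def __post_init__(self) -> None:
        if not self.library_sizes:
            raise ValueError("library_sizes must be non-empty")
        if any(v <= 0 for v in self.library_sizes.values()):
            raise ValueError("library sizes must be positive")

    @property
    def mean_library_size(self) -> float:
        return float(np.mean(list(self.library_sizes.values())))

    def factor(self, sample_id: str) -> float:
        return self.mean_library_size / self.library_sizes[sample_id]


def normalization_spec(samples: Iterable[SampleCounts]) -> NormalizationSpec:
    return NormalizationSpec({s.sample_id: s.library_size for s in samples})


def normalize_counts(
    samples: Sequence[SampleCounts],
    spec: NormalizationSpec | None = None,
) -> list[SampleCounts]:
    """Scale each sample's cells by mean library size / its library size.

    Normalized counts = raw counts x mean library size / individual library
    size. With library size defined as the classified total, every
    normalized sample total equals the mean library size by construction.
    """
    if spec is None:
        spec = normalization_spec(samples)
    out = []
    for s in samples:
        f = spec.factor(s.sample_id)
        out.append(SampleCounts(
            sample_id=s.sample_id,
            cells={k: v * f for k, v in s.cells.items()},
            unclassified=s.unclassified,
            library_size=s.library_size,
            total_pass=s.total_pass,
            conflicts=s.conflicts.copy(),
        ))
    return out


def _category_rows(separate_mito: bool) -> list[str]:
    rows = list(AMINO_ACIDS)
    if separate_mito:
        rows += [f"mt-{aa}" for aa in AMINO_ACIDS]
    return rows


def _row_label(aa: str, mito: bool, separate_mito: bool) -> str | None:
    if aa == AMBIGUOUS or aa not in AMINO_ACIDS:
        return None
    return f"mt-{aa}" if (mito and separate_mito) else aa


def length_table(
    samples: Sequence[SampleCounts],
    trf_class: str = TRF5,
    length_window: tuple[int, int] = REPORTING_WINDOW,
    separate_mito: bool = False,
) -> CountTable:
    """Category x fragment-length table for one class, summed over samples.

    Rows are the 21 fixed categories (zero rows explicit); columns every
    length in ``length_window``. Ambiguous-category reads are excluded.
    """
    if not samples:
        raise ValueError("length_table needs at least one sample")
    lo, hi = length_window
    lengths = list(range(lo, hi + 1))
    rows = _category_rows(separate_mito)
    m = pd.DataFrame(0.0, index=rows, columns=lengths)
    for s in samples:
        for (cls, aa, ln, mito), v in s.cells.items():
            label = _row_label(aa, mito, separate_mito)
            if cls == trf_class and label is not None and lo <= ln <= hi:
                m.loc[label, ln] += v
    normalized = any(isinstance(v, float) and not float(v).is_integer()
                     for s in samples for v in s.cells.values())
    return CountTable(data=m, normalized=normalized, kind="length",
                      trf_class=trf_class)


def per_sample_table(
    samples: Sequence[SampleCounts],
    trf_class: str = TRF5,
    separate_mito: bool = False,
) -> CountTable:
    """Category x sample table for one class.

    With ``separate_mito=True`` mitochondrial hits get their own ``mt-``
    rows; merged otherwise. Total and per-sample-mean columns are available
    as recomputed margins (``row_totals`` / ``row_means``).
    """
    rows = _category_rows(separate_mito)
    cols = [s.sample_id for s in samples]
    m = pd.DataFrame(0.0, index=rows, columns=cols)
    for s in samples:
        for (cls, aa, ln, mito), v in s.cells.items():
            label = _row_label(aa, mito, separate_mito)
            if cls == trf_class and label is not None:
                m.loc[label, s.sample_id] += v
    normalized = any(isinstance(v, float) and not float(v).is_integer()
                     for s in samples for v in s.cells.values())
    return CountTable(data=m, normalized=normalized, kind="per_sample",
                      trf_class=trf_class)


def dominance_ratio(row) -> float:
    """Largest cell over second-largest non-zero cell of a category row.

    Quantifies how sharply one fragment length dominates a category.
    Requires at least two non-zero cells.
    """
    values = sorted((float(v) for v in np.asarray(row, dtype=float) if v > 0),
                    reverse=True)
    if len(values) < 2:
        raise ValueError("dominance ratio needs >= 2 non-zero cells")
    return values[0] / values[1]


def proportion_by_length(table: CountTable, lengths: Iterable[int]) -> float:
    """Share of the grand total carried by the selected length columns."""
    lengths = list(lengths)
    missing = [l for l in lengths if l not in table.data.columns]
    if missing:
        raise KeyError(f"lengths not in table: {missing}")
    total = table.grand_total
    if total == 0:
        raise ValueError("proportion undefined: table grand total is zero")
    return float(table.data[lengths].to_numpy().sum()) / total
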