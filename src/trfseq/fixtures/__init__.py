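"""Bundled reference tables from the published serum tRF survey.

The three TSVs transcribe the study's count tables cell by cell: the tRF5
length distribution summed over animals (raw counts, 28-40 nt), the
normalized tRF5 counts per animal together with bovine tRNA gene counts
per category, and the tRF3 counts per animal. Only cells are stored —
totals, means and proportions are recomputed, which also resolves two
arithmetic slips in the printed margins.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..classify import TRF3, TRF5
from ..quantify import CountTable


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="category")


def load_table1() -> CountTable:
    """tRF5 raw counts by category and fragment length (nt), all animals."""
    df = _read("table1_trf5_by_length.tsv")
    df.columns = df.columns.astype(int)
    return CountTable(data=df.astype(float), normalized=False,
                      kind="length", trf_class=TRF5)


def load_table2() -> tuple[CountTable, pd.Series]:
    """Normalized tRF5 counts per animal, plus tRNA gene counts per category."""
    df = _read("table2_trf5_by_animal.tsv")
    genes = df.pop("trna_genes")
    table = CountTable(data=df.astype(float), normalized=True,
                       kind="per_sample", trf_class=TRF5)
    return table, genes


def load_table3() -> CountTable:
    """tRF3 counts per animal."""
    df = _read("table3_trf3_by_animal.tsv")
    return CountTable(data=df.astype(float), normalized=True,
                      kind="per_sample", trf_class=TRF3)
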