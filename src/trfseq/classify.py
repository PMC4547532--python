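"""Read classification by anchored perfect matching.

A read is called:

- ``TRF5`` if it is an exact prefix of a mature tRNA sequence,
- ``TRF3`` if it is an exact suffix of a mature tRNA, either as encoded or
  with the post-transcriptional CCA tail appended,
- ``TRF1`` if it is an exact prefix of a gene's 3' trailer (the genomic
  flank immediately downstream of the mature tRNA), and
- ``UNCLASSIFIED`` otherwise.

No mismatches are tolerated anywhere. The rules are checked in precedence
order TRF5 > TRF3 > TRF1; a read satisfying more than one rule (possible
for short reads over repeated sequence) takes the first class and bumps a
conflict counter. A read matching genes of different amino-acid categories
keeps its class but is labelled ``ambiguous`` and excluded from
per-category tables. When a read hits both nuclear and mitochondrial genes
of a category, the nuclear label wins and the conflict is counted.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .preprocess import UniqueReadSet
from .reference import TRFReferenceSet

TRF5 = "TRF5"
TRF3 = "TRF3"
TRF1 = "TRF1"
UNCLASSIFIED = "UNCLASSIFIED"
TRF_CLASSES = (TRF5, TRF3, TRF1)

AMBIGUOUS = "ambiguous"

# Cell key: (trf_class, amino_acid, fragment_length, mitochondrial)
CellKey = tuple[str, str, int, bool]


@dataclass
class TRFCall:
    """Classification of one read."""

    read_seq: str
    trf_class: str
    gene_ids: list[str] = field(default_factory=list)
    amino_acid: str = ""
    length: int = 0
    cca_status: str = "not_applicable"  # none | full_CCA | not_applicable
    mitochondrial: bool = False
    rule_conflict: bool = False      # read satisfied >1 classification rule
    nuc_mito_conflict: bool = False  # matched nuclear and mitochondrial genes


@dataclass
class SampleCounts:
    """Per-sample counts keyed by (class, amino acid, length, mito flag).

    Reads whose matched genes span several amino-acid categories are
    counted under the ``ambiguous`` pseudo-category so that count
    conservation (cells + unclassified == length-pass total) always holds;
    tables simply leave that row out.
    """

    sample_id: str
    cells: dict[CellKey, float] = field(default_factory=dict)
    unclassified: int = 0
    library_size: float = 0
    total_pass: int = 0
    conflicts: Counter = field(default_factory=Counter)

    @property
    def classified_total(self) -> float:
        return sum(self.cells.values())

    @property
    def ambiguous_total(self) -> float:
        return sum(v for k, v in self.cells.items() if k[1] == AMBIGUOUS)

    def class_total(self, trf_class: str) -> float:
        return sum(v for k, v in self.cells.items() if k[0] == trf_class)


def _label(ref: TRFReferenceSet, gene_ids: set[str]) -> tuple[str, bool, bool]:
    """Resolve (amino_acid, mitochondrial, nuc_mito_conflict) for a hit set."""
    genes = [ref.genes[g] for g in gene_ids]
    aas = {g.amino_acid for g in genes}
    amino_acid = aas.pop() if len(aas) == 1 else AMBIGUOUS
    mito_flags = {g.mitochondrial for g in genes}
    if mito_flags == {True}:
        return amino_acid, True, False
    # mixed nuclear/mitochondrial: the nuclear label wins, conflict noted
    return amino_acid, False, len(mito_flags) == 2


def classify_read(read_seq: str, ref: TRFReferenceSet) -> TRFCall:
    """Classify a single read against the reference by anchored exact match.

    All genes matching under the winning class are recorded; gene ids are
    returned sorted, so the call is independent of reference construction
    order.
    """
    seq = read_seq.upper().replace("U", "T")
    trf5_ids = ref.match_prefix(seq)
    plain_ids, cca_ids = ref.match_suffix(seq)
    trf3_ids = plain_ids | cca_ids
    trf1_ids = ref.match_flank_prefix(seq)

    n_rules = bool(trf5_ids) + bool(trf3_ids) + bool(trf1_ids)
    call = TRFCall(read_seq=seq, trf_class=UNCLASSIFIED, length=len(seq),
                   rule_conflict=n_rules > 1)

    if trf5_ids:
        call.trf_class, ids, call.cca_status = TRF5, trf5_ids, "not_applicable"
    elif trf3_ids:
        call.trf_class, ids = TRF3, trf3_ids
        # full_CCA only when no gene's plain mature end explains the read
        call.cca_status = "none" if plain_ids else "full_CCA"
    elif trf1_ids:
        call.trf_class, ids, call.cca_status = TRF1, trf1_ids, "not_applicable"
    else:
        return call

    call.gene_ids = sorted(ids)
    call.amino_acid, call.mitochondrial, call.nuc_mito_conflict = _label(ref, ids)
    return call


def classify_sample(
    reads: UniqueReadSet,
    ref: TRFReferenceSet,
    library_size_mode: str = "classified",
) -> SampleCounts:
    """Classify every unique read once and accumulate multiplicities.

    Each read contributes its multiplicity to a single
    (class, amino acid, length, mito) cell — per-read, not per-gene-hit —
    or to the unclassified tally. ``library_size_mode`` selects what the
    normalization step later divides by: ``"classified"`` (total classified
    tRF count, the default) or ``"all"`` (total length-pass reads).
    """
    if library_size_mode not in ("classified", "all"):
        raise ValueError("library_size_mode must be 'classified' or 'all'")
    sc = SampleCounts(sample_id=reads.sample_id, total_pass=reads.total_pass)
    for seq in sorted(reads.entries):  # iteration-order independence
        mult = reads.entries[seq]
        call = classify_read(seq, ref)
        if call.trf_class == UNCLASSIFIED:
            sc.unclassified += mult
        else:
            key = (call.trf_class, call.amino_acid, call.length, call.mitochondrial)
            sc.cells[key] = sc.cells.get(key, 0) + mult
        if call.rule_conflict:
            sc.conflicts["rule_precedence"] += 1
        if call.nuc_mito_conflict:
            sc.conflicts["nuclear_vs_mitochondrial"] += 1
    sc.library_size = (sc.classified_total if library_size_mode == "classified"
                       else sc.total_pass)
    return sc


def write_calls_tsv(reads: UniqueReadSet, ref: TRFReferenceSet, path) -> None:
    """Write one row per unique read with its full call."""
    with open(path, "w") as fh:
        fh.write("sequence\tmultiplicity\ttrf_class\tamino_acid\tlength\t"
                 "cca_status\tmitochondrial\tgene_ids\n")
        for seq in sorted(reads.entries):
            call = classify_read(seq, ref)
            fh.write(f"{seq}\t{reads.entries[seq]}\t{call.trf_class}\t"
                     f"{call.amino_acid}\t{call.length}\t{call.cca_status}\t"
                     f"{int(call.mitochondrial)}\t{','.join(call.gene_ids)}\n")


def classification_report(sc: SampleCounts) -> dict:
    return {
        "sample_id": sc.sample_id,
        "total_pass": sc.total_pass,
        "classified": sc.classified_total,
        "unclassified": sc.unclassified,
        "ambiguous": sc.ambiguous_total,
        "library_size": sc.library_size,
        "per_class": {c: sc.class_total(c) for c in TRF_CLASSES},
        "conflicts": dict(sc.conflicts),
    }


def write_classification_report(sc: SampleCounts, path) -> None:
    with open(path, "w") as fh:
        json.dump(classification_report(sc), fh, indent=2)
        fh.write("\n")
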