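"""FASTQ preprocessing: adapter clipping, length filtering, read collapsing.

Small-RNA inserts are shorter than the sequencing read length, so most
reads run into the 3' sequencing adapter; clipping scans for the leftmost
seeded adapter match. Quality strings are read but never used — downstream
classification is exact-match, so miscalled bases simply fail to classify.
Reads containing N are kept for the same reason.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

# NEBNext small-RNA 3' SR adapter; override per run if the library prep differs.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"
DEFAULT_MIN_OVERLAP = 7
DEFAULT_MAX_MISMATCHES = 1
DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 40


@dataclass
class UniqueReadSet:
    """Length-filtered unique reads with multiplicities for one sample."""

    sample_id: str
    entries: dict[str, int] = field(default_factory=dict)
    total_input: int = 0
    total_pass: int = 0

    def __post_init__(self) -> None:
        if sum(self.entries.values()) != self.total_pass:
            raise ValueError("total_pass must equal the sum of multiplicities")
        if self.total_pass > self.total_input:
            raise ValueError("total_pass cannot exceed total_input")


def clip_adapter(
    read: str,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> tuple[str, bool]:
    """Clip the 3' adapter from a read.

    Finds the leftmost position where a prefix of the adapter of length
    >= ``min_overlap`` (shortened only by the end of the read) matches with
    at most ``max_mismatches`` mismatches, and truncates the read there.
    Returns ``(clipped_read, clipped?)``; an adapter-free read comes back
    unchanged with ``clipped?=False``.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read = read.upper()
    adapter = adapter.upper()
    n = len(read)
    for i in range(0, n - min_overlap + 1):
        span = min(len(adapter), n - i)
        mismatches = 0
        for a, b in zip(read[i:i + span], adapter):
            if a != b:
                mismatches += 1
                if mismatches > max_mismatches:
                    break
        else:
            return read[:i], True
    return read, False


def filter_by_length(
    reads: Iterable[str],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[list[str], dict[str, int]]:
    """Keep reads with min_len <= length <= max_len (both bounds inclusive).

    Returns the retained reads and a tally ``{"input": n, "pass": k,
    "fail": n - k}``.
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    kept = []
    n = 0
    for r in reads:
        n += 1
        if min_len <= len(r) <= max_len:
            kept.append(r)
    return kept, {"input": n, "pass": len(kept), "fail": n - len(kept)}


def collapse_unique(reads: Iterable[str], sample_id: str = "",
                    total_input: int | None = None) -> UniqueReadSet:
    """Merge multiple occurrences of identical reads, keeping multiplicities."""
    counts = Counter(r.upper() for r in reads)
    total_pass = sum(counts.values())
    return UniqueReadSet(
        sample_id=sample_id,
        entries=dict(counts),
        total_input=total_pass if total_input is None else total_input,
        total_pass=total_pass,
    )


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq_seqs(path) -> Iterator[str]:
    """Yield read sequences from a (possibly gzipped) FASTQ file."""
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper()


def preprocess_reads(
    seqs: Iterable[str],
    sample_id: str = "",
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[UniqueReadSet, dict]:
    """Clip, length-filter and collapse an iterable of read sequences.

    Returns the unique-read set and a preprocessing report with input,
    clipped and length-pass tallies.
    """
    clipped_seqs = []
    n_input = n_clipped = 0
    for s in seqs:
        n_input += 1
        clipped, was_clipped = clip_adapter(s, adapter, min_overlap, max_mismatches)
        n_clipped += was_clipped
        clipped_seqs.append(clipped)
    kept, tally = filter_by_length(clipped_seqs, min_len, max_len)
    urs = collapse_unique(kept, sample_id, total_input=n_input)
    report = {
        "sample_id": sample_id,
        "input_reads": n_input,
        "clipped": n_clipped,
        "length_pass": tally["pass"],
        "length_fail": tally["fail"],
        "unique_reads": len(urs.entries),
    }
    return urs, report


def preprocess_fastq(path, sample_id: str | None = None, **kwargs
                     ) -> tuple[UniqueReadSet, dict]:
    """Run :func:`preprocess_reads` on a FASTQ file."""
    if sample_id is None:
        sample_id = Path(path).name.split(".")[0]
    return preprocess_reads(iter_fastq_seqs(path), sample_id=sample_id, **kwargs)


def write_collapsed_tsv(urs: UniqueReadSet, path) -> None:
    """Write (sequence, multiplicity) pairs, most abundant first."""
    with open(path, "w") as fh:
        fh.write("sequence\tmultiplicity\n")
        for seq, mult in sorted(urs.entries.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{seq}\t{mult}\n")


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
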