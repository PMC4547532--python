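"""tRNA gene reference handling.

Parses tRNA gene FASTA files with gtRNAdb-style headers, attaches genomic
flanking sequence on both sides of each gene, and builds the anchored-lookup
index that read classification queries against.

Coordinates are 0-based half-open internally; any reporting is 1-based
inclusive. Mature tRNA sequences are stored as genomically encoded DNA,
without the post-transcriptional CCA tail — the CCA-tolerant 3' end lookups
are synthesized at index-build time instead.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

# The 21 fragment categories used throughout: the 20 standard amino acids
# plus "Stop", which aggregates selenocysteine- and suppressor-annotated
# tRNA genes. Order matches the conventional alphabetical table layout.
AMINO_ACIDS: tuple[str, ...] = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Stop", "Thr", "Trp", "Tyr",
    "Val",
)

# Codons per category under the standard genetic code (Stop = the three
# stop codons, matching the aggregation of SeC/Sup tRNAs into "Stop").
CODON_COUNTS: dict[str, int] = {
    "Ala": 4, "Arg": 6, "Asn": 2, "Asp": 2, "Cys": 2, "Gln": 2, "Glu": 2,
    "Gly": 4, "His": 2, "Ile": 3, "Leu": 6, "Lys": 2, "Met": 1, "Phe": 2,
    "Pro": 4, "Ser": 6, "Stop": 3, "Thr": 4, "Trp": 1, "Tyr": 2, "Val": 4,
}

# Header isoacceptor tokens that fold into a category label.
_AA_ALIASES = {"SeC": "Stop", "Sec": "Stop", "Sup": "Stop", "iMet": "Met", "fMet": "Met"}

DEFAULT_NAME_PATTERN = r"tRNA-(?P<aa>[A-Za-z]{2,4})-(?P<anticodon>[A-Za-z]{3})"
DEFAULT_LOCUS_PATTERN = (
    r"(?P<contig>[\w.]+):(?P<start>\d+)-(?P<end>\d+)\s*\((?P<strand>[+-])\)"
)
DEFAULT_MITO_PATTERN = r"(?i)(^chrM\.|\bchrM\b|\bMT\b|mito)"
DEFAULT_INTRON_PATTERN = r"intron[=:]\s*(?P<istart>\d+)-(?P<iend>\d+)"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TRNAGeneRecord:
    """One tRNA gene: identity, mature sequence, locus, and flanks.

    ``mature_seq`` is the genomic mature sequence (introns removed when
    annotated, no CCA). ``flank5``/``flank3`` are in transcript orientation
    and at most ``flank_len`` (40 by default) bases each; they are empty
    until :func:`attach_flanks` runs.
    """

    gene_id: str
    amino_acid: str
    anticodon: str
    mature_seq: str
    contig: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    flank5: str = ""
    flank3: str = ""
    mitochondrial: bool = False

    def __post_init__(self) -> None:
        if not self.mature_seq:
            raise ValueError(f"{self.gene_id}: empty mature sequence")
        bad = set(self.mature_seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.gene_id}: non-DNA characters {sorted(bad)}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")


def _normalize_category(token: str) -> str:
    token = _AA_ALIASES.get(token, token)
    if token in CODON_COUNTS:
        return token
    cap = token.capitalize()
    if cap in CODON_COUNTS:
        return cap
    return "unknown"


def parse_trna_fasta(
    source,
    *,
    name_pattern: str = DEFAULT_NAME_PATTERN,
    locus_pattern: str = DEFAULT_LOCUS_PATTERN,
    mito_pattern: str = DEFAULT_MITO_PATTERN,
    intron_pattern: str = DEFAULT_INTRON_PATTERN,
    remove_introns: bool = True,
) -> list[TRNAGeneRecord]:
    """Parse a tRNA gene FASTA into records.

    ``source`` may be a path, an open handle, or FASTA content itself
    (a string starting with ``>``). Headers are matched against
    ``name_pattern`` for the ``tRNA-<AA>-<anticodon>`` token; headers that
    do not match are kept with ``amino_acid="unknown"`` and a warning.
    Locus coordinates in the header, if present, are 1-based inclusive and
    converted to 0-based half-open. Intron annotations (1-based positions
    within the gene sequence) are excised by default.

    Empty sequences raise ``ValueError``.
    """
    if isinstance(source, str) and source.lstrip().startswith(">"):
        handle = io.StringIO(source)
    elif isinstance(source, (str, Path)):
        handle = open(source)
    else:
        handle = source

    name_re = re.compile(name_pattern)
    locus_re = re.compile(locus_pattern)
    mito_re = re.compile(mito_pattern)
    intron_re = re.compile(intron_pattern)

    records: list[TRNAGeneRecord] = []
    for entry in SeqIO.parse(handle, "fasta"):
        header = entry.description
        seq = str(entry.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"{entry.id}: empty sequence in tRNA FASTA")

        m = name_re.search(header)
        if m:
            amino_acid = _normalize_category(m.group("aa"))
            anticodon = m.group("anticodon").upper().replace("U", "T")
            if amino_acid == "unknown":
                logger.warning("header %r: unrecognized amino-acid token %r",
                               header, m.group("aa"))
        else:
            amino_acid, anticodon = "unknown", "unknown"
            logger.warning("header %r does not match the tRNA name pattern", header)

        contig, start, end, strand = "", 0, 0, "+"
        lm = locus_re.search(header)
        if lm:
            contig = lm.group("contig")
            start = int(lm.group("start")) - 1
            end = int(lm.group("end"))
            strand = lm.group("strand")

        im = intron_re.search(header)
        if im and remove_introns:
            a, b = int(im.group("istart")) - 1, int(im.group("iend"))
            if not (0 <= a < b <= len(seq)):
                raise ValueError(f"{entry.id}: intron {a + 1}-{b} outside gene")
            seq = seq[:a] + seq[b:]

        records.append(TRNAGeneRecord(
            gene_id=entry.id,
            amino_acid=amino_acid,
            anticodon=anticodon,
            mature_seq=seq,
            contig=contig,
            start=start,
            end=end,
            strand=strand,
            mitochondrial=bool(mito_re.search(header)),
        ))
    return records


def _contig_slice(genome, contig: str, start: int, end: int) -> str:
    """Fetch genome[contig][start:end] from a pyfaidx Fasta or a plain mapping."""
    record = genome[contig]
    return str(record[start:end]).upper()


def attach_flanks(gene: TRNAGeneRecord, genome, flank_len: int = 40) -> TRNAGeneRecord:
    """Attach up-/downstream genomic flanks to a gene, in transcript orientation.

    ``flank5`` holds the ``flank_len`` bases immediately 5' of the mature
    start and ``flank3`` the bases immediately 3' of the mature end; for a
    minus-strand gene both are extracted from the opposite side of the locus
    and reverse-complemented. Flanks are truncated (with a warning) when the
    locus sits within ``flank_len`` of a contig edge. The record is modified
    in place and returned.
    """
    if gene.contig not in genome:
        raise KeyError(f"{gene.gene_id}: contig {gene.contig!r} not in genome")
    contig_len = len(genome[gene.contig])
    if not (0 <= gene.start < gene.end <= contig_len):
        raise ValueError(f"{gene.gene_id}: locus outside contig {gene.contig}")

    up_start = max(0, gene.start - flank_len)
    upstream = _contig_slice(genome, gene.contig, up_start, gene.start)
    downstream = _contig_slice(
        genome, gene.contig, gene.end, min(contig_len, gene.end + flank_len))

    if gene.strand == "+":
        gene.flank5, gene.flank3 = upstream, downstream
    else:
        gene.flank5, gene.flank3 = revcomp(downstream), revcomp(upstream)

    if len(gene.flank5) < flank_len or len(gene.flank3) < flank_len:
        logger.warning("%s: flank truncated at contig edge (5'=%d nt, 3'=%d nt)",
                       gene.gene_id, len(gene.flank5), len(gene.flank3))
    return gene


@dataclass
class TRFReferenceSet:
    """Indexed tRNA reference supporting O(read-length) anchored queries.

    Four lookup tables map anchored substrings to gene ids, for every
    substring length inside ``read_len_window``:

    - ``by_prefix``: prefixes of the mature sequence (5'-fragment anchor);
    - ``by_suffix``: suffixes of the mature sequence (3' anchor, no CCA);
    - ``by_suffix_cca``: suffixes of mature + ``CCA`` that include at least
      part of the appended tail;
    - ``by_flank_prefix``: prefixes of the 3' trailer flank.
    """

    genes: dict[str, TRNAGeneRecord]
    by_prefix: dict[str, set[str]] = field(default_factory=dict)
    by_suffix: dict[str, set[str]] = field(default_factory=dict)
    by_suffix_cca: dict[str, set[str]] = field(default_factory=dict)
    by_flank_prefix: dict[str, set[str]] = field(default_factory=dict)
    flank_len: int = 40
    read_len_window: tuple[int, int] = (15, 45)

    def match_prefix(self, seq: str) -> set[str]:
        return self.by_prefix.get(seq, set())

    def match_suffix(self, seq: str) -> tuple[set[str], set[str]]:
        """Gene ids whose mature end (plain, CCA-appended) equals ``seq``."""
        return (self.by_suffix.get(seq, set()),
                self.by_suffix_cca.get(seq, set()))

    def match_flank_prefix(self, seq: str) -> set[str]:
        return self.by_flank_prefix.get(seq, set())


def build_reference(
    genes: Iterable[TRNAGeneRecord],
    flank_len: int = 40,
    read_len_window: tuple[int, int] = (15, 45),
    allow_partial_cca: bool = False,
) -> TRFReferenceSet:
    """Build the anchored-lookup index over a gene collection.

    Every anchored substring whose length falls in ``read_len_window`` is
    enumerated once; queries are then single dictionary lookups. Duplicate
    gene ids raise; an empty gene list raises.

    By default only the two terminal forms named by the classification rule
    are indexed for 3' fragments: the exact mature end and the mature end
    with a full appended CCA. ``allow_partial_cca=True`` additionally
    accepts C/CC partial tails.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("cannot build a reference from an empty gene list")
    table: dict[str, TRNAGeneRecord] = {}
    for g in genes:
        if g.gene_id in table:
            raise ValueError(f"duplicate gene id {g.gene_id!r}")
        table[g.gene_id] = g

    lo, hi = read_len_window
    if not (1 <= lo <= hi):
        raise ValueError("read_len_window must satisfy 1 <= lo <= hi")

    ref = TRFReferenceSet(genes=table, flank_len=flank_len,
                          read_len_window=read_len_window)
    for gid, g in table.items():
        mature = g.mature_seq
        with_cca = mature + "CCA"
        for k in range(lo, min(hi, len(mature)) + 1):
            ref.by_prefix.setdefault(mature[:k], set()).add(gid)
            ref.by_suffix.setdefault(mature[-k:], set()).add(gid)
        # CCA-appended suffixes: only those actually covering the tail,
        # otherwise they duplicate plain mature suffixes shifted by 3.
        for k in range(max(lo, 4), min(hi, len(with_cca)) + 1):
            ref.by_suffix_cca.setdefault(with_cca[-k:], set()).add(gid)
        if allow_partial_cca:
            for tail in ("C", "CC"):
                ext = mature + tail
                for k in range(max(lo, len(tail) + 1), min(hi, len(ext)) + 1):
                    ref.by_suffix_cca.setdefault(ext[-k:], set()).add(gid)
        for k in range(lo, min(hi, len(g.flank3)) + 1):
            ref.by_flank_prefix.setdefault(g.flank3[:k], set()).add(gid)
    return ref


def write_extended_reference(genes: Iterable[TRNAGeneRecord], path) -> None:
    """Write flank5 + mature + flank3 per gene as FASTA."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id} extended flank5={len(g.flank5)} "
                     f"mature={len(g.mature_seq)} flank3={len(g.flank3)}\n")
            fh.write(g.flank5 + g.mature_seq + g.flank3 + "\n")


def write_manifest(genes: Iterable[TRNAGeneRecord], path) -> None:
    """Write a TSV manifest (gene_id, category, anticodon, lengths, mito)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tamino_acid\tanticodon\tmature_len\t"
                 "flank5_len\tflank3_len\tmitochondrial\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.amino_acid}\t{g.anticodon}\t"
                     f"{len(g.mature_seq)}\t{len(g.flank5)}\t{len(g.flank3)}\t"
                     f"{int(g.mitochondrial)}\n")


def gene_counts_by_category(genes: Iterable[TRNAGeneRecord]) -> dict[str, int]:
    """Number of tRNA genes per amino-acid category (all 21 keys present)."""
    counts = {aa: 0 for aa in AMINO_ACIDS}
    for g in genes:
        if g.amino_acid in counts:
            counts[g.amino_acid] += 1
    return counts
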