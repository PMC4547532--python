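"""Synthetic tRNA references and labelled small-RNA reads.

The generator emulates the structure of a serum small-RNA sequencing
experiment: a set of tRNA genes embedded at known loci (both strands) in a
toy genome, and per-animal FASTQ files of adapter-bearing reads drawn from
tRNA 5' ends, 3' ends (with or without the CCA tail), and 3' trailer
flanks, plus decoy reads of non-tRNA sequence. Every read carries a
ground-truth label, so classification can be scored exactly.

Defaults mirror the serum profile the pipeline targets: 5'-end fragments
dominate heavily (90% of reads), per-category abundances follow the
published per-animal totals, and 5'-fragment lengths follow the published
per-category length histograms (e.g. His bimodal at 31/34 nt). Decoys
stand in for the other small non-coding RNAs a real library contains.

One RNG stream is derived per sample from (seed, sample index), so samples
are independent and individually reproducible; a fixed seed reproduces
output byte for byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .classify import TRF1, TRF3, TRF5
from .preprocess import DEFAULT_ADAPTER
from .reference import AMINO_ACIDS, TRNAGeneRecord, attach_flanks, build_reference, revcomp

DECOY = "decoy"

_BASES = np.array(list("ACGT"))

# Three-letter -> one-letter, to pull anticodons from the standard code.
_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}


def _anticodons_for(category: str) -> list[str]:
    if category == "Stop":
        codons = standard_dna_table.stop_codons
    else:
        one = _AA3_TO_1[category]
        codons = [c for c, aa in standard_dna_table.forward_table.items()
                  if aa == one]
    return sorted(revcomp(c) for c in codons)


def _header_token(category: str) -> str:
    # Stop-category genes carry the selenocysteine token, as curated
    # tRNA databases annotate them.
    return "SeC" if category == "Stop" else category


@dataclass
class SimulationConfig:
    """Everything that determines a simulated dataset.

    ``class_mix`` gives the probability that a read originates from a
    5' fragment, 3' fragment, 3' trailer fragment, or from non-tRNA decoy
    sequence. ``category_weights`` shapes relative category abundance
    (default: published per-animal totals plus a pseudocount of 1, so no
    category has zero mass). ``trf5_length_dist`` maps each category to a
    discrete length distribution over 28-40 nt (default: fitted from the
    published length table; zero rows fall back to uniform on 30-34).
    """

    seed: int = 0
    n_samples: int = 8
    n_reads: int = 50_000                 # per sample
    n_genes_per_category: int | Mapping[str, int] = 2
    mito_categories: tuple[str, ...] = ("Val", "Tyr")
    mature_length_range: tuple[int, int] = (70, 95)
    flank_len: int = 40
    class_mix: dict[str, float] = field(default_factory=lambda: {
        TRF5: 0.90, TRF3: 0.005, TRF1: 0.005, DECOY: 0.09})
    category_weights: dict[str, float] | None = None
    trf5_length_dist: dict[str, dict[int, float]] | None = None
    trf3_length_range: tuple[int, int] = (18, 25)
    trf1_length_range: tuple[int, int] = (18, 30)
    decoy_length_range: tuple[int, int] = (18, 40)
    cca_prob: float = 0.5
    adapter: str = DEFAULT_ADAPTER
    machine_read_len: int = 50
    error_rate: float = 0.0
    inject_ambiguity: bool = False

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix probabilities sum to {total}, not 1")
        if not 0.0 <= self.cca_prob <= 1.0:
            raise ValueError("cca_prob must lie in [0, 1]")
        if isinstance(self.n_genes_per_category, Mapping):
            bad = [c for c, n in self.n_genes_per_category.items() if n < 1]
        else:
            bad = [] if self.n_genes_per_category >= 1 else ["all"]
        if bad:
            raise ValueError(f"need at least one gene per simulated category: {bad}")
        if self.category_weights is None:
            from .fixtures import load_table2
            totals = load_table2()[0].row_totals
            self.category_weights = {aa: float(totals[aa]) + 1.0
                                     for aa in AMINO_ACIDS}
        if self.trf5_length_dist is None:
            from .fixtures import load_table1
            self.trf5_length_dist = fit_length_preset(load_table1().data)

    def genes_for(self, category: str) -> int:
        if isinstance(self.n_genes_per_category, Mapping):
            return int(self.n_genes_per_category.get(category, 0))
        return int(self.n_genes_per_category)


def fit_length_preset(table1: pd.DataFrame) -> dict[str, dict[int, float]]:
    """Per-category empirical length distributions from a length table.

    Each row is normalized to 1; all-zero rows fall back to a uniform
    distribution over 30-34 nt, the bulk of the observed range.
    """
    preset: dict[str, dict[int, float]] = {}
    fallback = {ln: 0.2 for ln in range(30, 35)}
    for aa, row in table1.iterrows():
        total = float(row.sum())
        if total <= 0:
            preset[aa] = dict(fallback)
        else:
            preset[aa] = {int(ln): float(v) / total
                          for ln, v in row.items() if v > 0}
    return preset


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


_ANCHOR_LEN = 18  # distinctness scale: no two genes may share an 18-nt end


def simulate_reference(config: SimulationConfig
                       ) -> tuple[list[TRNAGeneRecord], dict[str, str]]:
    """Generate tRNA genes embedded in a toy genome, with flanks attached.

    Genes are placed on alternating strands of a nuclear contig (plus a
    mitochondrial contig for ``mito_categories``), separated by random
    spacer. Rejection sampling keeps every gene's 5' and 3' ends pairwise
    distinct at 18 nt — hence also at 28 nt — so fragment provenance is
    unambiguous unless ambiguity injection is requested, which forces one
    cross-category pair to share a 30-nt prefix.
    """
    rng = np.random.default_rng([config.seed, 11])
    lo, hi = config.mature_length_range
    seen_anchors: set[str] = set()
    specs: list[tuple[str, str, str, bool]] = []  # (gene_id, category, seq, mito)

    def draw_mature(force_prefix: str = "") -> str:
        for _ in range(200):
            length = int(rng.integers(lo, hi + 1))
            seq = force_prefix + _random_seq(rng, length - len(force_prefix))
            anchors = {seq[:_ANCHOR_LEN], seq[-_ANCHOR_LEN:]}
            if force_prefix:
                anchors = {seq[-_ANCHOR_LEN:]}
            if anchors & seen_anchors:
                continue
            seen_anchors.update({seq[:_ANCHOR_LEN], seq[-_ANCHOR_LEN:]})
            return seq
        raise RuntimeError("could not draw a distinct mature sequence "
                           "in 200 attempts")

    for category in AMINO_ACIDS:
        anticodons = _anticodons_for(category)
        for i in range(config.genes_for(category)):
            seq = draw_mature()
            anticodon = anticodons[i % len(anticodons)]
            gid = f"tRNA-{_header_token(category)}-{anticodon}-{i + 1}-1"
            specs.append((gid, category, seq, False))
    for j, category in enumerate(config.mito_categories):
        anticodon = _anticodons_for(category)[0]
        gid = f"chrM.tRNA-{_header_token(category)}-{anticodon}-{j + 1}-1"
        specs.append((gid, category, draw_mature(), True))

    if config.inject_ambiguity and len(specs) >= 2:
        # overwrite one gene of a different category with a shared 30-nt prefix
        donor_seq = specs[0][2]
        victim = next(k for k, s in enumerate(specs) if s[1] != specs[0][1])
        gid, category, _, mito = specs[victim]
        specs[victim] = (gid, category, draw_mature(force_prefix=donor_seq[:30]),
                         mito)

    spacer = 60  # > flank_len, so trailer flanks never reach a neighbour gene
    genome: dict[str, str] = {}
    genes: list[TRNAGeneRecord] = []
    for contig, mito_flag in (("chr1", False), ("chrM", True)):
        parts: list[str] = [_random_seq(rng, spacer)]
        pos = spacer
        for k, (gid, category, seq, mito) in enumerate(s for s in specs
                                                       if s[3] == mito_flag):
            strand = "+" if k % 2 == 0 else "-"
            embedded = seq if strand == "+" else revcomp(seq)
            start, end = pos, pos + len(seq)
            parts.append(embedded)
            parts.append(_random_seq(rng, spacer))
            pos = end + spacer
            genes.append(TRNAGeneRecord(
                gene_id=gid, amino_acid=category,
                anticodon=_anticodon_of(gid), mature_seq=seq,
                contig=contig, start=start, end=end, strand=strand,
                mitochondrial=mito))
        if len(parts) > 1:
            genome[contig] = "".join(parts)
    for g in genes:
        attach_flanks(g, genome, config.flank_len)
    return genes, genome


def _anticodon_of(gene_id: str) -> str:
    return gene_id.split("tRNA-")[1].split("-")[1]


def write_reference_fastas(genes: Sequence[TRNAGeneRecord],
                           genome: Mapping[str, str], outdir) -> None:
    """Write the gene FASTA (database-style headers with loci) and genome."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "trna_genes.fasta", "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id} {g.contig}:{g.start + 1}-{g.end}"
                     f"({g.strand})\n{g.mature_seq}\n")
    with open(outdir / "genome.fasta", "w") as fh:
        for contig, seq in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def _draw_category(rng, categories: list[str], weights: np.ndarray) -> str:
    return categories[rng.choice(len(categories), p=weights)]


def simulate_reads(
    config: SimulationConfig,
    genes: Sequence[TRNAGeneRecord],
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Draw labelled reads for every sample.

    Each read: class ~ class_mix; gene ~ category abundance; length ~ the
    class/category length distribution; sequence = the anchored slice its
    class dictates (3' fragments append CCA with probability ``cca_prob``);
    decoys are random sequence rejection-sampled against every anchor
    lookup. The sequencing adapter is appended and the read truncated to
    the machine read length, with random fill when the insert+adapter fall
    short. Returns ``{sample_id: [(read_id, sequence), ...]}`` and a
    ground-truth table with one row per read.
    """
    window = (min(config.trf3_length_range[0], config.trf1_length_range[0],
                  config.decoy_length_range[0], 15), 45)
    ref = build_reference(genes, config.flank_len, read_len_window=window)

    by_cat: dict[str, list[TRNAGeneRecord]] = {}
    for g in genes:
        by_cat.setdefault(g.amino_acid, []).append(g)
    categories = sorted(by_cat)
    cat_w = np.array([config.category_weights.get(c, 1.0) for c in categories])
    cat_w = cat_w / cat_w.sum()

    class_names = sorted(config.class_mix)
    class_p = np.array([config.class_mix[c] for c in class_names])

    samples: dict[str, list[tuple[str, str]]] = {}
    truth_rows: list[dict] = []
    for s_idx in range(config.n_samples):
        sample_id = f"sample{s_idx + 1}"
        rng = np.random.default_rng([config.seed, 7919, s_idx])
        reads: list[tuple[str, str]] = []
        for r_idx in range(config.n_reads):
            cls = class_names[rng.choice(len(class_names), p=class_p)]
            insert, gene = _draw_insert(rng, cls, config, by_cat, categories,
                                        cat_w, ref)
            read = insert + config.adapter
            if len(read) < config.machine_read_len:
                read += _random_seq(rng, config.machine_read_len - len(read))
            read = read[:config.machine_read_len]
            if config.error_rate > 0:
                read = _mutate(rng, read, config.error_rate)
            read_id = f"{sample_id}.{r_idx + 1}"
            reads.append((read_id, read))
            truth_rows.append({
                "sample_id": sample_id, "read_id": read_id,
                "true_class": cls,
                "true_gene": gene.gene_id if gene else "",
                "true_amino_acid": gene.amino_acid if gene else "",
                "true_length": len(insert),
                "true_mitochondrial": bool(gene.mitochondrial) if gene else False,
            })
        samples[sample_id] = reads
    return samples, pd.DataFrame(truth_rows)


def _draw_insert(rng, cls, config, by_cat, categories, cat_w, ref
                 ) -> tuple[str, TRNAGeneRecord | None]:
    if cls == DECOY:
        lo, hi = config.decoy_length_range
        for _ in range(100):
            seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            if not (ref.match_prefix(seq) or any(ref.match_suffix(seq))
                    or ref.match_flank_prefix(seq)):
                return seq, None
        raise RuntimeError("could not draw a non-matching decoy in 100 attempts")

    category = _draw_category(rng, categories, cat_w)
    gene = by_cat[category][rng.integers(len(by_cat[category]))]
    if cls == TRF5:
        dist = config.trf5_length_dist.get(
            category, {ln: 0.2 for ln in range(30, 35)})
        lengths = sorted(dist)
        p = np.array([dist[ln] for ln in lengths])
        p = p / p.sum()
        for _ in range(50):
            ln = lengths[rng.choice(len(lengths), p=p)]
            if ln <= len(gene.mature_seq):
                return gene.mature_seq[:ln], gene
        raise RuntimeError("5' fragment length draw kept exceeding the "
                           "mature length")
    if cls == TRF3:
        lo, hi = config.trf3_length_range
        ln = int(rng.integers(lo, hi + 1))
        if rng.random() < config.cca_prob:
            return (gene.mature_seq + "CCA")[-ln:], gene
        return gene.mature_seq[-ln:], gene
    if cls == TRF1:
        lo, hi = config.trf1_length_range
        ln = min(int(rng.integers(lo, hi + 1)), len(gene.flank3))
        return gene.flank3[:ln], gene
    raise ValueError(f"unknown read class {cls!r}")


def _mutate(rng, read: str, rate: float) -> str:
    out = list(read)
    for i in range(len(out)):
        if rng.random() < rate:
            alternatives = [b for b in "ACGT" if b != out[i]]
            out[i] = alternatives[rng.integers(3)]
    return "".join(out)


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def dataset_checksum(samples: Mapping[str, list[tuple[str, str]]]) -> str:
    """Stable digest of a simulated read set, for determinism checks."""
    h = hashlib.sha256()
    for sample_id in sorted(samples):
        for read_id, seq in samples[sample_id]:
            h.update(f"{sample_id}\t{read_id}\t{seq}\n".encode())
    return h.hexdigest()
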