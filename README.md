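# trfseq

Classification and quantification of circulating tRNA-derived RNA
fragments (tRFs) from small-RNA sequencing data, built around the fragment
taxonomy used for serum profiling in cattle:

- **tRF5** — a read that aligns perfectly to the 5' end of a mature tRNA;
- **tRF3** — a read that aligns perfectly to the 3' end of a mature tRNA,
  with or without the post-transcriptionally added CCA tail;
- **tRF1** — a read that aligns perfectly to the start of the 3' trailer,
  the genomic flank immediately downstream of the mature tRNA.

The package is for researchers profiling circulating small non-coding RNA
who want reproducible tRF calls without a heavyweight aligner: matching is
anchored and exact (no mismatches, no gaps), which makes the
classification rule auditable and the counts deterministic.

## What it does

1. **Reference building** — parse tRNA gene FASTA with
   gtRNAdb-style headers (`tRNA-His-GTG-1-1`), excise annotated introns,
   attach 40-bp genomic flanks on both sides (strand-aware), and index
   every anchored substring for O(read-length) lookup.
2. **Preprocessing** — clip the 3' sequencing adapter (seeded scan,
   1 mismatch tolerated), keep reads of 18–40 nt, and collapse identical
   reads into (sequence, multiplicity) pairs.
3. **Classification** — assign each unique read a class by anchored exact
   matching, precedence tRF5 > tRF3 > tRF1; reads hitting genes of
   different amino-acid categories are labelled ambiguous; unmatched reads
   (other small ncRNAs, errors) fall into an unclassified sink.
4. **Quantification** — aggregate counts per (class, amino acid, length),
   normalize per sample by `raw * mean library size / sample library
   size`, and emit category × length and category × sample tables with
   recomputed margins.
5. **Statistics** — Pearson correlations of normalized tRF5 totals against
   codon counts and tRNA gene counts over the 21 amino-acid categories
   (20 standard + Stop), with exact-t p-values; length-window proportions
   and dominance ratios.
6. **Simulation** — a seeded generator producing tRNA genes embedded in a
   toy genome and adapter-bearing labelled reads (tRF5/tRF3±CCA/tRF1 plus
   non-tRNA decoys), so the whole pipeline can be validated against known
   ground truth.

## Worked example

```sh
# simulate a labelled 3-sample dataset
trfseq simulate --seed 5 --n-samples 3 --n-reads 800 --out-dir sim/

# run the full pipeline on it
trfseq run --trna-fasta sim/trna_genes.fasta --genome-fasta sim/genome.fasta \
           --fastq 'sim/sample*.fastq' --out-dir out/
```

`out/` then contains per-sample call tables, the three count tables, the
correlation report and `summary.json`. Recomputing the survey statistics
from the bundled published count tables:

```sh
trfseq reproduce-paper-stats
```

prints (abridged):

```json
{
  "trf5_grand_total": 2323520,
  "proportion_30_34": 0.9873954172978928,
  "proportion_31": 0.27612458683376945,
  "his_dominance_ratio": 4.618049065420561,
  "correlation_codons_vs_trf5": {"r": -0.1229, "n": 21, "p": 0.5956},
  "correlation_genes_vs_trf5": {"r": 0.3944, "n": 21, "p": 0.0769},
  "trf3_total": 562,
  "trf3_per_animal_mean": 70.25,
  "trf3_per_animal_range": [41, 107]
}
```

Reading this: 2,323,520 serum tRF5s in total; 98.7% of them 30–34 nt long
with 27.6% at exactly 31 nt; the dominant His fragment length (34 nt)
outnumbers the runner-up 4.6-fold; and tRF5 abundance per amino acid is
essentially uncorrelated with how often the amino acid is encoded
(r = −0.12, p = 0.60) and only weakly associated with tRNA gene copy
number (r = 0.39, p = 0.08).

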