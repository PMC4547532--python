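# Methods

## The classification model

A tRNA-derived fragment is identified purely by where it anchors on a
tRNA gene, under three rules applied to each read with **no mismatches
tolerated**:

- **tRF5**: the read equals a prefix of a mature tRNA sequence.
- **tRF3**: the read equals a suffix of a mature tRNA, either as
  genomically encoded or with the enzymatically added `CCA` tail appended.
  Only the two named terminal forms are accepted by default; partial
  `C`/`CC` tails can be admitted with `allow_partial_cca=True`.
- **tRF1**: the read equals a prefix of the 3' trailer — the 40-bp genomic
  flank immediately downstream of the mature tRNA, the sequence released
  when the precursor's 3' extension is cleaved.

Rules are tested in the precedence order tRF5 > tRF3 > tRF1. A read that
satisfies more than one rule (possible for short reads over repeated
sequence) takes the first class, and the event is counted in a per-sample
conflict tally rather than silently discarded. Reads matching no anchor —
other small ncRNAs, degradation products, sequencing errors — fall into an
explicit unclassified sink; this replaces a genome-wide alignment
pre-filter with a direct statement of the same outcome (tRF or not-tRF).

The mature sequence is stored without the CCA tail (it is
post-transcriptional and absent from the genome); the CCA-bearing 3'
forms are synthesized when the lookup index is built. Annotated introns
are excised by default before indexing, since fragments come from the
processed tRNA; `remove_introns=False` keeps the gene sequence as-is for
references that pre-splice their entries.

Matching is implemented as exhaustive substring-to-gene dictionaries: for
every gene, every anchored substring with length inside the read-length
window (15–45 nt by default) is enumerated once at build time, making
each read a handful of O(read-length) hash lookups. For the gene sets
this is designed for (hundreds of genes × ≤45-nt anchors) the index is a
few MB; correctness is cross-checked in the test suite against a
brute-force per-gene scan.

### Label resolution

- A read matching several genes of one amino-acid category is counted
  once under that category (per-read, not per-hit, counting).
- A read matching genes of *different* categories keeps its class but is
  labelled `ambiguous`; it is excluded from per-category tables and
  reported separately, so category tables are never inflated by
  cross-category repeats.
- A read matching both nuclear and mitochondrial genes takes the nuclear
  label and the conflict is counted. Mitochondrial hits otherwise keep
  their flag and can be reported merged into the shared categories or as
  separate `mt-` rows.

## Preprocessing

The 3' sequencing adapter is clipped at the leftmost position where an
adapter prefix of at least `min_overlap = 7` nt matches with at most
`max_mismatches = 1`; the defaults are deliberately conservative seeds
for a 21-nt adapter (NEBNext small-RNA 3' SR adapter by default,
configurable). Reads of 18–40 nt (inclusive) are kept; identical reads
are collapsed to (sequence, multiplicity) pairs. Quality values are read
and ignored: no quality trimming is performed, because exact-match
classification already rejects miscalled fragments, and reads containing
`N` are kept for the same reason.

## Quantification and normalization

Counts accumulate per (class, amino acid, fragment length,
mitochondrial) cell. Normalized counts are
`raw × mean library size / sample library size`; the library size is the
sample's total classified tRF count by default (switchable to total
length-pass reads), so in the default mode every normalized sample total
equals the mean library size exactly. Normalized values are kept as
reals internally and rounded half-up only when tables are written.

Tables fix the 21 category rows (20 amino acids plus Stop, which
aggregates selenocysteine/suppressor tRNAs) so zero categories are
explicit. Margins — totals, means, proportions — are always recomputed
from cells and never stored; this is what resolves the two arithmetic
slips in the transcribed published tables (one row total, one column
total) in favour of their cells. The headline length table is reported
over 28–40 nt, the range that carries virtually all observed fragments;
columns below 0.2% of the grand total can be masked for presentation and
the full filtered window (18–40 nt) is always available.

## Correlations

Pearson r between normalized tRF5 totals and (a) codon counts per amino
acid under the standard genetic code (Stop = 3), (b) tRNA gene counts per
category, over all 21 categories including zero-count ones — that census
is what reproduces the published coefficients (r = 0.39 for gene counts,
r = −0.12 for codons). Two-sided p-values use the exact t transform
`t = r·sqrt(n−2)/sqrt(1−r²)` with n−2 degrees of freedom; at n = 21 a
normal approximation would be visibly off. The computation is delegated
to `scipy.stats.pearsonr` (which implements exactly this test) behind the
package's `pearson` interface; a brute-force covariance oracle in the
test suite pins the equivalence to 1e-12.

## The simulator

The generator emulates the structure the pipeline assumes, with
ground-truth labels for every read:

- **Reference**: 2 genes per category (plus mitochondrial Val and Tyr
  genes on their own contig), mature lengths uniform on 70–95 nt,
  embedded on alternating strands of a random genome with 60-nt spacers
  (longer than the 40-nt flank, so trailers never overlap a neighbour).
  Rejection sampling keeps every gene's first and last 18 nt pairwise
  distinct, so fragment provenance is unambiguous; an opt-in ambiguity
  injection forces one cross-category pair to share a 30-nt prefix to
  exercise the ambiguous path.
- **Reads**: class ∼ {tRF5: 0.90, tRF3: 0.005, tRF1: 0.005, decoy: 0.09},
  echoing the observed dominance of 5' fragments in serum with decoys
  standing in for the other small ncRNAs a real library contains; gene ∼
  per-category weights proportional to the published per-animal totals
  plus a pseudocount; tRF5 length ∼ the per-category empirical
  distribution fitted from the published length table (His bimodal at
  31/34 nt, Glu modal at 31 nt, zero rows uniform on 30–34); tRF3 appends
  CCA with probability 0.5 (both terminal forms are observed and no
  relative frequency is reported, so they are drawn evenly); tRF3/tRF1
  lengths uniform on 18–25 / 18–30 nt. Decoys are random sequence
  rejection-sampled against every anchor lookup, so by construction they
  must end unclassified. The adapter is appended and the read truncated
  to a 50-nt machine read length (a 50-cycle kit), so most inserts carry
  a partial adapter and clipping is exercised realistically.
- **Determinism**: one RNG stream per sample derived from (seed, sample
  index); a fixed seed reproduces FASTQ output byte for byte, and samples
  are individually reproducible.
- No sequencing-error model by default; an optional uniform substitution
  rate exists to demonstrate how exact-match classification degrades with
  errors. Quality strings are constant placeholders.

### What passing on synthetic data does and does not show

Error-free synthetic reads with unambiguous provenance are recovered at
100% by construction of the rules — that validates the implementation
(anchoring, CCA handling, conservation, normalization algebra), not the
biology. Real serum libraries contain sequencing errors, RT artefacts,
modified bases that terminate reverse transcription, and genuinely
ambiguous repeat-derived fragments; on such data exact matching
undercounts rather than misassigns, and the unclassified and ambiguous
tallies are the honest place that loss shows up. The simulator also does
not model quality-score structure, platform error profiles, or tRNA
modification chemistry.

## Problem sizes and numerical choices

The bundled count tables are used exactly as printed (cells only). The
validation suite runs the classifier-vs-oracle comparison on 10,000
random reads against a 20-gene reference and the end-to-end recovery
check on 10,000 error-free reads; the acceptance script simulates 8
samples × 10,000 reads — about a sixtieth of the real per-animal depth,
chosen because every property checked is exact (equality, conservation)
rather than asymptotic, so extra depth adds runtime but no information.
Ties in dominance ratios are not broken: the ratio uses the two largest
cells whatever their positions. Degenerate inputs fail loudly: empty
gene lists, constant correlation vectors, zero library sizes and all-zero
tables raise instead of returning NaN.

## Known limitations

- Internal fragments (tRF-halves, i-tRFs) are out of scope; reads from
  the interior of a tRNA are unclassified by design.
- Exact matching means a single sequencing error drops a read; counts
  are conservative and error-rate-dependent.
- The "Stop" category mixes selenocysteine and suppressor tRNAs, which
  is the convention of the tables this package reproduces.
- Library size is defined on classified reads by default; comparisons
  with pipelines that normalize on total reads should switch
  `library_size_mode` to `all`.
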