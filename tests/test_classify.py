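import numpy as np
import pytest

from trfseq.classify import (TRF1, TRF3, TRF5, UNCLASSIFIED, classify_read,
                             classify_sample)
from trfseq.preprocess import collapse_unique
from trfseq.reference import build_reference
from trfseq.simulate import SimulationConfig, simulate_reference

from conftest import make_gene


def brute_force_classify(seq, genes, window=(15, 45)):
    """Independent oracle: scan every gene, test anchored membership directly."""
    lo, hi = window
    if not lo <= len(seq) <= hi:
        return UNCLASSIFIED, set()
    trf5 = {g.gene_id for g in genes if g.mature_seq.startswith(seq)}
    trf3 = {g.gene_id for g in genes
            if g.mature_seq.endswith(seq) or (g.mature_seq + "CCA").endswith(seq)}
    trf1 = {g.gene_id for g in genes if g.flank3.startswith(seq)}
    for cls, ids in ((TRF5, trf5), (TRF3, trf3), (TRF1, trf1)):
        if ids:
            return cls, ids
    return UNCLASSIFIED, set()


class TestClassifyRead:
    def test_trf5_prefix(self, toy_gene, toy_reference):
        call = classify_read(toy_gene.mature_seq[:31], toy_reference)
        assert (call.trf_class, call.amino_acid, call.length) == (TRF5, "His", 31)
        assert call.cca_status == "not_applicable"

    def test_trf3_with_cca(self, toy_gene, toy_reference):
        read = (toy_gene.mature_seq + "CCA")[-22:]
        call = classify_read(read, toy_reference)
        assert (call.trf_class, call.length, call.cca_status) == (TRF3, 22, "full_CCA")

    def test_trf3_without_cca(self, toy_gene, toy_reference):
        call = classify_read(toy_gene.mature_seq[-19:], toy_reference)
        assert (call.trf_class, call.cca_status) == (TRF3, "none")

    def test_trf1_flank_prefix(self, toy_gene, toy_reference):
        call = classify_read(toy_gene.flank3[:20], toy_reference)
        assert (call.trf_class, call.length) == (TRF1, 20)

    def test_internal_slice_unclassified(self, toy_gene, toy_reference):
        call = classify_read(toy_gene.mature_seq[5:35], toy_reference)
        assert call.trf_class == UNCLASSIFIED

    def test_single_mismatch_unclassified(self, toy_gene, toy_reference):
        read = list(toy_gene.mature_seq[:31])
        read[15] = {"A": "C"}.get(read[15], "A")
        assert classify_read("".join(read), toy_reference).trf_class == UNCLASSIFIED

    def test_precedence_trf5_over_trf3(self):
        # contrived repeat: the read is both a prefix of one gene and a
        # suffix of another
        seq = "ACGTTGCA" * 5
        a = make_gene(gene_id="a", mature=seq[:20] + "G" * 52)
        b = make_gene(gene_id="b", amino_acid="Glu",
                      mature="G" * 52 + seq[:20])
        ref = build_reference([a, b])
        call = classify_read(seq[:20], ref)
        assert call.trf_class == TRF5
        assert call.gene_ids == ["a"]
        assert call.rule_conflict is True

    def test_cross_category_hit_is_ambiguous(self):
        shared = "ACGTGGCTAGCTAGGATCCA"
        a = make_gene(gene_id="a", amino_acid="His", mature=shared + "A" * 50)
        b = make_gene(gene_id="b", amino_acid="Glu", mature=shared + "C" * 50)
        ref = build_reference([a, b])
        call = classify_read(shared, ref)
        assert call.trf_class == TRF5
        assert call.amino_acid == "ambiguous"
        assert call.gene_ids == ["a", "b"]

    def test_nuclear_label_wins_over_mitochondrial(self):
        shared = "ACGTGGCTAGCTAGGATCCA" + "A" * 50
        nuc = make_gene(gene_id="nuc", mature=shared)
        mito = make_gene(gene_id="mt", mature=shared, mitochondrial=True)
        ref = build_reference([nuc, mito])
        call = classify_read(shared[:25], ref)
        assert call.mitochondrial is False
        assert call.nuc_mito_conflict is True

    def test_gene_ids_independent_of_reference_order(self, sim_dataset):
        _, genes, _, _, _ = sim_dataset
        fwd = build_reference(genes)
        rev = build_reference(list(reversed(genes)))
        read = genes[5].mature_seq[:30]
        assert classify_read(read, fwd) == classify_read(read, rev)


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_reads(self, sim_dataset):
        """Anchored-index classification agrees with direct per-gene scanning
        on every read type: true fragments, perturbations, random sequence."""
        _, genes, _, _, _ = sim_dataset
        genes = genes[:20]
        ref = build_reference(genes, read_len_window=(15, 45))
        rng = np.random.default_rng(2024)
        reads = []
        for _ in range(1500):
            g = genes[rng.integers(len(genes))]
            ln = int(rng.integers(15, 46))
            kind = rng.integers(5)
            if kind == 0:
                reads.append(g.mature_seq[:ln])
            elif kind == 1:
                reads.append((g.mature_seq + "CCA")[-ln:])
            elif kind == 2:
                reads.append(g.flank3[:ln])
            elif kind == 3:  # corrupted fragment
                base = list(g.mature_seq[:ln])
                base[rng.integers(len(base))] = "ACGT"[rng.integers(4)]
                reads.append("".join(base))
            else:
                reads.append("".join(rng.choice(list("ACGT"), size=ln)))
        for read in reads:
            want_cls, want_ids = brute_force_classify(read, genes)
            call = classify_read(read, ref)
            assert call.trf_class == want_cls, read
            assert set(call.gene_ids) == want_ids, read


class TestClassifySample:
    def test_count_conservation(self, toy_gene, toy_reference):
        reads = ([toy_gene.mature_seq[:31]] * 3
                 + [toy_gene.flank3[:20]] * 2
                 + ["TTTTGGGGCCCCAAAATTTT"] * 4)
        sc = classify_sample(collapse_unique(reads, "s"), toy_reference)
        assert sc.classified_total + sc.unclassified == sc.total_pass == 9
        assert sc.class_total(TRF5) == 3
        assert sc.class_total(TRF1) == 2
        assert sc.unclassified == 4

    def test_empty_read_set(self, toy_reference):
        sc = classify_sample(collapse_unique([], "s"), toy_reference)
        assert sc.cells == {} and sc.unclassified == 0

    def test_read_matching_two_genes_counted_once(self):
        a = make_gene(gene_id="a", amino_acid="Glu")
        b = make_gene(gene_id="b", amino_acid="Glu")
        ref = build_reference([a, b])
        sc = classify_sample(collapse_unique([a.mature_seq[:25]], "s"), ref)
        assert sc.classified_total == 1
        assert sc.cells == {(TRF5, "Glu", 25, False): 1}

    def test_library_size_modes(self, toy_gene, toy_reference):
        reads = [toy_gene.mature_seq[:31], "TTTTGGGGCCCCAAAATTTT"]
        urs = collapse_unique(reads, "s")
        assert classify_sample(urs, toy_reference).library_size == 1
        assert classify_sample(urs, toy_reference,
                               library_size_mode="all").library_size == 2
        with pytest.raises(ValueError):
            classify_sample(urs, toy_reference, library_size_mode="bogus")

    def test_ground_truth_recovery_on_simulated_sample(self, sim_dataset):
        from trfseq.preprocess import preprocess_reads
        cfg, genes, _, samples, truth = sim_dataset
        ref = build_reference(genes)
        sid = "sample1"
        urs, _ = preprocess_reads([seq for _, seq in samples[sid]], sid,
                                  adapter=cfg.adapter)
        sc = classify_sample(urs, ref)
        tt = truth[truth.sample_id == sid]
        want = tt[tt.true_class != "decoy"].groupby("true_class").size()
        for cls in (TRF5, TRF3, TRF1):
            assert sc.class_total(cls) == want.get(cls, 0)
        assert sc.unclassified == (tt.true_class == "decoy").sum()
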