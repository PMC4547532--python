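import pytest

from trfseq.classify import SampleCounts
from trfseq.reference import TRNAGeneRecord, attach_flanks, build_reference
from trfseq.simulate import SimulationConfig, simulate_reads, simulate_reference


def make_gene(gene_id="tRNA-His-GTG-1-1", amino_acid="His", mature=None,
              **kwargs):
    mature = mature or ("GCCGTGATCGTATAGTGGTTAGTACTCTGCGTTGTGGCCGCAGCAACC"
                        "TCGGTTCGAATCCGAGTCACGGCA")
    defaults = dict(anticodon="GTG", contig="chr1", start=100,
                    end=100 + len(mature), strand="+")
    defaults.update(kwargs)
    return TRNAGeneRecord(gene_id=gene_id, amino_acid=amino_acid,
                          mature_seq=mature, **defaults)


@pytest.fixture
def toy_genome():
    import numpy as np
    rng = np.random.default_rng(42)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=400))}


@pytest.fixture
def toy_gene(toy_genome):
    g = make_gene()
    toy = toy_genome["chr1"]
    # embed the mature sequence so flank extraction is self-consistent
    toy_genome["chr1"] = toy[:100] + g.mature_seq + toy[100 + len(g.mature_seq):]
    return attach_flanks(g, toy_genome)


@pytest.fixture
def toy_reference(toy_gene):
    return build_reference([toy_gene], read_len_window=(15, 45))


@pytest.fixture(scope="session")
def sim_dataset():
    """Small error-free dataset with decoys, shared across tests."""
    cfg = SimulationConfig(seed=7, n_samples=2, n_reads=2000)
    genes, genome = simulate_reference(cfg)
    samples, truth = simulate_reads(cfg, genes)
    return cfg, genes, genome, samples, truth


def sample_counts_from_cells(sample_id, cells, unclassified=0,
                             library_size=None):
    sc = SampleCounts(sample_id=sample_id, cells=dict(cells),
                      unclassified=unclassified)
    sc.total_pass = int(sum(cells.values())) + unclassified
    sc.library_size = (sc.classified_total if library_size is None
                       else library_size)
    return sc
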