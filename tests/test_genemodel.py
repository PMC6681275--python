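"""Gene-structure I/O, CDS assembly, introns and TIS coordinates."""

import numpy as np
import pytest

from microtrace import (
    FormatError,
    GeneModel,
    GenomicSequence,
    InvariantError,
    assemble_cds,
    introns_of,
    read_fasta,
    read_gff3,
    to_tis,
    write_fasta,
    write_gff3,
)
from microtrace.genemodel import reverse_complement


# -- FASTA -------------------------------------------------------------------


def test_read_fasta_minimal_record(tmp_path):
    p = tmp_path / "f.fa"
    p.write_text(">g1\nacgt\n")
    recs = read_fasta(p)
    assert len(recs) == 1
    assert recs[0].id == "g1"
    assert recs[0].residues == "ACGT"  # upper-cased


def test_read_fasta_preserves_record_order(tmp_path):
    p = tmp_path / "f.fa"
    p.write_text(">b\nAC\n>a\nGT\n>c\nNN\n")
    assert [r.id for r in read_fasta(p)] == ["b", "a", "c"]


def test_read_fasta_rejects_rna_alphabet(tmp_path):
    p = tmp_path / "f.fa"
    p.write_text(">g1\nACGU\n")
    with pytest.raises(FormatError):
        read_fasta(p)


def test_read_fasta_rejects_empty_record(tmp_path):
    p = tmp_path / "f.fa"
    p.write_text(">g1\n>g2\nACGT\n")
    with pytest.raises(FormatError):
        read_fasta(p)


def test_fasta_round_trip(tmp_path):
    seqs = [GenomicSequence("x", "ACGTN" * 30, "a test"), GenomicSequence("y", "TTTT")]
    p = tmp_path / "rt.fa"
    write_fasta(seqs, p)
    back = read_fasta(p)
    assert [(s.id, s.residues) for s in back] == [(s.id, s.residues) for s in seqs]


# -- GFF3 --------------------------------------------------------------------


def _gff(body: str) -> str:
    return "##gff-version 3\n" + body


def test_read_gff3_single_exon_plus(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text(
        _gff(
            "chr1\t.\tgene\t1\t30\t.\t+\t.\tID=g1\n"
            "chr1\t.\tmRNA\t1\t30\t.\t+\t.\tID=g1.t1;Parent=g1\n"
            "chr1\t.\texon\t1\t30\t.\t+\t.\tParent=g1.t1\n"
        )
    )
    (gene,) = read_gff3(p)
    assert gene.exons == [(0, 30)]
    assert gene.strand == "+"


def test_read_gff3_minus_strand_reverses_exon_order(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text(
        _gff(
            "chr1\t.\tgene\t1\t100\t.\t-\t.\tID=g1\n"
            "chr1\t.\tmRNA\t1\t100\t.\t-\t.\tID=g1.t1;Parent=g1\n"
            "chr1\t.\texon\t1\t40\t.\t-\t.\tParent=g1.t1\n"
            "chr1\t.\texon\t61\t100\t.\t-\t.\tParent=g1.t1\n"
        )
    )
    (gene,) = read_gff3(p)
    # coding order: downstream-most genomic interval first on the minus strand
    assert gene.exons == [(60, 100), (0, 40)]


def test_read_gff3_overlapping_exons_rejected(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text(
        _gff(
            "chr1\t.\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "chr1\t.\texon\t1\t50\t.\t+\t.\tParent=g1\n"
            "chr1\t.\texon\t40\t100\t.\t+\t.\tParent=g1\n"
        )
    )
    with pytest.raises(InvariantError):
        read_gff3(p)


def test_read_gff3_exon_outside_gene_span_rejected(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text(
        _gff(
            "chr1\t.\tgene\t10\t50\t.\t+\t.\tID=g1\n"
            "chr1\t.\texon\t1\t50\t.\t+\t.\tParent=g1\n"
        )
    )
    with pytest.raises(FormatError):
        read_gff3(p)


def test_read_gff3_missing_strand_rejected(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text(
        _gff(
            "chr1\t.\tgene\t1\t30\t.\t.\t.\tID=g1\n"
            "chr1\t.\texon\t1\t30\t.\t.\t.\tParent=g1\n"
        )
    )
    with pytest.raises(FormatError):
        read_gff3(p)


def test_read_gff3_empty_file_yields_no_genes(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text("##gff-version 3\n")
    assert read_gff3(p) == []


def test_gff3_round_trip_is_bit_exact(tmp_path, micro_gene):
    _, gene, _ = micro_gene
    p = tmp_path / "rt.gff3"
    write_gff3([gene], p)
    (back,) = read_gff3(p)
    assert back.exons == gene.exons
    assert back.cds_start_offset == gene.cds_start_offset
    assert back.strand == gene.strand
    assert back.seq_id == gene.seq_id
    # writing again reproduces the same bytes
    p2 = tmp_path / "rt2.gff3"
    write_gff3([back], p2)
    assert p.read_bytes() == p2.read_bytes()


# -- CDS assembly ------------------------------------------------------------


def test_assemble_cds_two_exons():
    genome = GenomicSequence("c", "ATGAA" + "GTAAAG" + "TGA")
    gene = GeneModel("g", "c", "+", [(0, 5), (11, 14)])
    assert assemble_cds(gene, genome) == "ATGAATGA"


def test_assemble_cds_strand_symmetry():
    genome = GenomicSequence("c", "ATGAA" + "GTAAAG" + "TGA")
    plus = GeneModel("g", "c", "+", [(0, 5), (11, 14)])
    rc = GenomicSequence("c", reverse_complement(genome.residues))
    n = len(genome.residues)
    minus = GeneModel("g", "c", "-", [(n - 5, n), (n - 14, n - 11)])
    assert assemble_cds(minus, rc) == assemble_cds(plus, genome)


@pytest.mark.parametrize("seed", range(5))
def test_assemble_cds_matches_slice_and_join_oracle(seed):
    rng = np.random.default_rng(seed)
    residues = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
    genome = GenomicSequence("c", residues)
    exons = [(10, 40), (60, 95), (120, 200)]
    offset = int(rng.integers(0, 30))
    plus = GeneModel("g", "c", "+", exons, offset)
    oracle = "".join(residues[s:e] for s, e in exons)[offset:]
    assert assemble_cds(plus, genome) == oracle
    minus = GeneModel(
        "g", "c", "-", [(300 - e, 300 - s) for s, e in exons], offset
    )
    rc = GenomicSequence("c", reverse_complement(residues))
    assert assemble_cds(minus, rc) == oracle


def test_assemble_cds_length_identity(trace_gene):
    genome, gene, _ = trace_gene
    assert len(assemble_cds(gene, genome)) == gene.exonic_length - gene.cds_start_offset


def test_assemble_cds_rejects_out_of_range_exon():
    genome = GenomicSequence("c", "ACGT")
    gene = GeneModel("g", "c", "+", [(0, 10)])
    with pytest.raises(Exception):
        assemble_cds(gene, genome)


# -- introns -----------------------------------------------------------------


def test_introns_of_interval_and_dinucleotides():
    genome = GenomicSequence("c", "AAAAA" + "GTAAG" + "TTTTT")
    gene = GeneModel("g", "c", "+", [(0, 5), (10, 15)])
    (intron,) = introns_of(gene, genome)
    assert (intron.start, intron.end) == (5, 10)
    assert intron.donor_dinuc == "GT"
    assert intron.acceptor_dinuc == "AG"


def test_single_exon_gene_has_no_introns():
    genome = GenomicSequence("c", "ATGTGA")
    gene = GeneModel("g", "c", "+", [(0, 6)])
    assert introns_of(gene, genome) == []


def test_intron_count_and_complement_tiling(micro_gene):
    genome, gene, _ = micro_gene
    introns = introns_of(gene, genome)
    assert len(introns) == gene.n_exons - 1
    # introns tile exactly the complement of exons within the gene span
    lex = gene.local_exons()
    covered = sorted(lex + [(i.local_start, i.local_end) for i in introns])
    assert covered[0][0] == 0
    for (s1, e1), (s2, e2) in zip(covered, covered[1:]):
        assert e1 == s2
    lo, hi = gene.span
    assert covered[-1][1] == hi - lo


# -- TIS coordinates ---------------------------------------------------------


@pytest.fixture
def tis_gene():
    # exon1 (0,9) with ATG at local 2, intron (9,14), exon2 (14,22)
    genome = GenomicSequence("c", "AAATGAAAA" + "GTCAG" + "CCCCCCCC")
    return genome, GeneModel("g", "c", "+", [(0, 9), (14, 22)], cds_start_offset=2)


def test_tis_of_atg_is_plus_one(tis_gene):
    _, gene = tis_gene
    assert int(to_tis(gene, 2)) == 1


def test_tis_has_no_zero(tis_gene):
    _, gene = tis_gene
    assert int(to_tis(gene, 1)) == -1


def test_tis_counts_intronic_nucleotides(tis_gene):
    # the 10th nucleotide after the A of the ATG lies inside intron 1
    _, gene = tis_gene
    assert int(to_tis(gene, 12)) == 11


def test_tis_strictly_monotone_and_nonzero(trace_gene):
    _, gene, _ = trace_gene
    lo, hi = gene.span
    positions = range(lo, hi) if gene.strand == "+" else range(hi - 1, lo - 1, -1)
    values = [int(to_tis(gene, p)) for p in positions]
    assert 0 not in values
    assert all(b > a for a, b in zip(values, values[1:]))


# -- model invariants --------------------------------------------------------


def test_gene_model_rejects_overlapping_exons():
    with pytest.raises(InvariantError):
        GeneModel("g", "c", "+", [(0, 10), (5, 20)])


def test_gene_model_rejects_bad_strand():
    with pytest.raises(InvariantError):
        GeneModel("g", "c", ".", [(0, 10)])


def test_gene_model_rejects_offset_outside_chain():
    with pytest.raises(InvariantError):
        GeneModel("g", "c", "+", [(0, 10)], cds_start_offset=10)
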