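"""Trace scanning, exon-edge matching, locus classification and splice
variant enumeration."""

import numpy as np
import pytest
from Bio.Seq import Seq

from microtrace import (
    ABSENT,
    FUSED,
    INDEPENDENT,
    TRACE,
    GeneModel,
    GenomicSequence,
    Intron,
    ScanConfig,
    classify_locus,
    enumerate_splice_variants,
    match_exon_edge,
    reverse_translate,
    scan_gene,
    scan_intron_for_trace,
)

NT = np.array(list("ACGT"))


def _rand(rng, n):
    return "".join(NT[rng.integers(0, 4, n)])


# -- scan_intron_for_trace ---------------------------------------------------


def test_scanner_finds_the_junction_micro_exon():
    """An intron ending ...AG TCTATTTGG GT, with the upstream exon ending in
    G, yields exactly one 9-bp VYL-encoding candidate."""
    intron = Intron(1, 0, 37, "GT" + "A" * 20 + "AG" + "TCTATTTGG" + "GT")
    hits = scan_intron_for_trace(intron, "CAG", "GC", "VYL")
    assert len(hits) == 1
    (c,) = hits
    assert c.core_sequence == "TCTATTTGG"
    assert c.length == 9
    assert (c.phase_in, c.phase_out) == (1, 1)
    assert c.upstream_acceptor == "AG"
    assert c.downstream_donor == "GT"


def test_scanner_empty_on_featureless_intron():
    intron = Intron(1, 0, 40, "A" * 40)
    assert scan_intron_for_trace(intron, "AG", "GC", "VYL") == []


def test_scanner_respects_donor_set():
    # same trace but closed by GC: only found when GC is an allowed donor
    seq = "GT" + "A" * 20 + "AG" + "TCTATTTGG" + "GC" + "AAAG"
    intron = Intron(1, 0, len(seq), seq)
    assert scan_intron_for_trace(intron, "CAG", "GC", "VYL") == []
    hits = scan_intron_for_trace(
        intron, "CAG", "GC", "VYL", ScanConfig(donors=("GT", "GC"))
    )
    assert [c.downstream_donor for c in hits] == ["GC"]


def _naive_scan(intron_seq, up, down, motif, donors=("GT",), min_core=3, max_core=30):
    """Independent enumeration of every (window, phase) triple."""
    m = len(motif)
    found = []
    n = len(intron_seq)
    for i in range(2, n):
        if intron_seq[i - 2 : i] != "AG":
            continue
        for j in range(i + min_core, min(i + max_core, n - 2) + 1):
            if intron_seq[j : j + 2] not in donors:
                continue
            w = intron_seq[i:j]
            for a in (0, 1, 2):
                if a > len(up):
                    continue
                t = 3 * m - a
                if len(w) >= t and len(w) - t <= 2:
                    coding = (up[-a:] if a else "") + w[:t]
                elif 1 <= t - len(w) <= 2 and t - len(w) <= len(down):
                    coding = (up[-a:] if a else "") + w + down[: t - len(w)]
                else:
                    continue
                if "N" not in coding and str(Seq(coding).translate()) == motif:
                    found.append((i, j - i, a))
    return sorted(found)


@pytest.mark.parametrize("motif", ["VYL", "GCL"])
def test_scanner_equals_exhaustive_window_oracle(motif):
    rng = np.random.default_rng(hash(motif) % 2**31)
    for trial in range(25):
        n = int(rng.integers(80, 200))
        seq = list(_rand(rng, n))
        # salt with extra AG/GT and, half the time, a planted coding window
        for _ in range(6):
            p = int(rng.integers(0, n - 1))
            seq[p : p + 2] = "AG" if rng.integers(0, 2) else "GT"
        if trial % 2:
            coding = next(reverse_translate(motif).expansions())
            a = int(rng.integers(0, 3))
            p = int(rng.integers(4, n - 3 * len(motif) - 8))
            insert = "AG" + coding[a:] + "GT"
            seq[p : p + len(insert)] = insert
        seq = "".join(seq)[:n]
        up = _rand(rng, 3)
        if trial % 2:
            up = up[: 3 - a] + coding[:a] if a else up
        down = _rand(rng, 3)
        intron = Intron(1, 0, len(seq), seq)
        got = sorted(
            (c.offset_in_intron, c.length, c.phase_in)
            for c in scan_intron_for_trace(intron, up, down, motif)
        )
        assert got == _naive_scan(seq, up, down, motif)


def test_scanner_orders_hits_by_start_position(trace_gene):
    genome, gene, _ = trace_gene
    hits = scan_gene(gene, genome, "VYL")
    offsets = [(c.intron_index, c.offset_in_intron) for c in hits]
    assert offsets == sorted(offsets)


def test_candidate_tis_coordinates_match_truth(trace_gene):
    genome, gene, truth = trace_gene
    (c,) = scan_gene(gene, genome, "VYL")
    assert (c.core_start, c.core_end) == (truth.core_start, truth.core_end)
    assert c.core_sequence == truth.core_sequence


# -- match_exon_edge ---------------------------------------------------------


def test_edge_match_on_intron_loss_gene(fused_gene):
    genome, gene, _ = fused_gene
    pm = match_exon_edge(gene, genome, "VYL", "5prime", 2)
    assert pm is not None
    assert pm.phase_in == 1  # the upstream exon supplies the V codon's first nt


def test_edge_match_rejects_mid_exon_motif():
    # VYL is present but buried mid-exon: edge anchoring must not fire
    exon1 = "ATGAAA" + "GTCTATTTG" + "AAATAA"
    genome = GenomicSequence("c", exon1)
    gene = GeneModel("g", "c", "+", [(0, len(exon1))])
    assert match_exon_edge(gene, genome, "VYL", "5prime", 0) is None
    assert match_exon_edge(gene, genome, "VYL", "3prime", 0) is None


def test_edge_match_three_prime_with_borrow():
    # motif at the 3' end of exon 1; its last codon completed by exon 2
    e1 = "ATGAAA" + "GTCTATT"  # VYL coding minus its last 2 nt
    e2 = "TGAAATAA"
    genome = GenomicSequence("c", e1 + "GTAAAAAG" + e2)
    gene = GeneModel(
        "g", "c", "+", [(0, len(e1)), (len(e1) + 8, len(e1) + 8 + len(e2))]
    )
    pm = match_exon_edge(gene, genome, "VYL", "3prime", 0)
    assert pm is not None
    assert pm.phase_out == 1  # 2 nt borrowed from downstream -> end phase 1


def test_edge_match_absent_on_clean_gene(absent_gene):
    genome, gene, _ = absent_gene
    for k in range(gene.n_exons):
        for edge in ("5prime", "3prime"):
            assert match_exon_edge(gene, genome, "VYL", edge, k) is None


# -- classify_locus ----------------------------------------------------------


def test_classify_recovers_planted_micro(micro_gene):
    genome, gene, _ = micro_gene
    cls = classify_locus(gene, genome, "VYL")
    assert cls.state == INDEPENDENT
    assert not cls.warning


def test_classify_recovers_planted_fused(fused_gene):
    genome, gene, _ = fused_gene
    cls = classify_locus(gene, genome, "VYL")
    assert cls.state == FUSED
    assert cls.edge == "5prime"


def test_classify_recovers_planted_trace_with_diff(trace_gene):
    genome, gene, truth = trace_gene
    cls = classify_locus(gene, genome, "VYL")
    assert cls.state == TRACE
    assert cls.diff == truth.expected_diff == "VYL→GCL"
    assert cls.replacement_peptide == "GCL"


def test_classify_absent(absent_gene):
    genome, gene, _ = absent_gene
    cls = classify_locus(gene, genome, "VYL")
    assert cls.state == ABSENT
    assert not cls.candidates


def test_classify_restricts_to_replacement_list(trace_gene):
    genome, gene, _ = trace_gene
    assert classify_locus(gene, genome, "VYL", ["GCL"]).state == TRACE
    assert classify_locus(gene, genome, "VYL", ["VSA"]).state != TRACE


def test_conflicting_evidence_prefers_annotation_with_warning():
    """A gene carrying both an annotated micro-exon and an intronic trace is
    called independent, flagged."""
    e1 = "ATGCATG"  # ends mid-codon: phase 1 into the motif
    i1 = "GT" + "AAAAAA" + "AG" + "TCTATTTGG" + "GT" + "AAAAAA" + "AG"
    me = "TCTATTTGG"
    i2 = "GT" + "AAAAAAAA" + "AG"
    e3 = "GTTAA"
    s = e1 + i1 + me + i2 + e3
    genome = GenomicSequence("c", s)
    b1 = len(e1)
    b2 = b1 + len(i1)
    b3 = b2 + len(me)
    b4 = b3 + len(i2)
    gene = GeneModel("g", "c", "+", [(0, b1), (b2, b3), (b4, len(s))])
    cls = classify_locus(gene, genome, "VYL")
    assert cls.state == INDEPENDENT
    assert cls.warning
    assert cls.candidates  # the intronic trace is still reported as evidence


# -- enumerate_splice_variants ----------------------------------------------


def test_variants_restore_the_motif(trace_gene):
    genome, gene, _ = trace_gene
    cls = classify_locus(gene, genome, "VYL")
    variants = enumerate_splice_variants(gene, genome, cls)
    assert len(variants) >= 2
    ref = next(v for v in variants if v.is_reference)
    restored = [
        v for v in variants if not v.is_reference and v.diff_vs_reference == "GCL→VYL"
    ]
    assert len(restored) == 1
    assert ref.peptide.replace("GCL", "VYL", 1) == restored[0].peptide


def test_reference_only_when_no_candidates(absent_gene):
    genome, gene, _ = absent_gene
    cls = classify_locus(gene, genome, "VYL")
    variants = enumerate_splice_variants(gene, genome, cls)
    assert len(variants) == 1
    assert variants[0].is_reference
    assert variants[0].diff_vs_reference == "identical"


def test_emitted_variants_revalidate_under_donor_acceptor_rule(trace_gene):
    """Every new intron of every non-reference variant starts with a donor
    from the configured set and ends AG."""
    genome, gene, _ = trace_gene
    cfg = ScanConfig()
    cls = classify_locus(gene, genome, "VYL", config=cfg)
    variants = enumerate_splice_variants(gene, genome, cls, cfg)
    local = gene.local_sequence(genome)
    ref_gaps = {
        (e1, s2)
        for (_, e1), (s2, _) in zip(gene.local_exons(), gene.local_exons()[1:])
    }
    checked = 0
    for v in variants:
        if v.is_reference:
            continue
        for (_, e1), (s2, _) in zip(v.exon_chain, v.exon_chain[1:]):
            if (e1, s2) in ref_gaps:
                continue
            assert local[e1 : e1 + 2] in cfg.donors
            assert local[s2 - 2 : s2] == "AG"
            assert s2 - e1 >= 4
            checked += 1
    assert checked > 0


def test_frame_shifting_variants_are_flagged_not_dropped(trace_gene):
    genome, gene, _ = trace_gene
    cls = classify_locus(gene, genome, "VYL")
    variants = enumerate_splice_variants(gene, genome, cls)
    # the window may contain AG acceptors that shift the frame; those stay,
    # flagged as truncating
    shifted = [v for v in variants if v.has_internal_stop]
    for v in shifted:
        assert not v.is_reference
        assert len(v.peptide) < len(
            next(x for x in variants if x.is_reference).peptide
        )


def test_candidate_invariants_hold_on_emission(trace_gene):
    genome, gene, _ = trace_gene
    for c in scan_gene(gene, genome, "VYL"):
        assert c.upstream_acceptor == "AG"
        assert c.downstream_donor in ScanConfig().donors
        assert c.length <= ScanConfig().max_core
        assert c.encoded_motif == "VYL"
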