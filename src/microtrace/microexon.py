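"""Core micro-exon analysis.

Given an annotated gene, a genomic sequence and a peptide motif (e.g.
the conserved VYL of the first AP2 domain of WRI1-class transcription
factors), this module

* scans introns for a *trace* of a motif-coding micro-exon — a short
  window sandwiched between an AG acceptor and a GT (configurably GC)
  donor that, together with the flanking exon context and some codon
  phase, encodes the motif;
* matches the motif coding at annotated exon edges (the intron-loss
  configuration);
* classifies the locus into one of four evolutionary fates
  (independent micro-exon / fused exon edge / trace in intron / absent);
* enumerates the donor-AG-consistent splice variants implied by a trace,
  translating each and diffing its peptide against the annotation.

Splice plausibility is terminal dinucleotides only — no branch point or
polypyrimidine tract model — because that is exactly the enumerative
argument the analysis formalizes.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from .codonmap import (
    DegeneratePattern,
    PeptideMotif,
    PhasedMatch,
    match_phased,
    reverse_translate,
    translate,
)
from .errors import InvariantError
from .genemodel import GeneModel, GenomicSequence, Intron, introns_of, to_tis

# locus fate states
INDEPENDENT = "independent_micro_exon"
FUSED = "fused_exon_edge"
TRACE = "trace_in_intron"
ABSENT = "absent"

ACCEPTOR = "AG"


@dataclass(frozen=True)
class ScanConfig:
    """Tunable rules for the trace scan and variant enumeration.

    ``donors`` defaults to the canonical GT; add "GC" for the documented
    minor splice class.  ``max_core`` caps candidate length (micro-exon
    semantics).  ``acceptor_window`` bounds the alternative-acceptor
    search downstream of a candidate's donor.
    """

    donors: tuple[str, ...] = ("GT",)
    min_core: int = 3
    max_core: int = 30
    acceptor_window: int = 30

    def __post_init__(self) -> None:
        if not self.donors:
            raise InvariantError("at least one donor dinucleotide required")
        for d in self.donors:
            if len(d) != 2 or set(d) - set("ACGT"):
                raise InvariantError(f"invalid donor dinucleotide {d!r}")
        if not 1 <= self.min_core <= self.max_core:
            raise InvariantError("need 1 <= min_core <= max_core")
        if self.acceptor_window < 1:
            raise InvariantError("acceptor_window must be positive")


@dataclass(frozen=True)
class MicroExonCandidate:
    """An intronic window that can encode the motif as a spliced-in micro-exon."""

    gene_id: str
    intron_index: int
    offset_in_intron: int  # 0-based offset of the core within the intron
    core_sequence: str
    length: int
    phase_in: int
    phase_out: int
    upstream_acceptor: str
    downstream_donor: str
    encoded_motif: str
    core_start: int | None = None  # TIS coordinate of first core nucleotide
    core_end: int | None = None  # TIS coordinate of last core nucleotide
    local_start: int | None = None  # gene-local unspliced coordinates
    local_end: int | None = None

    def __post_init__(self) -> None:
        if self.upstream_acceptor != ACCEPTOR:
            raise InvariantError("candidate must be preceded by AG")
        if len(self.downstream_donor) != 2:
            raise InvariantError("donor must be a dinucleotide")
        if self.length != len(self.core_sequence):
            raise InvariantError("length/core_sequence mismatch")


def scan_intron_for_trace(
    intron: Intron,
    upstream_tail: str,
    downstream_head: str,
    motif: PeptideMotif | str,
    config: ScanConfig = ScanConfig(),
    gene_id: str = "",
    pattern: DegeneratePattern | None = None,
) -> list[MicroExonCandidate]:
    """Every AG-[core]-donor window in the intron that encodes the motif.

    A window qualifies when (i) the dinucleotide immediately 5' of it is
    AG, (ii) the dinucleotide immediately 3' of it is in the donor set,
    and (iii) some phase decomposition with the flanking exon context
    encodes the motif.  All hits are reported (one candidate per window
    and phase), ordered by start position; overlaps are not suppressed.
    """
    if isinstance(motif, str):
        motif = PeptideMotif(motif)
    if pattern is None:
        pattern = reverse_translate(motif)
    seq = intron.sequence
    n = len(seq)
    acceptor_ends = [i for i in range(2, n) if seq[i - 2 : i] == ACCEPTOR]
    donor_starts = sorted(
        j for j in range(n - 1) if seq[j : j + 2] in config.donors
    )
    out: list[MicroExonCandidate] = []
    for i in acceptor_ends:
        lo = bisect_left(donor_starts, i + config.min_core)
        hi = bisect_right(donor_starts, i + config.max_core)
        for j in donor_starts[lo:hi]:
            window = seq[i:j]
            for pm in match_phased(pattern, upstream_tail, window, downstream_head):
                out.append(
                    MicroExonCandidate(
                        gene_id=gene_id,
                        intron_index=intron.index,
                        offset_in_intron=i,
                        core_sequence=window,
                        length=j - i,
                        phase_in=pm.phase_in,
                        phase_out=pm.phase_out,
                        upstream_acceptor=ACCEPTOR,
                        downstream_donor=seq[j : j + 2],
                        encoded_motif=motif.residues,
                    )
                )
    out.sort(key=lambda c: (c.offset_in_intron, c.length, c.phase_in))
    return out


def _exon_seqs(gene: GeneModel, genome: GenomicSequence) -> list[str]:
    local = gene.local_sequence(genome)
    return [local[s:e] for s, e in gene.local_exons()]


def scan_gene(
    gene: GeneModel,
    genome: GenomicSequence,
    motif: PeptideMotif | str,
    config: ScanConfig = ScanConfig(),
) -> list[MicroExonCandidate]:
    """Trace-scan every intron of a gene, attaching TIS and local coordinates."""
    if isinstance(motif, str):
        motif = PeptideMotif(motif)
    pattern = reverse_translate(motif)
    exons = _exon_seqs(gene, genome)
    out: list[MicroExonCandidate] = []
    for intron in introns_of(gene, genome):
        up = exons[intron.index - 1][-2:]
        down = exons[intron.index][:2]
        for c in scan_intron_for_trace(
            intron, up, down, motif, config, gene_id=gene.gene_id, pattern=pattern
        ):
            ls = intron.local_start + c.offset_in_intron
            le = ls + c.length
            out.append(
                MicroExonCandidate(
                    **{
                        **c.__dict__,
                        "core_start": int(to_tis(gene, gene.local_to_genomic(ls))),
                        "core_end": int(to_tis(gene, gene.local_to_genomic(le - 1))),
                        "local_start": ls,
                        "local_end": le,
                    }
                )
            )
    return out


def match_exon_edge(
    gene: GeneModel,
    genome: GenomicSequence,
    motif: PeptideMotif | str,
    edge: str,
    exon_index: int,
) -> PhasedMatch | None:
    """Motif coding anchored at an exon's 5' or 3' edge (split codons allowed).

    Returns the lowest-phase match or None.  Anchoring is strict: a
    motif buried mid-exon does not match.
    """
    if isinstance(motif, str):
        motif = PeptideMotif(motif)
    if edge not in {"5prime", "3prime"}:
        raise ValueError("edge must be '5prime' or '3prime'")
    exons = _exon_seqs(gene, genome)
    if not 0 <= exon_index < len(exons):
        raise IndexError(f"exon index {exon_index} out of range")
    pattern = reverse_translate(motif)
    m = len(motif)
    exon = exons[exon_index]
    if edge == "5prime":
        up = exons[exon_index - 1][-2:] if exon_index > 0 else ""
        for a in (0, 1, 2):
            t = 3 * m - a
            if a > len(up) or len(exon) < t:
                continue
            coding = (up[-a:] if a else "") + exon[:t]
            if pattern.matches(coding):
                return PhasedMatch(a, exon[:t], 0)
        return None
    down = exons[exon_index + 1][:2] if exon_index + 1 < len(exons) else ""
    for r in (0, 1, 2):
        t = 3 * m - r
        if r > len(down) or len(exon) < t:
            continue
        coding = exon[-t:] + down[:r]
        if pattern.matches(coding):
            return PhasedMatch(0, exon[-t:], t % 3)
    return None


@dataclass
class LocusClassification:
    """The evolutionary fate of the motif locus in one gene."""

    gene_id: str
    state: str
    candidates: list[MicroExonCandidate] = field(default_factory=list)
    edge_match: PhasedMatch | None = None
    edge_exon_index: int | None = None
    edge: str | None = None
    replacement_peptide: str | None = None
    diff: str | None = None
    warning: bool = False

    def __post_init__(self) -> None:
        if self.state not in {INDEPENDENT, FUSED, TRACE, ABSENT}:
            raise InvariantError(f"unknown state {self.state!r}")


def _edge_peptide(
    exons: list[str], exon_index: int, phase_in: int, m: int
) -> str | None:
    """Translate the 5'-edge coding of an exon under a given phase."""
    up = exons[exon_index - 1][-2:] if exon_index > 0 else ""
    t = 3 * m - phase_in
    if phase_in > len(up) or len(exons[exon_index]) < t:
        return None
    return translate((up[-phase_in:] if phase_in else "") + exons[exon_index][:t])


def classify_locus(
    gene: GeneModel,
    genome: GenomicSequence,
    motif: PeptideMotif | str,
    replacement_motifs: list[str] | None = None,
    config: ScanConfig = ScanConfig(),
) -> LocusClassification:
    """Classify the motif locus of a gene.

    Priority: an annotated micro-exon wins (with a warning flag if an
    intronic trace coexists); otherwise an intronic trace whose
    downstream exon edge encodes a *different* peptide is a trace; an
    exon-edge motif with clean introns is a fused edge; else absent.
    When ``replacement_motifs`` is given the trace call additionally
    requires the edge peptide to be one of them.
    """
    if isinstance(motif, str):
        motif = PeptideMotif(motif)
    m = len(motif)
    pattern = reverse_translate(motif)
    exons = _exon_seqs(gene, genome)
    introns = introns_of(gene, genome)
    candidates = scan_gene(gene, genome, motif, config)

    # annotated micro-exon: a short internal exon flanked AG ... donor
    annotated: tuple[int, PhasedMatch] | None = None
    for k in range(1, len(exons) - 1):
        if not config.min_core <= len(exons[k]) <= config.max_core:
            continue
        if introns[k - 1].acceptor_dinuc != ACCEPTOR:
            continue
        if introns[k].donor_dinuc not in config.donors:
            continue
        pms = match_phased(pattern, exons[k - 1][-2:], exons[k], exons[k + 1][:2])
        if pms:
            annotated = (k, pms[0])
            break

    if annotated is not None:
        k, pm = annotated
        return LocusClassification(
            gene.gene_id,
            INDEPENDENT,
            candidates=candidates,
            edge_match=pm,
            edge_exon_index=k,
            edge="5prime",
            warning=bool(candidates),
        )

    if candidates:
        c = candidates[0]
        edge_pep = _edge_peptide(exons, c.intron_index, c.phase_in, m)
        accept = edge_pep is not None and edge_pep != motif.residues
        if accept and replacement_motifs is not None:
            accept = edge_pep in replacement_motifs
        if accept:
            return LocusClassification(
                gene.gene_id,
                TRACE,
                candidates=candidates,
                replacement_peptide=edge_pep,
                diff=f"{motif.residues}→{edge_pep}",
            )
        # motif both in the intron and at the adjacent edge: conflicting
        edge_pm = match_exon_edge(gene, genome, motif, "5prime", c.intron_index)
        if edge_pm is not None:
            return LocusClassification(
                gene.gene_id,
                FUSED,
                candidates=candidates,
                edge_match=edge_pm,
                edge_exon_index=c.intron_index,
                edge="5prime",
                warning=True,
            )
        return LocusClassification(gene.gene_id, ABSENT, candidates=candidates)

    for k in range(len(exons)):
        for edge in ("5prime", "3prime"):
            pm = match_exon_edge(gene, genome, motif, edge, k)
            if pm is not None:
                return LocusClassification(
                    gene.gene_id,
                    FUSED,
                    edge_match=pm,
                    edge_exon_index=k,
                    edge=edge,
                )
    return LocusClassification(gene.gene_id, ABSENT)


@dataclass
class SpliceVariant:
    """One exon chain consistent with the donor/AG rule, with its peptide.

    Peptides are translated up to the first stop; ``has_internal_stop``
    flags variants truncated relative to the reference by a premature
    stop (typically frame-shifting acceptor choices).
    """

    gene_id: str
    exon_chain: tuple[tuple[int, int], ...]  # gene-local unspliced intervals
    used_sites: tuple[tuple[tuple[int, str], tuple[int, str]], ...]
    peptide: str
    diff_vs_reference: str
    is_reference: bool = False
    has_internal_stop: bool = False
    label: str = ""


def _chain_cds(local: str, chain, offset: int) -> str:
    return "".join(local[s:e] for s, e in chain)[offset:]


def _chain_sites(gene: GeneModel, local: str, chain):
    sites = []
    for (_, e1), (s2, _) in zip(chain, chain[1:]):
        donor = local[e1 : e1 + 2]
        acceptor = local[s2 - 2 : s2]
        sites.append(
            (
                (gene.local_to_genomic(e1), donor),
                (gene.local_to_genomic(s2 - 1), acceptor),
            )
        )
    return tuple(sites)


def _generic_diff(ref: str, alt: str) -> str:
    if ref == alt:
        return "identical"
    i = 0
    while i < min(len(ref), len(alt)) and ref[i] == alt[i]:
        i += 1
    j = 0
    while (
        j < min(len(ref), len(alt)) - i and ref[len(ref) - 1 - j] == alt[len(alt) - 1 - j]
    ):
        j += 1
    a = ref[i : len(ref) - j] or "-"
    b = alt[i : len(alt) - j] or "-"
    return f"{a}→{b}"


def enumerate_splice_variants(
    gene: GeneModel,
    genome: GenomicSequence,
    locus: LocusClassification,
    config: ScanConfig = ScanConfig(),
) -> list[SpliceVariant]:
    """The reference transcript plus every candidate-restoring variant.

    For each intronic candidate: (a) splice the candidate in as an
    independent exon using the annotated downstream acceptor, and
    (b) splice it in with any alternative AG acceptor found within
    ``config.acceptor_window`` nucleotides past the candidate's donor
    (which may fall inside the annotated downstream exon — the
    replacement-excision case).  New introns must start with a
    configured donor and end AG; the annotated (reference) introns are
    exempt, since an atypically spliced annotation is precisely what a
    trace implies.  Variants with internal stops are kept but flagged.
    """
    local = gene.local_sequence(genome)
    lex = gene.local_exons()
    offset = gene.cds_start_offset

    def _peptide(chain) -> str:
        """Translation of the chain's CDS up to (excluding) the first stop."""
        pep = translate(_chain_cds(local, chain, offset))
        return pep.split("*", 1)[0]

    ref_pep = _peptide(lex)
    ref_gaps = {(e1, s2) for (_, e1), (s2, _) in zip(lex, lex[1:])}

    def _new_gaps_valid(chain) -> bool:
        for (_, e1), (s2, _) in zip(chain, chain[1:]):
            if (e1, s2) in ref_gaps:
                continue
            if s2 - e1 < 4:
                return False
            if local[e1 : e1 + 2] not in config.donors:
                return False
            if local[s2 - 2 : s2] != ACCEPTOR:
                return False
        return True

    def _variant(
        chain,
        label: str,
        cand: MicroExonCandidate | None = None,
        cand_spliced_start: int | None = None,
    ) -> SpliceVariant:
        pep = _peptide(chain)
        if cand is not None and len(pep) == len(ref_pep):
            m = len(cand.encoded_motif)
            c0 = (cand_spliced_start - cand.phase_in - offset) // 3
            if (
                0 <= c0 and c0 + m <= len(pep)
                and ref_pep[:c0] == pep[:c0]
                and ref_pep[c0 + m :] == pep[c0 + m :]
            ):
                diff = f"{ref_pep[c0:c0 + m]}→{pep[c0:c0 + m]}"
            else:
                diff = _generic_diff(ref_pep, pep)
        else:
            diff = _generic_diff(ref_pep, pep)
        return SpliceVariant(
            gene_id=gene.gene_id,
            exon_chain=tuple(chain),
            used_sites=_chain_sites(gene, local, chain),
            peptide=pep,
            diff_vs_reference=diff,
            is_reference=label == "reference",
            has_internal_stop=len(pep) < len(ref_pep),
            label=label,
        )

    variants = [_variant(lex, "reference")]
    seen = {tuple(lex)}

    for cand in locus.candidates:
        if cand.local_start is None:
            continue
        cs, ce = cand.local_start, cand.local_end
        i = cand.intron_index  # candidate sits between exon i-1 and exon i
        # spliced offset of the candidate start in any chain that inserts it
        spliced_before = sum(e - s for s, e in lex[:i])

        # (a) candidate in, annotated acceptor
        chain_a = lex[:i] + [(cs, ce)] + lex[i:]
        if _new_gaps_valid(chain_a) and tuple(chain_a) not in seen:
            seen.add(tuple(chain_a))
            variants.append(_variant(chain_a, "micro_exon_in", cand, spliced_before))

        # (b) candidate in, alternative acceptor within the window
        e_i_start, e_i_end = lex[i]
        for q in range(ce + 2, min(ce + 2 + config.acceptor_window, len(local) - 1)):
            if local[q : q + 2] != ACCEPTOR:
                continue
            s_new = q + 2
            if s_new >= e_i_end or s_new == e_i_start:
                continue
            chain_b = lex[:i] + [(cs, ce), (s_new, e_i_end)] + lex[i + 1 :]
            if _new_gaps_valid(chain_b) and tuple(chain_b) not in seen:
                seen.add(tuple(chain_b))
                variants.append(
                    _variant(chain_b, f"alt_acceptor@{s_new}", cand, spliced_before)
                )

    return variants
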