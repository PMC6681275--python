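"""Synthetic inputs with planted truth for every pipeline stage.

The gene generator emulates multi-exon plant genes (default five backbone
exons, 60–400 nt each, introns 80–600 nt) whose motif locus sits between
backbone exons 2 and 3 — the third-exon context typical of WRI1-family
genes — in one of four planted states:

``micro``
    the motif is encoded by an independent micro-exon of 3·m nt flanked
    by canonical GT…AG introns, with split codons (default phase 1: the
    upstream exon supplies the first nucleotide of the motif's first
    codon);
``fused``
    intron loss — the motif coding sits at the 5' edge of the third
    exon with no intronic trace;
``trace``
    atypical splicing — the annotated third exon starts with a
    *replacement* peptide (default GCL) while the second intron ends
    with AG + micro-exon + GT, its last dinucleotide being the
    micro-exon's donor (an atypical annotated acceptor), and the
    replacement coding carries an alternative AG acceptor exactly 3·m nt
    past the donor so that splicing the micro-exon back in restores the
    motif and nothing else;
``absent``
    no motif coding anywhere.

Backgrounds (intron interiors, UTRs) are rejection-sampled so that no
*unplanted* window satisfies the scanner's criteria and the generated
classification equals the planted state; generation fails loudly after a
retry cap rather than emitting an ambiguous gene.  Every generator is a
pure function of its spec and seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codonmap import AMINO_ACIDS, CODONS_FOR, PeptideMotif, translate
from .errors import GenerationError, InvariantError
from .expression import CtTable
from .genemodel import (
    GeneModel,
    GenomicSequence,
    reverse_complement,
    to_tis,
    write_fasta,
    write_gff3,
)
from .microexon import (
    ABSENT,
    FUSED,
    INDEPENDENT,
    TRACE,
    ScanConfig,
    classify_locus,
)
from .motifscan import AW_BOX_LENGTH, scan_aw_box

STATES = ("micro", "fused", "trace", "absent")
_STATE_TO_CLASS = {
    "micro": INDEPENDENT,
    "fused": FUSED,
    "trace": TRACE,
    "absent": ABSENT,
}
_MAX_TRIES = 60
_NT = np.array(list("ACGT"))


@dataclass
class GeneSpec:
    """Parameters of one synthetic gene."""

    motif: str = "VYL"
    planted_state: str = "micro"
    n_exons: int = 5
    exon_length: tuple[int, int] = (60, 400)
    intron_length: tuple[int, int] = (80, 600)
    phase_in: int = 1
    replacement: str = "GCL"
    locus_exon: int = 2  # planted between backbone exons 2 and 3 (1-based)
    motif_codons: tuple[str, ...] | None = None
    strand: str | None = None  # None -> drawn from the seed
    gene_id: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_state not in STATES:
            raise InvariantError(f"unknown planted state {self.planted_state!r}")
        if self.phase_in not in (0, 1, 2):
            raise InvariantError("phase_in must be 0, 1 or 2")
        if not 2 <= self.locus_exon < self.n_exons:
            raise InvariantError("locus must sit between two internal backbone exons")
        for lo, hi in (self.exon_length, self.intron_length):
            if not 1 <= lo <= hi:
                raise InvariantError("length ranges must be positive and ordered")
        if self.exon_length[0] < 3 * len(self.motif) + 12:
            raise InvariantError("exons too short to host the motif locus")
        if self.planted_state == "trace" and self.replacement == self.motif:
            raise InvariantError("replacement must differ from the motif")
        if self.motif_codons is not None:
            if len(self.motif_codons) != len(self.motif):
                raise InvariantError("need one codon per motif residue")
            for aa, codon in zip(self.motif, self.motif_codons):
                if codon.upper() not in CODONS_FOR[aa]:
                    raise InvariantError(f"{codon!r} does not encode {aa!r}")
        if not self.gene_id:
            self.gene_id = f"synth_{self.planted_state}_{self.seed}"


@dataclass(frozen=True)
class TruthRecord:
    """What was planted, for validating the pipeline against ground truth."""

    gene_id: str
    planted_state: str
    core_start: int | None  # TIS coordinate of the first core nucleotide
    core_end: int | None
    core_sequence: str
    expected_diff: str | None


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, n)])


def _rand_codon(rng: np.random.Generator, aa: str, prefix: str = "") -> str:
    options = [c for c in CODONS_FOR[aa] if c.startswith(prefix)]
    if not options:
        raise GenerationError(f"no codon for {aa!r} with prefix {prefix!r}")
    return options[rng.integers(0, len(options))]


def _rand_residue_codon(
    rng: np.random.Generator, prefix: str = "", suffix: str = ""
) -> tuple[str, str]:
    options = [
        (aa, c)
        for aa in AMINO_ACIDS
        for c in CODONS_FOR[aa]
        if c.startswith(prefix) and c.endswith(suffix)
    ]
    if not options:
        raise GenerationError(
            f"no codon with prefix {prefix!r} and suffix {suffix!r}"
        )
    return options[rng.integers(0, len(options))]


def _trace_codons(
    rng: np.random.Generator, motif_codons: list[str], replacement: str, p: int
) -> tuple[list[str], str]:
    """Replacement codons + the codon following the locus, satisfying the
    trace geometry (shared p-nt prefix with the motif's first codon; an AG
    acceptor ending exactly 3m nt past the micro-exon donor)."""
    m = len(replacement)
    repl = [
        _rand_codon(rng, aa, motif_codons[0][:p] if i == 0 else "")
        for i, aa in enumerate(replacement)
    ]
    if p == 0:
        # AG must be the last two replacement-coding nucleotides
        last = [c for c in CODONS_FOR[replacement[-1]] if c.endswith("AG")]
        if not last:
            raise GenerationError(
                f"replacement {replacement!r} incompatible with phase 0 "
                "(no codon ending AG); use phase 1 or 2 or another replacement"
            )
        repl[-1] = last[rng.integers(0, len(last))]
        _, nxt = _rand_residue_codon(rng)
    elif p == 1:
        last = [
            c
            for c in CODONS_FOR[replacement[-1]]
            if c.endswith("A") and (m > 1 or c.startswith(motif_codons[0][:1]))
        ]
        if not last:
            raise GenerationError(
                f"replacement {replacement!r} incompatible with phase 1 "
                "(no codon ending A)"
            )
        repl[-1] = last[rng.integers(0, len(last))]
        _, nxt = _rand_residue_codon(rng, prefix="G")
    else:  # p == 2: the following codon must begin AG
        _, nxt = _rand_residue_codon(rng, prefix="AG")
    return repl, nxt


def generate_gene(
    spec: GeneSpec,
) -> tuple[GenomicSequence, GeneModel, TruthRecord]:
    """Deterministically generate one gene with its planted truth.

    Raises :class:`GenerationError` when rejection sampling exceeds the
    retry cap (try a longer motif or shorter introns) or when the
    requested replacement/phase combination is geometrically infeasible.
    """
    rng = np.random.default_rng(spec.seed)
    motif = PeptideMotif(spec.motif)
    m = len(motif)
    p = spec.phase_in
    config = ScanConfig(max_core=max(30, 3 * m))
    last_error = "rejection sampling exhausted"
    for _ in range(_MAX_TRIES):
        try:
            result = _build_gene(rng, spec, motif, p, config)
        except _Reject as rej:
            last_error = str(rej)
            continue
        return result
    raise GenerationError(
        f"could not generate gene {spec.gene_id!r} in {_MAX_TRIES} tries "
        f"({last_error}); consider a longer motif or shorter introns"
    )


class _Reject(Exception):
    pass


def _build_gene(rng, spec: GeneSpec, motif: PeptideMotif, p: int, config: ScanConfig):
    m = len(motif)
    state = spec.planted_state
    n = spec.n_exons
    k = spec.locus_exon  # boundary after backbone exon k (1-based)
    lens = rng.integers(spec.exon_length[0], spec.exon_length[1] + 1, n)
    ilens = rng.integers(spec.intron_length[0], spec.intron_length[1] + 1, n - 1)
    s_k = int(lens[:k].sum())
    total = int(lens.sum())

    base5 = int(rng.integers(9, 31))
    utr5 = base5 + (s_k - base5 - p) % 3
    base3 = int(rng.integers(9, 31))
    utr3 = base3 + (total - utr5 - base3) % 3
    n_codons = (total - utr5 - utr3) // 3
    c_locus = (s_k - utr5 - p) // 3
    if not (1 <= c_locus and c_locus + m + 3 <= n_codons):
        raise _Reject("locus does not fit inside the coding sequence")

    # -- coding sequence -----------------------------------------------------
    motif_codons = (
        [c.upper() for c in spec.motif_codons]
        if spec.motif_codons
        else [_rand_codon(rng, aa) for aa in motif.residues]
    )
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        aa = AMINO_ACIDS[rng.integers(0, 20)]
        codons.append(_rand_codon(rng, aa))
    codons.append(CODONS_FOR["*"][rng.integers(0, 3)])

    if state in ("micro", "fused"):
        codons[c_locus : c_locus + m] = motif_codons
    elif state == "trace":
        repl, nxt = _trace_codons(rng, motif_codons, spec.replacement, p)
        codons[c_locus : c_locus + m] = repl
        codons[c_locus + m] = nxt

    peptide = translate("".join(codons[:-1]))
    expected_count = 1 if state in ("micro", "fused") else 0
    if peptide.count(motif.residues) != expected_count:
        raise _Reject("motif appeared at an unplanted peptide position")

    spliced = _rand_dna(rng, utr5) + "".join(codons) + _rand_dna(rng, utr3)
    assert len(spliced) == total
    bounds = np.concatenate([[0], np.cumsum(lens)])
    backbone = [spliced[bounds[i] : bounds[i + 1]] for i in range(n)]

    # -- exon/intron layout --------------------------------------------------
    exon_seqs = list(backbone)
    planted_intron_gap = None  # index into the gaps list
    me_seq = ""
    if state == "micro":
        if len(exon_seqs[k]) < 3 * m + 10:
            raise _Reject("third backbone exon too short to carve the micro-exon")
        me_seq = exon_seqs[k][: 3 * m]
        exon_seqs = exon_seqs[:k] + [me_seq, exon_seqs[k][3 * m :]] + exon_seqs[k + 1 :]
    elif state == "trace":
        nxt_codon = codons[c_locus + m]
        me_seq = "".join(motif_codons)[p:] + nxt_codon[:p]
        planted_intron_gap = k - 1

    introns = []
    n_gaps = len(exon_seqs) - 1
    ilens = list(ilens) + [int(rng.integers(*spec.intron_length))] * (
        n_gaps - len(ilens)
    )
    planted_offset = None
    for g in range(n_gaps):
        length = int(ilens[g])
        if planted_intron_gap is not None and g == planted_intron_gap:
            a_len = max(length - (6 + len(me_seq)), 10)
            interior = _rand_dna(rng, a_len)
            intron = "GT" + interior + "AG" + me_seq + "GT"
            planted_offset = 2 + a_len + 2  # core offset within the intron
        else:
            intron = "GT" + _rand_dna(rng, max(length - 4, 4)) + "AG"
        introns.append(intron)

    # -- assemble the chromosome --------------------------------------------
    pad_l = _rand_dna(rng, int(rng.integers(30, 81)))
    pad_r = _rand_dna(rng, int(rng.integers(30, 81)))
    parts = []
    local_exons = []
    pos = len(pad_l)
    for i, ex in enumerate(exon_seqs):
        parts.append(ex)
        local_exons.append((pos, pos + len(ex)))
        pos += len(ex)
        if i < len(introns):
            parts.append(introns[i])
            pos += len(introns[i])
    local_gene = "".join(parts)
    chrom_plus = pad_l + local_gene + pad_r

    strand = spec.strand or ("+" if rng.integers(0, 2) == 0 else "-")
    if strand == "+":
        chrom = chrom_plus
        genomic_exons = local_exons
    else:
        chrom = reverse_complement(chrom_plus)
        L = len(chrom)
        genomic_exons = [(L - e, L - s) for s, e in local_exons]

    genome = GenomicSequence(f"chr_{spec.gene_id}", chrom)
    gene = GeneModel(spec.gene_id, genome.id, strand, genomic_exons, utr5)

    origin = local_exons[0][0]  # chromosome-local offset of gene-local 0

    # -- self-check: planted truth must be the only signal --------------------
    cls = classify_locus(gene, genome, motif, config=config)
    if cls.state != _STATE_TO_CLASS[state]:
        raise _Reject(f"classified {cls.state}, planted {state}")
    if cls.warning:
        raise _Reject("conflicting evidence from background sequence")
    if state == "trace":
        me_local = local_exons[k - 1][1] + planted_offset - origin
        ok = all(
            c.intron_index == k
            and c.local_start == me_local
            and c.length == len(me_seq)
            for c in cls.candidates
        )
        if not (ok and cls.candidates):
            raise _Reject("spurious scanner hit in an intron")
        if cls.replacement_peptide != spec.replacement:
            raise _Reject("edge peptide is not the planted replacement")
    elif cls.candidates:
        raise _Reject("spurious scanner hit in an intron")
    if state == "micro" and cls.edge_exon_index != k:
        raise _Reject("annotated micro-exon recovered at the wrong exon")
    if state == "fused" and (cls.edge_exon_index, cls.edge) != (k, "5prime"):
        raise _Reject("edge match recovered at the wrong exon edge")

    # -- truth record ---------------------------------------------------------
    def tis(chrom_local: int) -> int:
        return int(to_tis(gene, gene.local_to_genomic(chrom_local - origin)))

    if state == "micro":
        s, e = local_exons[k]
        truth = TruthRecord(spec.gene_id, state, tis(s), tis(e - 1), me_seq, None)
    elif state == "trace":
        s = local_exons[k - 1][1] + planted_offset
        truth = TruthRecord(
            spec.gene_id,
            state,
            tis(s),
            tis(s + len(me_seq) - 1),
            me_seq,
            f"{motif.residues}→{spec.replacement}",
        )
    elif state == "fused":
        # locus spans the last p nt of exon k and the first 3m-p of exon k+1;
        # TIS coordinates are unspliced, so convert each end separately
        s5 = local_exons[k - 1][1] - p if p else local_exons[k][0]
        e3 = local_exons[k][0] + 3 * m - p - 1
        truth = TruthRecord(
            spec.gene_id, state, tis(s5), tis(e3), "".join(motif_codons), None
        )
    else:
        truth = TruthRecord(spec.gene_id, state, None, None, "", None)
    return genome, gene, truth


def write_dataset(
    genes: list[tuple[GenomicSequence, GeneModel, TruthRecord]],
    out_dir: str | os.PathLike,
) -> dict[str, str]:
    """Write FASTA + GFF3 + truth TSV for a list of generated genes."""
    os.makedirs(out_dir, exist_ok=True)
    fasta = os.path.join(out_dir, "genes.fasta")
    gff = os.path.join(out_dir, "genes.gff3")
    truth_path = os.path.join(out_dir, "truth.tsv")
    write_fasta([g for g, _, _ in genes], fasta)
    write_gff3([m for _, m, _ in genes], gff)
    with open(truth_path, "w") as fh:
        fh.write(
            "gene_id\tplanted_state\tcore_start\tcore_end\tcore_sequence\texpected_diff\n"
        )
        for _, _, t in genes:
            fh.write(
                "\t".join(
                    [
                        t.gene_id,
                        t.planted_state,
                        "" if t.core_start is None else str(t.core_start),
                        "" if t.core_end is None else str(t.core_end),
                        t.core_sequence,
                        t.expected_diff or "",
                    ]
                )
                + "\n"
            )
    return {"fasta": fasta, "gff": gff, "truth": truth_path}


# -- promoters ---------------------------------------------------------------


def generate_promoter(
    length: int,
    n_sites: int,
    seed: int = 0,
    seq_id: str = "promoter",
    clean_background: bool = False,
) -> tuple[GenomicSequence, list[int]]:
    """Uniform background with ``n_sites`` planted AW-box instances.

    Planted sites are non-overlapping plus-strand consensus instances
    with random spacer nucleotides; their start offsets are returned.
    With ``clean_background`` the background is additionally
    rejection-sampled until the only plus-strand hits are the planted
    ones (minus-strand chance hits overlapping planted sites cannot be
    scrubbed and are left in place).
    """
    rng = np.random.default_rng(seed)
    if n_sites * AW_BOX_LENGTH > length:
        raise GenerationError(f"{n_sites} sites do not fit in {length} nt")
    for _ in range(200):
        seq = list(_rand_dna(rng, length))
        if n_sites:
            starts = np.sort(rng.choice(length - AW_BOX_LENGTH + 1, n_sites, replace=False))
            if np.any(np.diff(starts) < AW_BOX_LENGTH):
                continue
        else:
            starts = np.array([], dtype=int)
        positions = [int(s) for s in starts]
        for s in positions:
            site = (
                "C" + _rand_dna(rng, 1) + "T" + _rand_dna(rng, 1) + "G"
                + _rand_dna(rng, 7) + "CG"
            )
            seq[s : s + AW_BOX_LENGTH] = site
        genomic = GenomicSequence(seq_id, "".join(seq))
        if not clean_background:
            return genomic, positions
        extra = [
            h
            for h in scan_aw_box(genomic, "both")
            if not (h.strand == "+" and h.start in set(positions))
        ]
        if not extra:
            return genomic, positions
    raise GenerationError("could not scrub promoter background of chance AW boxes")


# -- qPCR tables -------------------------------------------------------------


def generate_ct_table(
    folds: dict[str, dict[str, float]],
    reference_gene: str,
    calibrator_sample: str,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
):
    """Ct table consistent with the given true fold changes.

    ``folds[sample][gene]`` is the fold change versus the calibrator
    sample (which is added with fold 1 for every gene if absent).
    Baseline Ct values are drawn on a quarter-cycle grid so that with
    ``noise_sd=0`` and dyadic folds the computed fold changes are exact.
    Gaussian noise (SD in cycles) is added per replicate measurement.
    """
    rng = np.random.default_rng(seed)
    folds = {s: dict(g) for s, g in folds.items()}
    genes = sorted({g for gg in folds.values() for g in gg})
    folds.setdefault(calibrator_sample, {})
    for g in genes:
        folds[calibrator_sample].setdefault(g, 1.0)
        for s in folds:
            if g not in folds[s]:
                raise InvariantError(f"fold missing for gene {g!r} in sample {s!r}")
            if folds[s][g] <= 0:
                raise InvariantError("true folds must be positive")

    ref_ct = {s: 16.0 + int(rng.integers(0, 16)) / 4.0 for s in sorted(folds)}
    dct_cal = {g: int(rng.integers(8, 32)) / 4.0 for g in genes}
    rows = []
    for s in sorted(folds):
        for rep in range(1, replicates + 1):
            rows.append((s, reference_gene, rep, ref_ct[s] + rng.normal(0, noise_sd) if noise_sd else ref_ct[s]))
        for g in genes:
            ct = ref_ct[s] + dct_cal[g] - float(np.log2(folds[s][g]))
            for rep in range(1, replicates + 1):
                rows.append((s, g, rep, ct + rng.normal(0, noise_sd) if noise_sd else ct))
    df = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])
    return CtTable(df, reference_gene, calibrator_sample)
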