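"""Gene-structure primitives: sequences, exon chains, introns, TIS coordinates.

Coordinate conventions
----------------------
GFF3 files are 1-based inclusive; internally everything is 0-based
half-open.  Minus-strand genes are flipped into coding orientation
immediately after reading, so every downstream module reasons in coding
orientation only.  Translation-initiation-site (TIS) coordinates number
nucleotides along the *unspliced* gene: +1 is the A of the ATG, upstream
positions are negative, and there is no position 0 — introns are counted,
matching how splice-junction positions are conventionally reported for
gene-structure figures.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import CoordinateError, FormatError, InvariantError

DNA_ALPHABET = frozenset("ACGTN")


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


@dataclass
class GenomicSequence:
    """A named DNA sequence over {A, C, G, T, N} (input case-normalized)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise InvariantError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains characters outside A/C/G/T/N: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """A stranded, exon-structured protein-coding gene on a genomic sequence.

    ``exons`` are genomic 0-based half-open intervals ordered 5'->3' in
    *coding* orientation (descending genomic start for minus-strand genes).
    ``cds_start_offset`` counts spliced exonic nucleotides from the first
    exon base to the A of the ATG.
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise InvariantError(f"gene {self.gene_id!r}: strand must be + or -")
        if not self.exons:
            raise InvariantError(f"gene {self.gene_id!r}: at least one exon required")
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        for s, e in self.exons:
            if e - s < 1 or s < 0:
                raise InvariantError(
                    f"gene {self.gene_id!r}: invalid exon interval ({s}, {e})"
                )
        ordered = self.exons if self.strand == "+" else self.exons[::-1]
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise InvariantError(
                    f"gene {self.gene_id!r}: exons overlap or are out of coding order"
                )
        if not 0 <= self.cds_start_offset < self.exonic_length:
            raise InvariantError(
                f"gene {self.gene_id!r}: cds_start_offset {self.cds_start_offset} "
                "falls outside the exon chain"
            )

    # -- geometry -----------------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) covering all exons, half-open."""
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def genomic_to_local(self, pos: int) -> int:
        """Genomic position -> unspliced coding-orientation offset from gene 5' end."""
        lo, hi = self.span
        return pos - lo if self.strand == "+" else (hi - 1) - pos

    def local_to_genomic(self, local: int) -> int:
        lo, hi = self.span
        return lo + local if self.strand == "+" else (hi - 1) - local

    def local_exons(self) -> list[tuple[int, int]]:
        """Exon intervals in unspliced local (coding-orientation) coordinates."""
        lo, hi = self.span
        if self.strand == "+":
            return [(s - lo, e - lo) for s, e in self.exons]
        return [(hi - e, hi - s) for s, e in self.exons]

    def local_sequence(self, genome: GenomicSequence) -> str:
        """The unspliced gene region in coding orientation."""
        lo, hi = self.span
        if hi > len(genome):
            raise CoordinateError(
                f"gene {self.gene_id!r} exceeds sequence {genome.id!r} "
                f"({hi} > {len(genome)})"
            )
        region = genome.residues[lo:hi]
        return region if self.strand == "+" else reverse_complement(region)

    def atg_local(self) -> int:
        """Unspliced local coordinate of the A of the ATG."""
        remaining = self.cds_start_offset
        for s, e in self.local_exons():
            if remaining < e - s:
                return s + remaining
            remaining -= e - s
        raise InvariantError("cds_start_offset outside exon chain")  # pragma: no cover


@dataclass
class Intron:
    """An intron in coding orientation, with its terminal dinucleotides."""

    index: int  # 1 = between exon 1 and exon 2 (coding order)
    start: int  # genomic, half-open
    end: int
    sequence: str
    donor_dinuc: str = field(init=False)
    acceptor_dinuc: str = field(init=False)
    local_start: int = 0  # unspliced coding-orientation offset of first base
    local_end: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) < 4:
            raise InvariantError(
                f"intron {self.index}: length {len(self.sequence)} < 4"
            )
        self.donor_dinuc = self.sequence[:2]
        self.acceptor_dinuc = self.sequence[-2:]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TisCoordinate:
    """Signed position from the translation initiation site; no position 0."""

    position: int

    def __post_init__(self) -> None:
        if self.position == 0:
            raise InvariantError("TIS coordinate 0 does not exist")

    def __int__(self) -> int:
        return self.position


# -- FASTA ------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> list[GenomicSequence]:
    """Read DNA records; sequences are upper-cased and alphabet-checked."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has no sequence")
        try:
            records.append(
                GenomicSequence(rec.id, str(rec.seq), rec.description[len(rec.id):].strip())
            )
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: list[GenomicSequence], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            header = f">{s.id} {s.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


# -- GFF3 -------------------------------------------------------------------


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene/mRNA/exon/CDS features into GeneModel objects.

    Exons are re-ordered into coding orientation; the CDS features (when
    present) define ``cds_start_offset``.
    """
    text = open(path).read()
    if not any(line.strip() and not line.startswith("#") for line in text.splitlines()):
        return []
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        if g.strand not in {"+", "-"}:
            raise FormatError(f"{path}: gene {g.id!r} has no strand")
        exons = [f for f in db.children(g.id, featuretype="exon")]
        if not exons:
            raise FormatError(f"{path}: gene {g.id!r} has no exon features")
        gspan = (g.start - 1, g.end)
        intervals = []
        for ex in exons:
            iv = (ex.start - 1, ex.end)
            if iv[0] < gspan[0] or iv[1] > gspan[1]:
                raise FormatError(
                    f"{path}: exon {iv} outside gene {g.id!r} span {gspan}"
                )
            intervals.append(iv)
        intervals.sort()
        coding_order = intervals if g.strand == "+" else intervals[::-1]

        cds = [f for f in db.children(g.id, featuretype="CDS")]
        offset = 0
        if cds:
            if g.strand == "+":
                first_base = min(c.start for c in cds) - 1
            else:
                first_base = max(c.end for c in cds) - 1
            offset = _spliced_offset(coding_order, g.strand, first_base, path, g.id)
        genes.append(GeneModel(g.id, g.seqid, g.strand, coding_order, offset))
    return genes


def _spliced_offset(
    coding_exons: list[tuple[int, int]], strand: str, genomic_pos: int, path, gene_id
) -> int:
    acc = 0
    for s, e in coding_exons:
        if s <= genomic_pos < e:
            within = genomic_pos - s if strand == "+" else (e - 1) - genomic_pos
            return acc + within
        acc += e - s
    raise FormatError(f"{path}: CDS start of gene {gene_id!r} not inside any exon")


def write_gff3(genes: list[GeneModel], path: str | os.PathLike, source: str = "microtrace") -> None:
    """Write gene/mRNA/exon/CDS features (1-based inclusive, bit-exact round trip)."""
    lines = ["##gff-version 3"]
    for g in genes:
        lo, hi = g.span
        attrs = f"ID={g.gene_id}"
        lines.append(
            "\t".join([g.seq_id, source, "gene", str(lo + 1), str(hi), ".", g.strand, ".", attrs])
        )
        mid = f"{g.gene_id}.t1"
        lines.append(
            "\t".join([g.seq_id, source, "mRNA", str(lo + 1), str(hi), ".", g.strand, ".",
                       f"ID={mid};Parent={g.gene_id}"])
        )
        for s, e in sorted(g.exons):
            lines.append(
                "\t".join([g.seq_id, source, "exon", str(s + 1), str(e), ".", g.strand, ".",
                           f"Parent={mid}"])
            )
        # CDS pieces: from the ATG through the end of the exon chain.
        remaining = g.cds_start_offset
        coding_acc = 0
        pieces = []
        for s, e in g.exons:  # coding order
            length = e - s
            if remaining >= length:
                remaining -= length
                continue
            if g.strand == "+":
                cs, ce = s + remaining, e
            else:
                cs, ce = s, e - remaining
            phase = (3 - coding_acc % 3) % 3
            pieces.append((cs, ce, phase))
            coding_acc += ce - cs
            remaining = 0
        for cs, ce, phase in sorted(pieces):
            lines.append(
                "\t".join([g.seq_id, source, "CDS", str(cs + 1), str(ce), ".", g.strand,
                           str(phase), f"Parent={mid}"])
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# -- derived structures -----------------------------------------------------


def assemble_cds(gene: GeneModel, genome: GenomicSequence) -> str:
    """Spliced coding sequence: exons joined in coding orientation, trimmed at the ATG."""
    if gene.seq_id != genome.id:
        raise CoordinateError(
            f"gene {gene.gene_id!r} refers to {gene.seq_id!r}, got sequence {genome.id!r}"
        )
    local = gene.local_sequence(genome)
    spliced = "".join(local[s:e] for s, e in gene.local_exons())
    return spliced[gene.cds_start_offset :]


def introns_of(gene: GeneModel, genome: GenomicSequence) -> list[Intron]:
    """Introns in coding orientation (empty list for single-exon genes)."""
    if gene.seq_id != genome.id:
        raise CoordinateError(
            f"gene {gene.gene_id!r} refers to {gene.seq_id!r}, got sequence {genome.id!r}"
        )
    local = gene.local_sequence(genome)
    lex = gene.local_exons()
    introns = []
    for i, ((_, e1), (s2, _)) in enumerate(zip(lex, lex[1:]), start=1):
        g_a = gene.local_to_genomic(e1)
        g_b = gene.local_to_genomic(s2 - 1)
        start, end = min(g_a, g_b), max(g_a, g_b) + 1
        introns.append(
            Intron(
                index=i,
                start=start,
                end=end,
                sequence=local[e1:s2],
                local_start=e1,
                local_end=s2,
            )
        )
    return introns


def to_tis(gene: GeneModel, genomic_position: int) -> TisCoordinate:
    """TIS coordinate of a genomic position: unspliced count, +1 at the A of ATG."""
    u = gene.genomic_to_local(genomic_position)
    u_atg = gene.atg_local()
    return TisCoordinate(u - u_atg + 1 if u >= u_atg else u - u_atg)
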