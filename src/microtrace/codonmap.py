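"""Genetic-code utilities: translation, degenerate reverse translation, and
phase-aware matching of a peptide motif across splice junctions.

The key object is :class:`PhasedMatch`.  A short coding segment (a
micro-exon, or an exon edge) rarely carries whole codons: the upstream
exon may supply the first ``phase_in`` nucleotides of the motif's first
codon, and the segment's 3' end may sit mid-codon, handing
``phase_out = (phase_in + len(core)) % 3`` nucleotides into the codon
completed by the downstream exon.  A 9-nt core with ``phase_in = 1``
therefore contributes 8 nucleotides to a tripeptide and hands 1 on —
exactly the split-codon geometry of conserved VYL-type micro-exons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .errors import FormatError, InvariantError

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter residue; stop codons map to "*"
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: residue -> sorted tuple of codons from the standard code
CODONS_FOR: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, r in _STANDARD.forward_table.items() if r == aa))
    for aa in AMINO_ACIDS
}
CODONS_FOR["*"] = tuple(sorted(_STANDARD.stop_codons))


@dataclass(frozen=True)
class PeptideMotif:
    """A short peptide query (e.g. the conserved VYL of the first AP2 domain)."""

    residues: str
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise InvariantError("motif must contain at least one residue")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise InvariantError(f"non-standard residues in motif: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


def translate(dna: str, frame: int = 0) -> str:
    """Standard-code translation of ``dna`` from ``frame``.

    The trailing partial codon is dropped, stops render as ``*`` and any
    codon containing N renders as ``X`` (N is never resolved, even when
    the ambiguity would not matter).
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    dna = dna.upper()
    bad = set(dna) - set("ACGTN")
    if bad:
        raise FormatError(f"non-DNA characters in input: {sorted(bad)}")
    s = dna[frame:]
    out = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i : i + 3]
        out.append(CODON_TO_AA.get(codon, "X"))
    return "".join(out)


@dataclass(frozen=True)
class DegeneratePattern:
    """Per-residue codon alternatives for a motif (exact standard-code sets).

    ``matches`` treats N as a mismatch: codon sets only ever contain
    unambiguous codons.
    """

    motif: PeptideMotif
    codon_sets: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.codon_sets) != len(self.motif):
            raise InvariantError("one codon set per motif residue required")

    @property
    def n_expansions(self) -> int:
        n = 1
        for s in self.codon_sets:
            n *= len(s)
        return n

    def expansions(self):
        """Every nucleotide sequence whose translation is the motif."""
        for combo in itertools.product(*(sorted(s) for s in self.codon_sets)):
            yield "".join(combo)

    def matches(self, dna: str) -> bool:
        if len(dna) != 3 * len(self.motif):
            return False
        return all(
            dna[3 * i : 3 * i + 3] in s for i, s in enumerate(self.codon_sets)
        )


def reverse_translate(
    motif: PeptideMotif | str,
    residue_alternatives: dict[str, str] | None = None,
) -> DegeneratePattern:
    """Degenerate pattern of all codon spellings of ``motif``.

    ``residue_alternatives`` optionally widens single positions (e.g.
    ``{"V": "I"}`` accepts the natural IYL variant of VYL); default off.
    """
    if isinstance(motif, str):
        motif = PeptideMotif(motif)
    sets = []
    for aa in motif.residues:
        allowed = aa + (residue_alternatives or {}).get(aa, "")
        codons = set()
        for r in allowed:
            if r not in CODONS_FOR:
                raise InvariantError(f"unknown residue {r!r}")
            codons.update(CODONS_FOR[r])
        sets.append(frozenset(codons))
    return DegeneratePattern(motif, tuple(sets))


@dataclass(frozen=True)
class PhasedMatch:
    """A motif-coding decomposition across splice junctions.

    ``phase_in``: motif nucleotides supplied by the upstream exon.
    ``phase_out``: the 3'-junction phase, ``(phase_in + len(core)) % 3`` —
    either core nucleotides handed into the downstream codon (when the
    motif ends inside the core) or ``3 − borrowed`` when the motif's last
    codon is completed from the downstream head.
    """

    phase_in: int
    core: str
    phase_out: int

    def __post_init__(self) -> None:
        if self.phase_in not in (0, 1, 2) or self.phase_out not in (0, 1, 2):
            raise InvariantError("phases must be 0, 1 or 2")
        if self.phase_out != (self.phase_in + len(self.core)) % 3:
            raise InvariantError("phase_out inconsistent with phase_in and core length")


def match_phased(
    pattern: DegeneratePattern,
    upstream_tail: str,
    core_candidate: str,
    downstream_head: str,
) -> list[PhasedMatch]:
    """All phase decompositions under which ``core_candidate`` encodes the motif.

    For each ``phase_in`` in {0, 1, 2} the motif coding is
    ``upstream_tail[-phase_in:] + core[:3m - phase_in]`` when the core is
    long enough (at most two leftover core nucleotides are handed
    downstream), or extends by at most two nucleotides into
    ``downstream_head`` otherwise.  Matches are returned ordered by
    ``phase_in``; no probabilistic tie-breaking.
    """
    up = upstream_tail.upper()
    core = core_candidate.upper()
    down = downstream_head.upper()
    m = len(pattern.motif)
    need = 3 * m
    out: list[PhasedMatch] = []
    for a in (0, 1, 2):
        if a > len(up):
            continue
        t = need - a  # nucleotides the core + downstream must supply
        if t < 0:
            continue
        if len(core) >= t:
            if len(core) - t > 2:  # a whole extra codon would sit inside the core
                continue
            coding = (up[-a:] if a else "") + core[:t]
        else:
            r = t - len(core)
            if r > 2 or r > len(down):
                continue
            coding = (up[-a:] if a else "") + core + down[:r]
        if pattern.matches(coding):
            out.append(PhasedMatch(a, core, (a + len(core)) % 3))
    return out


def spliced_motif_coding(match: PhasedMatch, upstream_tail: str, downstream_head: str, m: int) -> str:
    """Reconstruct the motif's coding nucleotides for a returned match."""
    a = match.phase_in
    t = 3 * m - a
    core = match.core
    if len(core) >= t:
        return (upstream_tail[-a:] if a else "") + core[:t]
    return (upstream_tail[-a:] if a else "") + core + downstream_head[: t - len(core)]
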