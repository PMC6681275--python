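"""AW-box scanning.

The AW-box is the WRI1-binding consensus CnTnG(n)7CG found in proximal
upstream regions of fatty-acid-synthesis genes: a 14-mer with five fixed
positions (C, T, G at offsets 0/2/4 and CG at offsets 12/13) and nine
unconstrained positions.  Every occurrence is reported, overlaps
included, because downstream use is occurrence counting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import InvariantError
from .genemodel import GenomicSequence, reverse_complement

#: 5 consensus-prefix positions + 7 spacer + CG
AW_BOX_LENGTH = 14
_AW_RE = re.compile(r"(?=(C[ACGT]T[ACGT]G[ACGT]{7}CG))")


@dataclass(frozen=True)
class AWBoxHit:
    """One AW-box occurrence; ``start`` is always a plus-strand offset."""

    seq_id: str
    start: int
    strand: str
    site: str

    def __post_init__(self) -> None:
        if len(self.site) != AW_BOX_LENGTH:
            raise InvariantError("AW-box site must be 14 nt")
        s = self.site
        if not (s[0] == "C" and s[2] == "T" and s[4] == "G" and s[12:] == "CG"):
            raise InvariantError(f"site {s!r} violates the CnTnG(n)7CG consensus")

    @property
    def end(self) -> int:
        return self.start + AW_BOX_LENGTH


def scan_aw_box(seq: GenomicSequence, strands: str = "both") -> list[AWBoxHit]:
    """All AW-box occurrences on the requested strand(s).

    N never matches.  Minus-strand hits carry the site as read on the
    minus strand, with ``start`` converted to plus-strand coordinates.
    """
    if strands not in {"+", "-", "both"}:
        raise ValueError("strands must be '+', '-' or 'both'")
    hits: list[AWBoxHit] = []
    if strands in {"+", "both"}:
        for m in _AW_RE.finditer(seq.residues):
            hits.append(AWBoxHit(seq.id, m.start(), "+", m.group(1)))
    if strands in {"-", "both"}:
        rc = reverse_complement(seq.residues)
        n = len(rc)
        for m in _AW_RE.finditer(rc):
            hits.append(
                AWBoxHit(seq.id, n - m.start() - AW_BOX_LENGTH, "-", m.group(1))
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def hits_to_bed(hits: list[AWBoxHit]) -> str:
    """BED-like TSV: seq_id, start, end, strand, site."""
    lines = ["\t".join(["seq_id", "start", "end", "strand", "site"])]
    for h in hits:
        lines.append("\t".join([h.seq_id, str(h.start), str(h.end), h.strand, h.site]))
    return "\n".join(lines) + "\n"
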