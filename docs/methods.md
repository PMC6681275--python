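# Methods

## Coordinates and gene models

GFF3 input/output is 1-based inclusive; internally all intervals are 0-based
half-open. Minus-strand genes are flipped into coding orientation immediately
after reading, so every analysis module reasons in coding orientation only.
Translation-initiation-site (TIS) coordinates number nucleotides along the
*unspliced* gene — +1 at the A of the ATG, negative upstream, no position 0 —
because splice-junction positions are conventionally reported with introns
counted. `cds_start_offset` (spliced nucleotides from the first exon base to
the ATG) is recovered from CDS features on read and regenerated, with per-piece
phase, on write; the writer/reader pair round-trips models bit-exactly.

N is a legal sequence character but never matches a codon pattern and never
contributes to a translated residue other than X. Translation uses the
standard nuclear code only.

## Phased motif matching

A short coding segment rarely carries whole codons. A `PhasedMatch` records
`phase_in` — motif nucleotides supplied by the upstream exon (0–2) — and
`phase_out = (phase_in + |core|) mod 3`, the 3'-junction phase. The motif's
3·m coding nucleotides are `upstream[-phase_in:] + core[:3m - phase_in]` when
the core is long enough (at most two leftover core nucleotides are handed
into the codon completed downstream), or extend by at most two nucleotides
into the downstream head otherwise. The canonical VYL case is a 9-nt core
with `phase_in = 1`: one upstream G completes `G|TC TAT TTG`, and the core's
final nucleotide starts the next codon. All phase decompositions that
reproduce the motif are reported, ordered by `phase_in`; there is no
probabilistic tie-breaking. Reverse translation uses the exact standard-code
codon sets per residue; an optional residue-alternatives map (e.g. accepting
I at the V position, the documented IYL variant) widens single positions and
is off by default.

## Trace scanning and locus classification

A trace candidate is any intronic window W with (i) `AG` immediately 5' of W,
(ii) a configured donor (default `{GT}`, optionally `GC` for the minor
canonical class) immediately 3' of W, and (iii) a phase decomposition with
the flanking exon context that encodes the query motif. Window lengths are
bounded (default 3–30 nt — micro-exon semantics); overlapping candidates are
all reported. The scanner enumerates AG/donor position pairs directly rather
than sliding every window, which keeps a multi-kilobase intron at a few dozen
candidate windows.

Classification priority: an annotated micro-exon (short internal exon,
AG…donor flanks, motif-encoding) wins, with a warning flag if an intronic
trace coexists; otherwise an intronic trace whose downstream exon 5' edge
translates, under the candidate's phase, to a *different* peptide is
`trace_in_intron` (the edge peptide is reported as the replacement, and the
diff as `MOTIF→REPLACEMENT`); an exon-edge match with clean introns is
`fused_exon_edge`; otherwise `absent`. When a replacement list is supplied
the trace call additionally requires membership. Edge matching is strictly
edge-anchored: a motif buried mid-exon does not count.

## Splice-variant enumeration

For each candidate the enumerator emits (a) the candidate spliced in as an
independent exon using the annotated downstream acceptor and (b) the
candidate plus any alternative `AG` acceptor within a configured window
(default 30 nt) past the candidate's donor — the window that captures an
acceptor placed inside the annotated downstream exon, i.e. excision of the
replacement coding. Every *new* intron must start with a configured donor and
end `AG`; chains violating this are not emitted. The annotated introns are
exempt from that rule, because an atypically spliced annotation is precisely
what a trace implies — the reference transcript is emitted flagged
`is_reference`. Variant peptides are translated to the first stop; variants
truncated relative to the reference (frame-shifting acceptors) are retained
and flagged. When a variant's peptide has the reference's length and differs
only at the locus, the diff is reported as the locus substitution
(`GCL→VYL`); otherwise a minimal prefix/suffix-stripped description is used.

## Synthetic genes with planted truth

The generator emulates multi-exon plant genes: five backbone exons of
60–400 nt, introns of 80–600 nt, a 5' UTR of ~9–33 nt inside exon 1 (adjusted
so the locus falls on the required codon phase), a CDS built codon-by-codon
from a random peptide (so internal stops cannot occur by construction), and
the motif locus at the boundary of backbone exons 2 and 3 — the third-exon
context typical of this gene family — with upstream phase 1 by default.

Trace geometry: the annotated intron 2 ends `…AG + micro-exon + GT`, making
the micro-exon's donor the intron's final dinucleotide (an atypical annotated
acceptor), and the downstream exon begins with the replacement coding whose
alternative `AG` acceptor ends exactly 3·m nt past the donor. With motif
codons fixed to GTC/TAT/TTG this reproduces the junction string
`AGTCTATTTGGGT` literally, and the restored variant's peptide differs from
the annotation by exactly motif↔replacement. Feasibility constraints follow
from the geometry: the replacement's first codon must share its first
`phase_in` nucleotides with the motif's first codon (G and V share G, so
VYL→GCL requires phase 1; VYL→VSA also admits phase 2), and at phase 0 the
replacement's last codon would itself have to end `AG` (impossible for
leucine) — infeasible combinations raise immediately rather than generating a
contradictory gene.

Backgrounds are rejection-sampled: after assembly the gene is classified and
scanned, and any build with a spurious candidate, a spurious edge match, an
unplanted motif occurrence in the peptide, or a wrong classification is
discarded and redrawn (cap 60 attempts, then a hard error suggesting a longer
motif or shorter introns). A build in which the *planted* signal itself
failed to classify is likewise rejected loudly — recovery tests therefore
certify the scanner against an adversarially clean background, not against a
background trimmed to fit. Strand is drawn from the seed so both orientations
are exercised. Every generator is a pure function of spec + seed; identical
seeds give byte-identical FASTA/GFF3.

What the generator does *not* emulate: realistic nucleotide composition,
splice-site context beyond terminal dinucleotides, UTR structure, or
paralog-scale sequence similarity. Passing planted-truth tests therefore
demonstrates correctness of the inference on its own terms, not calibration
against real genomes.

Promoters are uniform backgrounds with non-overlapping planted AW-box
consensus instances; an optional clean-background mode rejection-samples
chance hits away (used for the zero-site case). Ct tables place baseline
values on a quarter-cycle grid (exact binary floats), so with zero noise and
dyadic true folds the ddCt recovery is bit-exact; Gaussian noise is added per
replicate measurement on the Ct scale.

## AW-box scanning

The consensus `CnTnG(n)7CG` is treated literally: a 14-mer with fixed C/T/G
at offsets 0/2/4 and CG at 12/13, nine free positions, N never matching.
Overlapping hits are all reported (downstream use is occurrence counting);
minus-strand hits carry the site as read on the minus strand with the start
converted to plus-strand coordinates. The expected chance rate in uniform
background is (1/4)^5 per offset per strand, which the tests verify within
three binomial standard errors over 10^6 offsets.

## Distance trees

The tree method is deliberately simple and fully specified: p-distance
(proportion of mismatched residues; pairwise gap deletion by default,
complete deletion available; a pair with no comparable columns is an error)
followed by canonical neighbor joining — Q-criterion selection, Saitou–Nei
limb lengths, deterministic tie-breaking on the lowest index pair, negative
limbs clamped to zero with a flag on the tree. NJ is exact on tree-additive
matrices, which the tests exploit: random trees (4–12 taxa) are converted to
path-distance matrices and must be recovered with identical bipartitions and
path distances to 1e-9. This is a reimplementation choice for distance trees
over protein MSAs, not a claim of bit-identity with any particular aligner's
guide tree. Trees serialize to newick via a trifurcating root (unrooted
convention).

Motif-region extraction anchors on a named reference row: the columns whose
reference residues spell the motif (gap columns inside the span included;
first occurrence wins with a warning on multiplicity), extracted identically
for every record; the label is the degapped region or `absent`.

## Expression calculators

ddCt: ΔCt = mean Ct(gene) − mean Ct(reference) within a sample; ΔΔCt =
ΔCt(sample) − ΔCt(calibrator); fold = 2^−ΔΔCt with amplification efficiency
fixed at 2 (the classical assumption; no efficiency correction). The
calibrator's fold is exactly 1 by construction. Dispersion is reported on the
Ct scale as sqrt(s²_gene/n + s²_ref/n) — the variance of each replicate mean
within the sample, the calibrator term not added — and as the asymmetric fold
interval 2^−(ΔΔCt ± SD). This propagation rule is a documented choice; the
classical method description does not fix one.

Reporter ratios: each replicate (an independent transfection) is normalized
individually as LUC/hRLUC, construct means are scaled so the empty-vector
control is exactly 1, and the replicate-ratio SD is reported on the same
scale. Ratio-of-means is used for Ct aggregation but mean-of-ratios for
reporter replicates, matching what each measurement design implies.
Significance testing is out of scope; only descriptive dispersion is
produced.

## Problem sizes and determinism

The acceptance-level tests run 200 generated genes per fate (seeds 1–200,
zero classification errors required), 50 scanner-vs-exhaustive-oracle
introns, 100 NJ recoveries, one 10-kb oracle comparison plus a 10^6-offset
false-positive calibration for the AW-box scanner, and 100 Monte-Carlo ddCt
recoveries — sizes chosen to give tight statistical checks while the whole
suite completes in seconds on one CPU. All randomness flows through seeded
`numpy` generators; hypothesis profiles are derandomized.

## Known limitations

* Splice plausibility is terminal dinucleotides only; no branch point,
  polypyrimidine tract, or strength scoring. Real introns satisfying the
  rule need not be splicable.
* Locus classification assumes one motif locus per gene; multiple independent
  loci would be reported only through the first.
* The alternative-acceptor window (default 30 nt) bounds the excision search;
  replacements further downstream are not enumerated.
* p-distance + NJ is a reconstruction convenience, not a model-based
  phylogeny; no bootstrap or rate modeling is provided.
* The edge-peptide (replacement) call uses the candidate's phase at the
  adjacent exon's 5' edge; exotic geometries (replacement at a 3' edge of the
  upstream exon) are detected as edge matches but not typed as replacements.
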