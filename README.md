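# microtrace

Detection of conserved-motif **micro-exons** and their evolutionary fates in
annotated protein-coding genes, with the companion analyses used in studies of
WRI1-class AP2-domain transcription factors.

## The problem

WRINKLED1 (WRI1), the master regulator of plant fatty-acid synthesis, carries a
conserved Val-Tyr-Leu (**VYL**) tripeptide inside its first AP2 DNA-binding
domain. In most plants those nine nucleotides form an independent **9-bp
micro-exon** whose codons are split across the flanking splice junctions
(typically the upstream exon supplies the first nucleotide of the V codon).
Across homologs the locus can take several fates:

* **independent micro-exon** — a short annotated exon flanked by a canonical
  AG acceptor and GT (or GC) donor;
* **fused exon edge** (intron loss) — the motif coding sits at an exon's 5' or
  3' edge with no intronic trace;
* **trace in intron** (atypical splicing) — the annotated transcript carries a
  *replacement* peptide (e.g. GCL) at the exon edge, while the intron still
  contains the ancestral micro-exon sandwiched between AG and GT; splicing it
  back in with a nearby alternative AG acceptor restores the motif exactly;
* **absent** — no motif coding at the locus.

`microtrace` formalizes this reasoning: it scans introns for AG-[core]-donor
windows that, together with the flanking exon context and some codon phase,
encode a query peptide motif; classifies each gene's locus; and enumerates the
donor…AG-consistent splice variants with their peptide consequences. Splice
plausibility is terminal dinucleotides only — exactly the enumerative argument
used in the field, with no branch-point or scoring model.

Supporting modules cover the rest of a typical study: an **AW-box** scanner
(the WRI1-binding consensus `CnTnG(n)7CG`, a 14-mer with five fixed
positions), motif-region extraction from a protein MSA with p-distance +
neighbor-joining trees, a classical **2^-ddCt** qPCR calculator and a
dual-luciferase reporter normalizer, and a synthetic-data generator that
plants each fate with known truth for end-to-end validation.

## Worked example

Generate a trace-state gene — annotated GCL at the third exon's 5' edge, a
VYL-encoding micro-exon hidden in intron 2 — then scan and classify it:

```bash
$ microtrace simulate --state trace --seed 7 --out demo
$ microtrace scan --fasta demo/genes.fasta --gff demo/genes.gff3 --motif VYL
gene_id	state	core_start_tis	core_end_tis	core_sequence	diff	n_variants
synth_trace_7	trace_in_intron	1628	1636	TTTATCTAG	VYL→GCL	3
```

Reading the row: the locus is classified `trace_in_intron`; the 9-bp candidate
micro-exon occupies nucleotides +1628..+1636 counted from the translation
initiation site (unspliced numbering, +1 = the A of ATG, no position 0); the
core `TTTATCTAG` plus one upstream exon nucleotide reads `G|TT TAT CTA|G…` =
VYL with one nucleotide handed to the downstream codon; the annotated edge
peptide is GCL, so the inferred substitution is `VYL→GCL`. Three splice
variants are enumerated: the reference, the motif-restoring alternative
acceptor (peptide diff `GCL→VYL`, all else identical), and a frame-shifting
acceptor retained but flagged as truncating.

The same analysis from Python:

```python
from microtrace import GeneSpec, generate_gene, classify_locus, enumerate_splice_variants

genome, gene, truth = generate_gene(GeneSpec(planted_state="trace", seed=7))
cls = classify_locus(gene, genome, "VYL")
print(cls.state, cls.diff)            # trace_in_intron VYL→GCL
for v in enumerate_splice_variants(gene, genome, cls):
    print(v.label, v.diff_vs_reference)
```

Other subcommands: `genes` (structure summary), `awbox` (BED-like AW-box
hits), `motif-table` (per-homolog motif region and variant label from an MSA),
`tree` (p-distance neighbor-joining, newick), `ddct`, `reporter`, and `run`
(full pipeline from a YAML config with a checksummed manifest).

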