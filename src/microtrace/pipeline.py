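"""End-to-end orchestration: FASTA + GFF3 in, classification reports out.

Reports are deterministic functions of the config and inputs: a
grep-able TSV, a JSON machine twin with full evidence, and a manifest
recording the config, package version and input checksums (no
timestamps, so reruns are byte-identical).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .codonmap import PeptideMotif
from .errors import FormatError
from .genemodel import read_fasta, read_gff3
from .microexon import ScanConfig, classify_locus, enumerate_splice_variants

log = logging.getLogger("microtrace")

TSV_COLUMNS = [
    "gene_id",
    "state",
    "warning",
    "intron_index",
    "core_start_tis",
    "core_end_tis",
    "core_sequence",
    "length",
    "phase_in",
    "phase_out",
    "diff",
    "n_variants",
]


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    fasta: str
    gff: str
    out_dir: str
    motif: str = "VYL"
    donors: tuple[str, ...] = ("GT",)
    min_core: int = 3
    max_core: int = 30
    acceptor_window: int = 30
    replacement_motifs: list[str] | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.donors = tuple(self.donors)
        PeptideMotif(self.motif)  # validates

    def scan_config(self) -> ScanConfig:
        return ScanConfig(
            donors=self.donors,
            min_core=self.min_core,
            max_core=self.max_core,
            acceptor_window=self.acceptor_window,
        )

    def validate_paths(self) -> None:
        for path in (self.fasta, self.gff):
            if not os.path.exists(path):
                raise FormatError(f"input file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = dataclasses.asdict(self)
        d["donors"] = list(d["donors"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Classify every gene and enumerate its splice variants.

    Returns the paths of the written reports.  An empty GFF3 yields an
    empty (header-only) report with a warning, not an error.
    """
    logging.basicConfig(level=config.log_level)
    config.validate_paths()
    scan_cfg = config.scan_config()
    seqs = {s.id: s for s in read_fasta(config.fasta)}
    genes = read_gff3(config.gff)
    if not genes:
        log.warning("no gene features in %s; writing empty report", config.gff)

    rows = []
    evidence = []
    for gene in genes:
        if gene.seq_id not in seqs:
            raise FormatError(
                f"gene {gene.gene_id!r} refers to missing sequence {gene.seq_id!r}"
            )
        genome = seqs[gene.seq_id]
        log.info("classifying %s", gene.gene_id)
        cls = classify_locus(
            gene, genome, config.motif, config.replacement_motifs, scan_cfg
        )
        variants = enumerate_splice_variants(gene, genome, cls, scan_cfg)
        c = cls.candidates[0] if cls.candidates else None
        rows.append(
            {
                "gene_id": gene.gene_id,
                "state": cls.state,
                "warning": cls.warning,
                "intron_index": c.intron_index if c else "",
                "core_start_tis": c.core_start if c else "",
                "core_end_tis": c.core_end if c else "",
                "core_sequence": c.core_sequence if c else "",
                "length": c.length if c else "",
                "phase_in": c.phase_in if c else "",
                "phase_out": c.phase_out if c else "",
                "diff": cls.diff or "",
                "n_variants": len(variants),
            }
        )
        evidence.append(
            {
                "gene_id": gene.gene_id,
                "state": cls.state,
                "warning": cls.warning,
                "diff": cls.diff,
                "replacement_peptide": cls.replacement_peptide,
                "edge": cls.edge,
                "edge_exon_index": cls.edge_exon_index,
                "candidates": [dataclasses.asdict(x) for x in cls.candidates],
                "variants": [
                    {
                        "label": v.label,
                        "exon_chain": [list(iv) for iv in v.exon_chain],
                        "used_sites": [
                            [list(d), list(a)] for d, a in v.used_sites
                        ],
                        "peptide": v.peptide,
                        "diff_vs_reference": v.diff_vs_reference,
                        "is_reference": v.is_reference,
                        "has_internal_stop": v.has_internal_stop,
                    }
                    for v in variants
                ],
            }
        )

    os.makedirs(config.out_dir, exist_ok=True)
    tsv_path = os.path.join(config.out_dir, "report.tsv")
    json_path = os.path.join(config.out_dir, "report.json")
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(evidence, fh, indent=1, sort_keys=True)
        fh.write("\n")
    cfg = dataclasses.asdict(config)
    cfg["donors"] = list(cfg["donors"])
    manifest = {
        "config": cfg,
        "version": __version__,
        "inputs": {
            "fasta": {"path": config.fasta, "sha256": _sha256(config.fasta)},
            "gff": {"path": config.gff, "sha256": _sha256(config.gff)},
        },
        "n_genes": len(genes),
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"tsv": tsv_path, "json": json_path, "manifest": manifest_path}
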