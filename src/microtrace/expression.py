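"""Relative-expression calculators.

Two small, exactly-specified computations:

* the classical ddCt method for qPCR (amplification efficiency fixed at
  2, fold change ``2**-ddCt`` relative to a reference gene and a
  calibrator sample), and
* dual-luciferase reporter normalization (firefly LUC divided by the
  hRLUC internal control per replicate, then scaled to an empty-vector
  control construct).

Aggregation follows the cited conventions: Ct values are averaged per
(sample, gene) before ratios are formed, whereas reporter replicates are
independent transfections and are averaged as per-replicate ratios.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, InvariantError

CT_COLUMNS = ("sample", "gene", "replicate", "ct")


@dataclass
class CtTable:
    """Long-format Ct measurements plus the normalization anchors."""

    data: pd.DataFrame
    reference_gene: str
    calibrator_sample: str

    def __post_init__(self) -> None:
        missing = set(CT_COLUMNS) - set(self.data.columns)
        if missing:
            raise FormatError(f"Ct table lacks columns {sorted(missing)}")
        ct = self.data["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
            raise InvariantError("Ct values must be finite and positive")
        samples = set(self.data["sample"])
        if self.calibrator_sample not in samples:
            raise InvariantError(
                f"calibrator sample {self.calibrator_sample!r} absent from table"
            )
        for s in samples:
            genes = set(self.data.loc[self.data["sample"] == s, "gene"])
            if self.reference_gene not in genes:
                raise InvariantError(
                    f"reference gene {self.reference_gene!r} missing in sample {s!r}"
                )

    @classmethod
    def read(
        cls,
        path: str | os.PathLike,
        reference_gene: str,
        calibrator_sample: str,
        sep: str = "\t",
    ) -> "CtTable":
        return cls(pd.read_csv(path, sep=sep), reference_gene, calibrator_sample)


@dataclass(frozen=True)
class RelativeExpression:
    """One sample x gene fold change, ``2**-ddCt``, with dispersion."""

    sample: str
    gene: str
    fold_change: float
    delta_ct: float
    delta_delta_ct: float
    sd_delta_ct: float  # on the Ct scale
    fold_low: float
    fold_high: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise InvariantError("fold change must be positive")


def delta_delta_ct(table: CtTable) -> list[RelativeExpression]:
    """Fold changes for every non-reference gene in every sample.

    dCt = mean Ct(gene) − mean Ct(reference) within the sample;
    ddCt = dCt(sample) − dCt(calibrator); fold = 2**−ddCt.  The reported
    SD is sqrt(s²_gene/n + s²_ref/n) on the Ct scale (variance of each
    replicate mean), and the fold interval is 2**−(ddCt ± SD).  The
    calibrator sample's fold change is exactly 1.
    """
    df = table.data
    stats = (
        df.groupby(["sample", "gene"])["ct"]
        .agg(["mean", "var", "count"])
        .reset_index()
    )
    stats["var"] = stats["var"].fillna(0.0)  # single replicate
    by_sample: dict[str, pd.DataFrame] = {
        s: g.set_index("gene") for s, g in stats.groupby("sample")
    }
    ref = table.reference_gene
    for s, g in by_sample.items():
        if ref not in g.index:
            raise InvariantError(f"reference gene missing in sample {s!r}")

    def _dct(sample: str, gene: str) -> tuple[float, float]:
        g = by_sample[sample]
        dct = float(g.loc[gene, "mean"] - g.loc[ref, "mean"])
        var = float(
            g.loc[gene, "var"] / g.loc[gene, "count"]
            + g.loc[ref, "var"] / g.loc[ref, "count"]
        )
        return dct, var

    out: list[RelativeExpression] = []
    for sample in sorted(by_sample):
        for gene in by_sample[sample].index:
            if gene == ref:
                continue
            if gene not in by_sample[table.calibrator_sample].index:
                raise InvariantError(
                    f"gene {gene!r} absent from calibrator sample "
                    f"{table.calibrator_sample!r}"
                )
            dct, var = _dct(sample, gene)
            dct_cal, _ = _dct(table.calibrator_sample, gene)
            ddct = dct - dct_cal
            sd = math.sqrt(var)
            out.append(
                RelativeExpression(
                    sample=sample,
                    gene=gene,
                    fold_change=2.0 ** -ddct,
                    delta_ct=dct,
                    delta_delta_ct=ddct,
                    sd_delta_ct=sd,
                    fold_low=2.0 ** -(ddct + sd),
                    fold_high=2.0 ** -(ddct - sd),
                )
            )
    return out


def expression_to_dataframe(rows: list[RelativeExpression]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass(frozen=True)
class ReporterReading:
    """One transfection replicate of a dual-luciferase assay."""

    construct: str
    replicate: int
    luc: float
    hrluc: float

    def __post_init__(self) -> None:
        if not self.hrluc > 0:
            raise InvariantError("hRLUC activity must be positive")


@dataclass(frozen=True)
class ReporterRatio:
    construct: str
    relative_ratio: float
    sd: float
    n: int


def relative_ratio(
    readings: list[ReporterReading], control_construct: str
) -> list[ReporterRatio]:
    """Per-construct mean LUC/hRLUC scaled so the control construct is 1.

    Each replicate is normalized individually (mean of ratios); the SD is
    the replicate-ratio SD on the same relative scale.
    """
    per: dict[str, list[float]] = {}
    for r in readings:
        per.setdefault(r.construct, []).append(r.luc / r.hrluc)
    if control_construct not in per:
        raise InvariantError(f"control construct {control_construct!r} missing")
    control_mean = float(np.mean(per[control_construct]))
    out = []
    for construct in sorted(per):
        ratios = np.asarray(per[construct], dtype=float)
        mean = float(ratios.mean())
        sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0
        out.append(
            ReporterRatio(
                construct=construct,
                relative_ratio=mean / control_mean,
                sd=sd / control_mean,
                n=len(ratios),
            )
        )
    return out


def read_reporter_table(
    path: str | os.PathLike, sep: str = "\t"
) -> list[ReporterReading]:
    df = pd.read_csv(path, sep=sep)
    missing = {"construct", "replicate", "luc", "hrluc"} - set(df.columns)
    if missing:
        raise FormatError(f"reporter table lacks columns {sorted(missing)}")
    return [
        ReporterReading(str(r.construct), int(r.replicate), float(r.luc), float(r.hrluc))
        for r in df.itertuples()
    ]
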