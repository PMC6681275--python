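"""Shared fixtures: deterministic synthetic genes in each planted state."""

import pytest
from hypothesis import settings

from microtrace import GeneSpec, generate_gene

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")

#: the motif codons that reproduce the canonical printed splice junction
#: (V=GTC, Y=TAT, L=TTG -> micro-exon core TCTATTTGG between AG and GT)
CANONICAL_VYL_CODONS = ("GTC", "TAT", "TTG")


@pytest.fixture(scope="session")
def trace_gene():
    """Trace-state gene whose second intron carries AGTCTATTTGGGT."""
    return generate_gene(
        GeneSpec(
            planted_state="trace",
            motif="VYL",
            replacement="GCL",
            motif_codons=CANONICAL_VYL_CODONS,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def micro_gene():
    return generate_gene(GeneSpec(planted_state="micro", seed=11))


@pytest.fixture(scope="session")
def fused_gene():
    return generate_gene(GeneSpec(planted_state="fused", seed=11))


@pytest.fixture(scope="session")
def absent_gene():
    return generate_gene(GeneSpec(planted_state="absent", seed=11))
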