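import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from peff import simdata


@pytest.fixture(scope="session")
def tiny_reference():
    """20 kb single-contig reference with 4 annotated genes."""
    return simdata.generate_reference(
        n_contigs=1, contig_length=20_000, n_genes=4, gene_length=800, seed=42
    )


@pytest.fixture(scope="session")
def tiny_population(tiny_reference):
    """10 accessions segregating for one 60 bp presence/absence segment."""
    locus = simdata.CausalLocus("contig1", 9_000, 60, 0.5, 1.5, name="causal")
    spec = simdata.PopulationSpec(10, [locus], snp_rate=0.0, seed=7)
    return simdata.simulate_population(tiny_reference, spec)
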