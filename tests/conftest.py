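import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from isoratio import ExonCounts, GeneModel, SimConfig, build_gene_model


@pytest.fixture(scope="session")
def uniform_model() -> GeneModel:
    """15 exons of 100 bp, variant starting at exon 10: L0=1500, L1=600."""
    return build_gene_model(SimConfig())


@pytest.fixture()
def make_counts():
    def _make(values, sample_id="s1", total=10**6):
        return ExonCounts(sample_id=sample_id, counts=np.asarray(values),
                          total_mapped_reads=total)
    return _make
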