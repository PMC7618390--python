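import numpy as np
import pandas as pd
import pytest

from apcrisk.cds import DEFAULT_REGIONS, INDEL_TYPES, SBS96_TYPES, CdsContext
from apcrisk.simulate import default_hit_probabilities, generate_cds


@pytest.fixture(scope="session")
def apc_regions_ctx():
    """Full-length dummy CDS carrying the canonical APC region table."""
    return CdsContext("ATG" * 1700, regions=dict(DEFAULT_REGIONS))


@pytest.fixture(scope="session")
def toy_ctx():
    """Deterministic 60-codon CDS with a 7-T homopolymer run in its R3."""
    return generate_cds(60, seed=11, homopolymer_runs=(("T", 7, 52),))


@pytest.fixture(scope="session")
def hit_probs():
    return default_hit_probabilities()


def uniform_sbs_signature(name="U"):
    return pd.DataFrame({name: np.full(96, 1 / 96)}, index=list(SBS96_TYPES))


def uniform_indel_signature(name="U"):
    return pd.DataFrame({name: np.full(71, 1 / 71)}, index=list(INDEL_TYPES))


def delta_signature(mutation_type, catalogue, name="D"):
    col = pd.Series(0.0, index=list(catalogue))
    col[mutation_type] = 1.0
    return col.to_frame(name)


def single_exposure(name="U"):
    return pd.DataFrame({name: [1.0]}, index=["s1"])
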