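import numpy as np
import pytest

from almask import default_params
from almask.msa_io import Alignment


@pytest.fixture(scope="session")
def params120():
    return default_params(120)


@pytest.fixture(scope="session")
def params250():
    return default_params(250)


@pytest.fixture(scope="session")
def params4(params120):
    """Pair-HMM params over a reduced 4-letter alphabet (A, C, D, E).

    Restriction of the PAM120 joint emissions, renormalised; sequences for
    these params are integer arrays over 0..3.
    """
    joint = params120.match_emission[:4, :4].copy()
    joint = (joint + joint.T) / 2.0
    joint /= joint.sum()
    bg = params120.gap_emission[:4].copy()
    bg /= bg.sum()
    return params120.with_match_emission(joint, bg)


@pytest.fixture
def tiny_alignment():
    return Alignment(("s1", "s2", "s3"), ("AC-DE", "A-CDE", "ACCDE"))


@pytest.fixture(scope="session")
def small_family():
    """A deterministic 6-sequence simulated family (cached per session)."""
    from almask import simulate_family

    aln, ungapped, cfg = simulate_family(
        n_taxa=6, root_length=80, divergence=0.8, seed=42
    )
    return aln
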