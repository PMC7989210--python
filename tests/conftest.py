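import numpy as np
import pandas as pd
import pytest

from hcmomics import synthio

VAR_CLASSES = ("snv", "duplication", "splice_acceptor_snv")


@pytest.fixture(scope="session", params=VAR_CLASSES)
def template(request):
    return synthio.make_locus_template(request.param)


@pytest.fixture(scope="session")
def templates():
    return {vc: synthio.make_locus_template(vc) for vc in VAR_CLASSES}


@pytest.fixture(scope="session")
def small_omics():
    """A small planted-factor study reused across o2pls tests."""
    return synthio.simulate_multiomics(
        n_samples=24, p_regions=120, q_genes=80, joint_rank=1,
        group_effect=2.0, n_de=20, de_loading_boost=5.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
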