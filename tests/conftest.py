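import numpy as np
import pandas as pd
import pytest

from oetomics import GeneratorConfig, generate_bundle, truth_report
from oetomics import preprocess as pp


@pytest.fixture(scope="session")
def bundle0():
    """Zero measurement noise: every planted structure is exactly recoverable."""
    cfg = GeneratorConfig(
        n_genes=300, noise_sd=0.0, seed=11, n_zero_rna=10, allele_fraction=0.15
    )
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def truth0(bundle0):
    return truth_report(bundle0)


@pytest.fixture(scope="session")
def corrected0(bundle0):
    factors = pp.compute_batch_factors(bundle0.protein)
    return pp.apply_batch_correction(bundle0.protein, factors)


@pytest.fixture(scope="session")
def averaged0(bundle0, corrected0):
    """Stage-averaged (protein, rpf, mrna) triple at zero noise."""
    return (
        pp.merge_replicates(corrected0),
        pp.merge_replicates(bundle0.rpf),
        pp.merge_replicates(bundle0.mrna),
    )


@pytest.fixture(scope="session")
def bundle_noisy():
    cfg = GeneratorConfig(n_genes=300, noise_sd=0.1, seed=23)
    return generate_bundle(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
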