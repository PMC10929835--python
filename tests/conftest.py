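import warnings

import pytest

from cupscore.preprocess import batch_correct
from cupscore.synth import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort, seed 1: (expr, clinical, maf, cnv, truth)."""
    return generate_cohort(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def corrected_expr(default_cohort):
    expr = default_cohort[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return batch_correct(expr)
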