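import numpy as np
import pytest

import endophen as ep


@pytest.fixture(scope="session")
def fixture_cohort():
    return ep.fixture_cohort(seed=0)


@pytest.fixture(scope="session")
def small_expression():
    """A light-weight simulated expression dataset shared across tests."""
    cfg = ep.ExpressionSimConfig(n_genes=1500, target_set_size=40, seed=11)
    return ep.gen_expression(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_es(ordered_in_set):
    """Independent ECDF-scan oracle for the signed enrichment score.

    A literal loop over the ranked list, recomputing both ECDFs at every
    position and keeping the deviation of largest magnitude.
    """
    flags = list(ordered_in_set)
    m = sum(flags)
    n = len(flags) - m
    seen_set = seen_rest = 0
    d_plus = d_minus = 0.0
    for f in flags:
        if f:
            seen_set += 1
        else:
            seen_rest += 1
        diff = seen_set / m - seen_rest / n
        d_plus = max(d_plus, diff)
        d_minus = max(d_minus, -diff)
    return d_plus if d_plus >= d_minus else -d_minus
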