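"""Shared fixtures: expensive phantom generations are session-scoped so
the suite pays for each of them once."""

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from ctecv import phantom as ph  # noqa: E402


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, aligned, texture-free phantom: exact intensity checks."""
    spec = ph.PhantomSpec(noise_sd=0.0, texture_sd_hu=0.0)
    pre, delayed, truth = ph.generate_paired_ct(spec)
    return spec, pre, delayed, truth


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noiseless, aligned phantom with the default texture."""
    spec = ph.PhantomSpec(noise_sd=0.0)
    pre, delayed, truth = ph.generate_paired_ct(spec)
    return spec, pre, delayed, truth


@pytest.fixture()
def rng():
    # function-scoped: every test draws from its own fresh, seeded stream,
    # so outcomes do not depend on test execution order
    return np.random.default_rng(20240901)
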