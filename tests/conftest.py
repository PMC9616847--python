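from __future__ import annotations

import pytest

from deg_netprior.synthetic_data import SyntheticSpec, generate


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic bundle shared across read-only tests."""
    return generate(SyntheticSpec(seed=11))


@pytest.fixture()
def small_spec():
    return SyntheticSpec(n_genes=100, frac_up=0.2, frac_down=0.2, seed=7)
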