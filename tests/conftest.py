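import numpy as np
import pandas as pd
import pytest

from histoptm.peptidoforms import default_histone_library
from histoptm.synthetic import SampleDesign


@pytest.fixture(scope="session")
def library():
    return default_histone_library()


@pytest.fixture(scope="session")
def h4_family(library):
    return [p for p in library if p.family == "H4:4-17"]


@pytest.fixture
def design():
    return SampleDesign(seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_area_table(rng, n_families=3, forms_per_family=4, n_samples=5):
    """A random positive area table with synthetic family-structured keys."""
    keys = [
        f"H{f % 2 + 3}:{10 * f + 1}-{10 * f + 9}:K{10 * f + 2 + m}me{m % 3 + 1}"
        for f in range(n_families)
        for m in range(forms_per_family)
    ]
    data = rng.lognormal(10, 1, size=(len(keys), n_samples))
    cols = [f"TP{j}.A.1" for j in range(n_samples)]
    return pd.DataFrame(data, index=keys, columns=cols)
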