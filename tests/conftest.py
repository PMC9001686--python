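import numpy as np
import pytest

from lindnet import BathParameters, build_fmo_hamiltonian, build_generator
from lindnet.pipeline import make_fixtures


@pytest.fixture(scope="session")
def fmo():
    return build_fmo_hamiltonian()


@pytest.fixture(scope="session")
def micro():
    """Deterministic micro-pipeline: 2x2x2 grid, 1 ps horizons, 1-epoch model."""
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def gen_factory(fmo):
    cache = {}

    def make(lam, gamma, temperature, **kw):
        key = (lam, gamma, temperature, tuple(sorted(kw.items())))
        if key not in cache:
            cache[key] = build_generator(
                fmo, BathParameters(lam, gamma, temperature), **kw
            )
        return cache[key]

    return make


class ZeroModel:
    """Duck-typed stand-in predicting all-zero rows (metric oracle tests)."""

    def predict_rows(self, X):
        return np.zeros((len(X), 13))
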