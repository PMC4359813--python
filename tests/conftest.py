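import numpy as np
import pytest

from bloodassign import BloodType
from bloodassign.blood_types import TYPE_ORDER


def counts(**kwargs):
    """Mapping builder: counts(O_POS=4, a=2) -> {BloodType: int}."""
    out = {}
    for key, n in kwargs.items():
        t = BloodType[key] if len(key) > 1 else BloodType(key)
        out[t] = n
    return out


def random_instance(rng, max_units=30, max_stock=30):
    """A random day instance: per-type demands and stock."""
    dem = rng.multinomial(int(rng.integers(1, max_units + 1)), np.ones(8) / 8)
    st = rng.multinomial(int(rng.integers(0, max_stock + 1)), np.ones(8) / 8)
    requests = {t: int(dem[i]) for i, t in enumerate(TYPE_ORDER)}
    stock = {t: int(st[i]) for i, t in enumerate(TYPE_ORDER)}
    return requests, stock


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
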