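import numpy as np
import pandas as pd
import pytest

from hetvar import pedigree as pm
from hetvar import synthetic_data as sd


def make_pedigree(rows):
    """rows: (animal, sire, dam[, birth_date, f1])"""
    out = []
    for r in rows:
        animal, sire, dam = r[:3]
        bd = r[3] if len(r) > 3 else pd.Timestamp("2005-01-01")
        f1 = r[4] if len(r) > 4 else 0.5
        out.append((animal, sire, dam, bd, f1, 1.0 - f1))
    return pd.DataFrame(
        out, columns=["animal", "sire", "dam", "birth_date", "frac_breed1", "frac_breed2"]
    )


def random_pedigree(rng, n_max=12):
    """Random acyclic pedigree: each animal's parents are earlier animals or unknown."""
    n = int(rng.integers(3, n_max + 1))
    rows = []
    for i in range(1, n + 1):
        if i <= 2 or rng.random() < 0.3:
            s = d = 0
        else:
            s = int(rng.integers(1, i))
            d = int(rng.integers(1, i))
            if d == s:
                d = 0
        rows.append((i, s, d))
    return make_pedigree(rows)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but structured simulated dataset shared by fast tests."""
    truth = sd.TrueParameters(seed=77)
    return sd.simulate(truth, n_sires=12, daughters_per_sire=12, n_herds=8)


@pytest.fixture(scope="session")
def trio_structure():
    ped = make_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2)])
    rs = pm.renumber(ped)
    pm.compute_inbreeding(rs)
    return rs
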