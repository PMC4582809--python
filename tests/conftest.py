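import numpy as np
import pandas as pd
import pytest

from confusel import NormGenConfig, PropertyNorms, gen_property_norms


@pytest.fixture
def toy_norms() -> PropertyNorms:
    """Six concepts, hand-laid-out features: f_all in all six concepts,
    f_pair identical column to f_all2 (r=1), one unique feature each."""
    concepts = [f"c{i}" for i in range(6)]
    features = ["f_all", "f_all2", "f_some"] + [f"u{i}" for i in range(6)]
    pf = np.zeros((6, 9), dtype=int)
    col = np.array([3, 1, 4, 1, 5, 9])
    pf[:, 0] = col
    pf[:, 1] = 2 * col  # proportional -> r = 1 with f_all
    pf[:3, 2] = [2, 7, 1]  # in 3 concepts only
    for i in range(6):
        pf[i, 3 + i] = 5
    return PropertyNorms(concepts, features, pf,
                         domain=["living"] * 3 + ["nonliving"] * 3)


@pytest.fixture
def random_norms() -> PropertyNorms:
    """Random 8-concept x 15-feature norms for oracle-equivalence checks."""
    rng = np.random.default_rng(42)
    pf = rng.integers(0, 6, size=(8, 15))
    # guarantee every concept and feature is non-empty
    for i in range(8):
        if not pf[i].any():
            pf[i, i] = 1
    for j in range(15):
        if not pf[:, j].any():
            pf[j % 8, j] = 2
    return PropertyNorms(
        [f"c{i}" for i in range(8)], [f"f{j}" for j in range(15)], pf,
        domain=["living"] * 4 + ["nonliving"] * 4,
    )


@pytest.fixture(scope="session")
def default_norms() -> PropertyNorms:
    return gen_property_norms(NormGenConfig(seed=1))


@pytest.fixture
def norms_csv(tmp_path):
    path = tmp_path / "norms.csv"
    path.write_text(
        "concept,feature,production_frequency,domain\n"
        "A,f1,10,living\nA,f2,5,living\nB,f1,7,nonliving\n"
    )
    return path
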