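import numpy as np
import pandas as pd
import pytest


def _window(center: str, plus1: str = "A", minus2: str = "A", plus2: str = "A") -> str:
    w = list("AAAAAAAAAAAAAAA")
    w[7] = center
    w[8] = plus1
    w[5] = minus2
    w[9] = plus2
    return "".join(w)


@pytest.fixture
def toy_six_site_table() -> pd.DataFrame:
    """Six hand-constructed sites for the cascade: 3 match the minimal Cdk1
    consensus; of those, 2 reach mean log2 >= 1; of those, 1 has p < 0.1.

    Enumerated by hand: s1 mean 1.5, sd 0.08 -> p ~= 4e-5; s2 mean exactly
    1.0, sd 1.29 -> p ~= 0.22; s3 mean 0.05; s4/s5 lack the +1 proline;
    s6 is phosphotyrosine (never matches) with zero replicate variance.
    """
    rows = [
        ("P1", 10, "S", _window("S", "P"), [1.5, 1.6, 1.4, 1.5]),
        ("P2", 20, "T", _window("T", "P"), [2.5, -0.5, 1.5, 0.5]),
        ("P3", 30, "S", _window("S", "P"), [0.1, -0.1, 0.2, 0.0]),
        ("P4", 40, "S", _window("S", "A"), [1.5, 1.5, 1.6, 1.4]),
        ("P5", 50, "T", _window("T", "G"), [0.0, 0.1, -0.1, 0.0]),
        ("P6", 60, "Y", _window("Y", "P"), [2.0, 2.0, 2.0, 2.0]),
    ]
    table = pd.DataFrame(
        {
            "protein_id": [r[0] for r in rows],
            "gene": [r[0] for r in rows],
            "position": [r[1] for r in rows],
            "residue": [r[2] for r in rows],
            "window": [r[3] for r in rows],
            "loc_prob": 0.99,
        }
    )
    ratios = np.array([r[4] for r in rows])
    for j in range(4):
        table[f"log2_ratio_rep{j + 1}"] = ratios[:, j]
    return table


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
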