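import numpy as np
import pandas as pd
import pytest

from assemblage.metadata import SampleMetadata
from assemblage.otu import OtuTable


@pytest.fixture
def small_table() -> OtuTable:
    counts = np.array([
        [5, 0, 3, 1],
        [2, 4, 3, 1],
        [1, 1, 2, 6],
    ])
    return OtuTable(counts, ["s1", "s2", "s3"], ["o1", "o2", "o3", "o4"])


@pytest.fixture
def tax_table() -> OtuTable:
    counts = np.array([
        [4, 4, 2],
        [1, 1, 8],
    ])
    return OtuTable(
        counts, ["s1", "s2"], ["o1", "o2", "o3"],
        taxonomy=["Eukaryota;Alveolata;Ciliophora",
                  "Eukaryota;Stramenopiles",
                  "Eukaryota;Alveolata;Dinoflagellata"],
    )


@pytest.fixture
def transect_metadata() -> SampleMetadata:
    n = 8
    frame = pd.DataFrame({
        "habitat": ["water"] * (n // 2) + ["sediment"] * (n // 2),
        "longitude": np.linspace(118.0, 118.2, n),
        "latitude": [24.5] * n,
        "temperature": np.linspace(28.0, 34.0, n),
        "pH": np.linspace(8.0, 9.0, n),
        "TN": np.linspace(0.5, 3.0, n),
    }, index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"))
    return SampleMetadata(frame)


def random_table(rng: np.random.Generator, n_samples: int = 6,
                 n_otus: int = 40, depth: int = 1000) -> OtuTable:
    p = rng.dirichlet(np.full(n_otus, 0.3))
    counts = np.vstack([rng.multinomial(depth, p) for _ in range(n_samples)])
    return OtuTable(counts,
                    [f"s{i}" for i in range(n_samples)],
                    [f"o{j}" for j in range(n_otus)])
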