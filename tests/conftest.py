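import numpy as np
import pytest

from nmfselect.dataset import ClinicalDataset


@pytest.fixture
def tiny_ds() -> ClinicalDataset:
    """Four samples, three symptoms, all label kinds present."""
    return ClinicalDataset(
        values=np.array(
            [
                [0, 1, 2],
                [1, 0, 3],
                [0, 2, 0],
                [2, 1, 1],
            ]
        ),
        symptom_ids=["V1", "V2", "V3"],
        sample_ids=["S1", "S2", "S3", "S4"],
        stage=np.array([1, 1, 2, 2]),
        substage=["IA", "IB", "IIA", "IIB"],
        sex=np.array([0, 1, 0, 1]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_dataset(seed: int, p: int = 12, n: int = 5) -> ClinicalDataset:
    rng = np.random.default_rng(seed)
    values = rng.integers(0, 4, size=(p, n))
    values[:, 0] = np.arange(p) % 4  # guarantee at least one varying column
    stage = rng.integers(1, 4, size=p)
    return ClinicalDataset(
        values=values,
        symptom_ids=[f"V{j + 1}" for j in range(n)],
        sample_ids=[f"S{i + 1}" for i in range(p)],
        stage=stage,
        sex=rng.integers(0, 2, size=p),
    )
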