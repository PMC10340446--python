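import numpy as np
import pytest

from pneumoscope.data import DatasetSplit, Radiograph
from pneumoscope.synthetic import SynthConfig, generate_anomalous, generate_normal


def as_radiographs(arr: np.ndarray, label: str, tag: str) -> list[Radiograph]:
    return [Radiograph(a, f"{tag}{i:04d}", label) for i, a in enumerate(arr)]


@pytest.fixture(scope="session")
def small_synth():
    """A small normal/anomalous image pair of sets shared across tests."""
    cfg = SynthConfig(n_normal=60, n_anomalous=30, seed=123)
    return cfg, generate_normal(cfg), generate_anomalous(cfg)


@pytest.fixture(scope="session")
def tiny_split(small_synth) -> DatasetSplit:
    """One-class split over synthetic normals, anomalies as test_other."""
    _, normals, anoms = small_synth
    return DatasetSplit(
        train=as_radiographs(normals[:32], "negative", "tr"),
        validation=as_radiographs(normals[32:48], "negative", "va"),
        test_same=as_radiographs(normals[48:], "negative", "ts"),
        test_other=as_radiographs(anoms, "positive", "an"),
        scenario="train_neg",
    )


@pytest.fixture
def float64_layers():
    """Run the network stack in float64 (for finite-difference checks)."""
    import pneumoscope.layers as L
    saved = L.DTYPE
    L.DTYPE = np.float64
    yield
    L.DTYPE = saved
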