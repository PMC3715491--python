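import numpy as np
import pytest

from ggrs.barcodes import BarcodeSet, Barcode
from ggrs.digest import EnzymeSpec
from ggrs.simulate import SimConfig


@pytest.fixture
def avaii() -> EnzymeSpec:
    return EnzymeSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_barcode_set() -> BarcodeSet:
    return BarcodeSet(
        [
            Barcode("s1", "ACGT"),
            Barcode("s2", "TTAGC"),
            Barcode("s3", "CATCAG"),
        ]
    )


@pytest.fixture
def small_sim_config() -> SimConfig:
    """A small but fully structured simulated experiment."""
    return SimConfig(
        seed=7,
        genome_length=40_000,
        n_individuals=8,
        mean_depth=10,
        error_rate=0.0,
    )


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
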