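import pytest

from knowyourdata.demux import BarcodeSpec
from knowyourdata.simulate import SimConfig, sim_genome


@pytest.fixture(scope="session")
def small_genome() -> str:
    """A 20 kb seeded random genome shared across tests."""
    return sim_genome(SimConfig(seed=11, genome_size=20_000))[0]


@pytest.fixture(scope="session")
def rad_specs() -> list[BarcodeSpec]:
    """Four samples, offsets 0-3, PstI-style TGCAG overhang.

    Barcode pairwise Hamming distance is >= 3 at zero shift, so one
    barcode error can never reach another sample's barcode.
    """
    overhang = "TGCAG"
    offsets = frozenset({0, 1, 2, 3})
    return [
        BarcodeSpec("S1", "ACGGTA", offsets, overhang),
        BarcodeSpec("S2", "CTTAGC", offsets, overhang),
        BarcodeSpec("S3", "GAACTG", offsets, overhang),
        BarcodeSpec("S4", "TGCGAT", offsets, overhang),
    ]
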