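import numpy as np
import pytest

from shiftprobe import Peak, PeakList, Residue
from shiftprobe.synthetic_data import SyntheticSpec


@pytest.fixture
def spec():
    """Default synthetic study design at a fixed seed."""
    return SyntheticSpec(seed=42)


@pytest.fixture
def small_peaklist():
    """A deterministic 50-peak list with intensities."""
    rng = np.random.default_rng(7)
    peaks = PeakList(label="fixture")
    codes = "ACDEFGHIKL"
    for i in range(1, 51):
        peaks.add(
            Peak(
                Residue(i, codes[i % len(codes)]),
                delta_h=float(rng.uniform(7, 9.5)),
                delta_n=float(rng.uniform(105, 130)),
                intensity=float(rng.uniform(1e5, 1e6)),
            )
        )
    return peaks
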