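import numpy as np
import pandas as pd
import pytest

from methdev import synthetic_data as sd
from methdev.io_formats import make_sites_frame


@pytest.fixture(scope="session")
def small_dataset() -> sd.SimulatedDataset:
    """One reduced-scale synthetic dataset shared across the session."""
    return sd.simulate_dataset(sd.small_config(seed=11))


@pytest.fixture(scope="session")
def default_dataset() -> sd.SimulatedDataset:
    """Default-scale synthetic dataset (the generator's study conditions)."""
    return sd.simulate_dataset(sd.SimulationConfig(seed=7))


def sites_from_counts(pos, meth, total, chrom="chr1", strand="+") -> pd.DataFrame:
    """Tiny helper to build canonical site tables in tests."""
    n = len(pos)
    return make_sites_frame(np.full(n, chrom, dtype=object), pos,
                            np.full(n, strand, dtype=object), meth, total)
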