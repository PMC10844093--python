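import numpy as np
import pandas as pd
import pytest

from regnet.accessibility import TagCountMatrix
from regnet.synthetic_data import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_sim_config():
    """A scaled-down study: full planted program, quick to simulate."""
    return SimConfig(
        n_peaks=400,
        n_tfs=5,
        n_targets=60,
        n_edges=25,
        sites_per_edge=2,
        n_other_specific=40,
        n_common_peaks=40,
        n_proximal_peaks=10,
        n_down_genes=10,
        chrom_length=2_000_000,
        seed=11,
    )


def make_matrix(values, samples, peaks=None, groups=None, normalized=False):
    df = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=peaks or [f"pk{i}" for i in range(len(values))],
        columns=samples,
    )
    return TagCountMatrix(df, groups or {}, normalized=normalized)
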