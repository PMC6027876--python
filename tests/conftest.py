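import numpy as np
import pandas as pd
import pytest

from milletgs.containers import GenotypeMatrix


def make_gm(dosages, entry_type="hybrid", chrom="1", start_pos=100, entry_types=None):
    """Build a GenotypeMatrix from a 2-D array with auto-generated metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, k = dosages.shape
    marker_ids = pd.Index([f"m{j}" for j in range(k)], name="marker_id")
    markers = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": [start_pos + 10 * j for j in range(k)],
            "ref": "A",
            "alt": "T",
            "n_alleles": 2,
        },
        index=marker_ids,
    )
    entry_ids = pd.Index([f"s{i}" for i in range(n)], name="entry_id")
    entries = pd.DataFrame(
        {"entry_type": entry_types if entry_types is not None else entry_type},
        index=entry_ids,
    )
    return GenotypeMatrix(pd.DataFrame(dosages, index=entry_ids, columns=marker_ids),
                          markers, entries)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_study():
    """A small two-pool prediction study shared by several test modules."""
    from milletgs.experiments import simulate_prediction_study

    return simulate_prediction_study(
        n_b=15, n_r=15, n_markers=200, n_hybrids=80, n_qtl=40,
        dominance_ratio=0.5, h2=0.8, seed=101,
    )
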