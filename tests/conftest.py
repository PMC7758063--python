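import numpy as np
import pandas as pd
import pytest

import stratsim as st
from stratsim.genotype_sim import GenotypeDataset


def make_dataset(
    dosage,
    demes=None,
    rows=None,
    cols=None,
    positions=None,
    chroms=None,
    n_chrom=1,
    chrom_len=1_000_000.0,
):
    """Build a dense, genealogy-free dataset from an explicit dosage matrix.

    ``dosage`` is (n_individuals x n_variants); handy for exact-value
    unit tests where genotypes are chosen by hand.
    """
    D = np.asarray(dosage, dtype=np.int8)
    n, m = D.shape
    if demes is None:
        demes = np.zeros(n, dtype=int)
    demes = np.asarray(demes)
    if rows is None:
        rows = demes
    if cols is None:
        cols = np.zeros(n, dtype=int)
    if positions is None:
        positions = np.arange(m, dtype=float) * 1000.0
    if chroms is None:
        chroms = np.zeros(m, dtype=np.int32)
    dac = D.sum(axis=0, dtype=np.int64)
    samples = pd.DataFrame(
        {"individual": np.arange(n), "deme": demes, "row": rows, "col": cols}
    )
    variants = pd.DataFrame(
        {
            "chrom": np.asarray(chroms, dtype=np.int32),
            "pos": np.asarray(positions, dtype=float),
            "dac": dac,
            "frequency": dac / (2 * n),
        }
    )
    return GenotypeDataset(
        samples,
        variants,
        None,
        st.GenomeSpec(n_chrom, chrom_len),
        dosage_cache=D,
    )


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture(scope="session")
def grid22_cohort():
    """Small real cohort: recent model on a 2x2 grid, two chromosomes."""
    dem = st.build_demography("recent", st.GridSpec(2, 2), 0.05)
    return st.simulate_cohort(dem, st.GenomeSpec(2, 200_000), 20, seed=11)


@pytest.fixture(scope="session")
def two_deme_structured_cohort():
    """Two demes with strong differentiation (small Ne, rare migration).

    Perpetual structure at deme size 500 and m=0.001 gives FST large
    enough that leading PCs must separate the demes cleanly.
    """
    dem = st.build_demography(
        "perpetual", st.GridSpec(1, 2), 0.0005, deme_ne=300, perpetual_horizon=2000.0
    )
    return st.simulate_cohort(dem, st.GenomeSpec(2, 500_000), 40, seed=13)


@pytest.fixture(scope="session")
def panmictic_cohort():
    """A single unstructured population (1x1 grid)."""
    dem = st.build_demography("recent", st.GridSpec(1, 1), 0.0)
    return st.simulate_cohort(dem, st.GenomeSpec(2, 300_000), 120, seed=17)
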