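import numpy as np
import pandas as pd
import pytest

from halfsibkit import CountTable, GenotypeTable, default_design, simulate_pedigree


@pytest.fixture
def design():
    return default_design()


@pytest.fixture
def toy_genotypes():
    """Four samples x four markers with one missing cell."""
    return GenotypeTable(
        pd.DataFrame(
            [
                [0, 1, 2, 0],
                [1, 1, 0, np.nan],
                [0, 1, 2, 0],
                [2, 1, 0, 2],
            ],
            index=["s1", "s2", "s3", "s4"],
            columns=["m1", "m2", "m3", "m4"],
            dtype=float,
        )
    )


@pytest.fixture
def toy_counts():
    """Three contigs x three samples, equal library totals of 100 reads."""
    counts = pd.DataFrame(
        [[50, 10, 0], [30, 40, 60], [20, 50, 40]],
        index=["c1", "c2", "c3"],
        columns=["f1", "f2", "f3"],
    )
    lengths = pd.Series([500, 1000, 2000], index=counts.index)
    return CountTable(counts, lengths)


@pytest.fixture
def planted_sim():
    """Default half-sib design, 2000 markers, 5 planted, no missing data."""
    table, samples, truth = simulate_pedigree(
        n_markers=2000, maf_low=0.1, maf_high=0.5, n_planted=5, missing_rate=0.0, seed=42
    )
    offspring = table.subset([s.sample_id for s in samples])
    return table, offspring, samples, truth
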