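import numpy as np
import pandas as pd
import pytest

from asebead.pipeline import run_illumina
from asebead.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A default-condition 60-SNP cohort shared across tests."""
    return simulate_cohort(SimConfig(n_snps=60, seed=11))


@pytest.fixture(scope="session")
def small_run(small_cohort):
    """Full pipeline results on the shared cohort."""
    return run_illumina(small_cohort.beads, small_cohort.trios)


def make_beads(snp_ids, sample_id, array_id, intensity_a, intensity_b):
    """Assemble a bead table from parallel vectors."""
    return pd.DataFrame({
        "snp_id": np.asarray(snp_ids, dtype=object),
        "sample_id": sample_id,
        "array_id": array_id,
        "intensity_a": np.asarray(intensity_a, dtype=float),
        "intensity_b": np.asarray(intensity_b, dtype=float),
    })
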