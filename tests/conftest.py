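import numpy as np
import pandas as pd
import pytest

from methretain import BetaMatrix, SimulationConfig, simulate_dataset
from methretain.arrays import validate_manifest


def make_manifest(rows):
    """rows: (probe_id, chromosome, position, genomic_context[, strand])"""
    recs = []
    for r in rows:
        r = tuple(r) + ("unknown",) * (5 - len(r))
        recs.append(r)
    df = pd.DataFrame(
        recs, columns=["probe_id", "chromosome", "position", "genomic_context", "strand"]
    )
    return validate_manifest(df)


def make_betas(values, probe_ids=None, sample_ids=None):
    arr = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"cg{i:04d}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=probe_ids, columns=sample_ids))


@pytest.fixture(scope="session")
def small_config():
    # desk-scale dataset: ~2.3k probes, keeps the session fast
    counts = {
        "chr1": 300, "chr2": 250, "chr3": 200, "chr16": 150, "chr17": 150,
        "chr19": 150, "chr22": 120, "chr7": 250, "chr9": 200, "chr20": 180,
        "chrX": 300, "chrY": 20,
    }
    return SimulationConfig(seed=7, probes_per_chromosome=counts)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)
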