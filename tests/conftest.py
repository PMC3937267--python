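import numpy as np
import pandas as pd
import pytest

from hoxmir import simulate


@pytest.fixture(scope="session")
def small_config():
    """Two small clusters, clean reads; cheap enough for read expansion."""
    return simulate.SimulationConfig(
        seed=7,
        cluster_layout=((1, 5), (2, 5)),
        n_case=4,
        n_control=3,
        isomir_5p_shift_rate=0.0,
        isomir_3p_trim_rate=0.0,
        low_quality_read_rate=0.0,
        mean_log_mu=np.log(20.0),
        mean_log_sigma=0.5,
        baseline_means={"miR-10b-like": 40.0},
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate.simulate_dataset(small_config, with_reads=True)


@pytest.fixture(scope="session")
def reference(small_dataset):
    return small_dataset.reference


def naive_scan(genome: dict, query: str):
    """Independent O(nm) exact-occurrence oracle over both strands."""
    from hoxmir.quant import revcomp

    hits = []
    if "N" in query:
        return hits
    n = len(query)
    for chrom, seq in genome.items():
        for strand, q in (("+", query), ("-", revcomp(query))):
            for i in range(len(seq) - n + 1):
                window = seq[i : i + n]
                if "N" not in window and window == q:
                    hits.append((chrom, i, i + n, strand))
    return sorted(hits)


@pytest.fixture(scope="session")
def naive_scan_oracle():
    return naive_scan
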