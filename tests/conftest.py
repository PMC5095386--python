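import numpy as np
import pytest

from coscape import markers, pipeline, simulate


@pytest.fixture(scope="session")
def small_sim():
    """Small noisy population: (table, truth, config)."""
    return pipeline.make_fixture(seed=11)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noise-free population at very high depth: calls must equal truth."""
    cfg = pipeline.small_sim_config(
        seed=7, depth_mean=10_000.0, base_error=0.0, geno_error=0.0
    )
    table, truth = simulate.simulate_f2_population(cfg)
    return table, truth, cfg


#: filter thresholds compatible with the noiseless fixture's very high depth
NOISELESS_PARAMS = markers.FilterParams(depth_min=0, depth_max=10**9)


@pytest.fixture(scope="session")
def noiseless_matrix(noiseless_sim):
    table, truth, cfg = noiseless_sim
    return markers.filter_variants(table, NOISELESS_PARAMS), truth, cfg


def make_matrix(pos, calls, samples=None, f1="F1", chrom="chr1", lengths=None):
    """Hand-built single-chromosome MarkerMatrix for unit tests."""
    calls = np.asarray(calls, dtype=np.int8)
    if samples is None:
        samples = [f1] + [f"S{i}" for i in range(1, calls.shape[1])]
    return markers.MarkerMatrix(
        samples=list(samples),
        f1=f1,
        pos={chrom: np.asarray(pos, dtype=np.int64)},
        calls={chrom: calls},
        chrom_lengths=lengths or {},
    )
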