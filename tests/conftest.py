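import pytest

from mirrescue import SimulationParams, simulate_expression


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """A scaled-down cohort that keeps every structural feature of the
    defaults (three conditions, rescue majority, planted miRNAs, decoys)."""
    return SimulationParams(
        seed=7, n_probes=800, n_genes=600, n_altered=300, n_mirnas=60,
        utr_length_range=(100, 300),
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return simulate_expression(small_params)
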