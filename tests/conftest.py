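"""Session-scoped simulated datasets shared across the test modules."""
import pytest

from epitrio.synthetic_data import (
    ScenarioSpec,
    SimulationConfig,
    simulate_trio,
    table1_scenarios,
)


@pytest.fixture(scope="session")
def sim_clean():
    """Error-free miniature trio (22 autosomes + X, 5 Mb each), no scenarios."""
    return simulate_trio(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def sim_err():
    """Miniature trio with genotype error rate 1e-3."""
    return simulate_trio(SimulationConfig(seed=42, genotype_error_rate=1e-3))


@pytest.fixture(scope="session")
def sim_upd_err():
    """Paternal chr9 isodisomy with 0.5% genotype error."""
    return simulate_trio(
        SimulationConfig(seed=202, upd_chrom="chr9", genotype_error_rate=0.005)
    )


@pytest.fixture(scope="session")
def sim_scenarios():
    """Error-free miniature trio with the six planted causal configurations."""
    return simulate_trio(SimulationConfig(seed=11, scenarios=table1_scenarios()))


@pytest.fixture(scope="session")
def sim_roh():
    """Single chromosome carrying a planted 2 Mb homozygous region.

    mu = 0 isolates the ROH signal from incidental de novo het calls.
    """
    return simulate_trio(
        SimulationConfig(
            seed=77,
            chrom_lengths={"chr16": 5_000_000},
            mu=0.0,
            scenarios=[s for s in table1_scenarios() if s.gene == "PIGQ"],
        )
    )
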