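import numpy as np
import pytest

from tickmito.simulate import (PlantedMotif, PlantedSSR, SimulationParams,
                               simulate_mitogenome)


@pytest.fixture(scope="session")
def sim_record():
    """Plain synthetic mitogenome with the ancestral arrangement."""
    record, truth = simulate_mitogenome(SimulationParams(seed=11))
    return record, truth


@pytest.fixture(scope="session")
def planted_record():
    """Synthetic mitogenome with planted SSRs and motif instances."""
    params = SimulationParams(
        seed=42,
        intergenic_length=1000,
        planted_ssrs=(
            PlantedSSR("AAT", 6, host="IG"),
            PlantedSSR("A", 12, host="CR"),
            PlantedSSR("ACGT", 4, host="IG", offset=700),
        ),
        planted_motifs=(
            PlantedMotif("TTGTATCAAATTTAGAA", host="trnL1", strand=-1, offset=20),
            PlantedMotif("TTGTATCCTTTTGAGAA", host="IG", strand=1, offset=450),
        ),
    )
    record, truth = simulate_mitogenome(params)
    return record, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
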