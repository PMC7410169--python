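import numpy as np
import pytest

from demarg.demography import (
    DemographicModel,
    MigrationBand,
    Population,
    SampleConfig,
    build_time_grid,
)
from demarg.threading import EmissionContext


@pytest.fixture(scope="session")
def one_pop_model():
    """Panmictic population, three haploid samples: the P = 1 reduction."""
    return DemographicModel(
        grid=build_time_grid([0, 50e3, 100e3, 200e3, 400e3, 800e3]),
        populations=[Population("A", sizes=10_000)],
        samples=[
            SampleConfig("x", "A", ploidy=1),
            SampleConfig("y", "A", ploidy=1),
            SampleConfig("z", "A", ploidy=1),
        ],
    )


@pytest.fixture(scope="session")
def two_pop_model():
    """Two populations joined at 450 ky with one migration band at 150 ky."""
    return DemographicModel(
        grid=build_time_grid([0, 100e3, 200e3, 300e3, 500e3]),
        populations=[
            Population("Anc", sizes=10_000),
            Population("A", parent="Anc", divergence_time=450e3, sizes=10_000),
            Population("B", parent="Anc", divergence_time=450e3, sizes=5_000),
        ],
        bands=[MigrationBand("A", "B", 150e3, 0.01)],
        samples=[
            SampleConfig("a", "A", ploidy=1),
            SampleConfig("b", "B", ploidy=1),
        ],
    )


@pytest.fixture(scope="session")
def two_pop_model_3lin():
    """As two_pop_model but with an extra lineage in each population."""
    return DemographicModel(
        grid=build_time_grid([0, 100e3, 200e3, 300e3, 500e3]),
        populations=[
            Population("Anc", sizes=10_000),
            Population("A", parent="Anc", divergence_time=450e3, sizes=10_000),
            Population("B", parent="Anc", divergence_time=450e3, sizes=5_000),
        ],
        bands=[MigrationBand("A", "B", 150e3, 0.01)],
        samples=[
            SampleConfig("a1", "A", ploidy=1),
            SampleConfig("a2", "A", ploidy=1),
            SampleConfig("b1", "B", ploidy=1),
            SampleConfig("b2", "B", ploidy=1),
        ],
    )


def make_ctx(n, L, rng=None, missing=False, mu=1.45e-7, width=10.0):
    if rng is None or missing:
        alleles = np.full((n, L), -1 if missing else 0, dtype=np.int8)
    else:
        alleles = rng.integers(0, 2, size=(n, L)).astype(np.int8)
    return EmissionContext(
        alleles=alleles,
        mu_eff=np.full(L, mu),
        widths=np.full(L, width),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
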