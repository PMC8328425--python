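import numpy as np
import pytest

from trapnest.io import Dataset, NestRecord, SiteRecord, Taxon, UGSType
from trapnest.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    """Synthetic survey small enough for fast bootstraps (3 sites/type)."""
    config = GeneratorConfig(
        n_sites={u.value: 3 for u in UGSType}, tubes_mean=14.0, seed=11
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def survey_dataset() -> Dataset:
    """Study-sized synthetic survey (default config)."""
    return generate_dataset(seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def hand_nests() -> list[NestRecord]:
    """Three nests with hand-checkable counts."""
    return [
        NestRecord("n1", "S1", Taxon.BEE, "Osmia pumila", 10, 1, 2),
        NestRecord("n2", "S1", Taxon.BEE, "Osmia pumila", 5, 5, 0),
        NestRecord("n3", "S1", Taxon.BEE, "Heriades carinata", 6, 1, 2),
    ]


@pytest.fixture()
def one_site() -> list[SiteRecord]:
    return [
        SiteRecord("S1", UGSType.HOME_GARDEN, open_green=0.4, impervious=0.3, edge_density=0.01)
    ]
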