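import numpy as np
import pytest

from mtpopgen import coalsim
from mtpopgen.core import (
    PopulationDataset,
    RegionSet,
    STAT_REGIONS,
    VariantProfile,
)


@pytest.fixture(scope="session")
def small_regions() -> RegionSet:
    return RegionSet(((1, 200),))


@pytest.fixture(scope="session")
def reference() -> str:
    return coalsim.synthetic_reference(STAT_REGIONS)


@pytest.fixture(scope="session")
def small_reference(small_regions) -> str:
    return coalsim.synthetic_reference(small_regions)


@pytest.fixture(scope="session")
def constant_dataset() -> PopulationDataset:
    """Single population simulated under a constant-size model, theta=5."""
    cfg = coalsim.SimConfig(
        n=30, seed=2024, model=coalsim.DemographicModel.constant(5.0)
    )
    ds, _ = coalsim.simulate_dataset(cfg)
    return ds


@pytest.fixture(scope="session")
def three_pop_dataset() -> PopulationDataset:
    """Three populations with modest divergence (two split demes plus a
    resampled merge), used for table-shape and pipeline tests."""
    cfg1 = coalsim.SimConfig(
        n=24, seed=11, model=coalsim.DemographicModel.constant(4.0),
        split=(12, 12, 6.0),
    )
    ds1, _ = coalsim.simulate_dataset(cfg1)
    cfg2 = coalsim.SimConfig(
        n=10, seed=12, model=coalsim.DemographicModel.constant(4.0),
        population="popC",
    )
    ds2, _ = coalsim.simulate_dataset(cfg2)
    profiles = ds1.profiles + [
        VariantProfile(f"c_{p.sample_id}", p.variants, p.missing)
        for p in ds2.profiles
    ]
    pop_of = dict(ds1.pop_of)
    pop_of.update({f"c_{p.sample_id}": "popC" for p in ds2.profiles})
    return PopulationDataset(profiles, pop_of, STAT_REGIONS)


def make_profiles(variant_sets, prefix="s"):
    return [
        VariantProfile(f"{prefix}{i}", frozenset(vs))
        for i, vs in enumerate(variant_sets)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(12345))
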