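import warnings

import numpy as np
import pytest

from gflai import (
    ToyCanopyModel,
    build_lut,
    default_distribution_spec,
    lai_only_spec,
    make_training_set,
    simulate_field_campaign,
    train_gpr,
)

# the white-noise lower bound is hit by design on noise-free simulations
warnings.filterwarnings("ignore", message=".*noise_level is close to the specified lower bound.*")


@pytest.fixture(scope="session")
def full_spec():
    """Heterogeneous prior: every leaf/canopy/soil parameter varies."""
    return default_distribution_spec()


@pytest.fixture(scope="session")
def lai_spec():
    """Identifiable prior: only LAI varies, all else fixed at the means."""
    return lai_only_spec()


@pytest.fixture(scope="session")
def const_toy():
    """Toy model with constant endmembers and fixed extinction, for
    hand-computable closed forms."""
    return ToyCanopyModel(soil_spectrum=0.3, leaf_spectrum=0.5, extinction=0.5)


@pytest.fixture(scope="session")
def small_lut(lai_spec):
    """200-entry noise-free LAI-only LUT on the full band vector."""
    return build_lut(lai_spec, "B1B2B3B4", n_entries=200, seed=11, noise_sigma=0.0)


@pytest.fixture(scope="session")
def ndvi_model(lai_spec):
    """Small noise-free NDVI GPR trained on the identifiable prior."""
    train = make_training_set(lai_spec, "NDVI", n=300, noise_sigma=0.0, seed=21)
    return train, train_gpr(train, seed=21)


@pytest.fixture(scope="session")
def campaign(full_spec):
    return simulate_field_campaign(n_plots=29, spec=full_spec, noise_sigma=0.01, seed=31)
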