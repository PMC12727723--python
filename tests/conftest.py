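"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

import metconn as mc


@pytest.fixture(scope="session")
def small_scheme():
    """16 parcels (8 per hemisphere): fast, fully connected hemispheres."""
    return mc.generate_parcel_scheme(8, seed=11)


@pytest.fixture(scope="session")
def medium_scheme():
    """40 parcels: enough spatial structure for null-model tests."""
    return mc.generate_parcel_scheme(20, seed=12)


@pytest.fixture(scope="session")
def medium_data(medium_scheme):
    vox, truth = mc.generate_voxel_metabolites(medium_scheme, seed=13)
    return vox, truth


@pytest.fixture(scope="session")
def medium_metsim(medium_scheme, medium_data):
    vox, _ = medium_data
    retained = mc.filter_regions(vox, medium_scheme, min_voxels=1)
    reps = mc.perturb_voxels(vox, 5, seed=14)
    profiles = mc.compute_profiles(reps, medium_scheme, retained)
    return mc.compute_metsim(profiles)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)
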