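from __future__ import annotations

import numpy as np
import pytest

from nanori import phantom


def small_phantom_config(**overrides) -> phantom.PhantomConfig:
    """A fast miniature phantom (~11k cell voxels) for unit tests."""
    kw = dict(
        grid_shape=(24, 48, 48),
        voxel_size_nm=(400.0, 200.0, 200.0),
        cell_semiaxes_nm=(3200.0, 3600.0, 3600.0),
        nucleus_semiaxes_nm=(1400.0, 1300.0, 1300.0),
        nucleus_offset_nm=(0.0, 600.0, 600.0),
        perinuclear_shell_nm=800.0,
        puncta_radius_range_vox=(1.5, 2.5),
        geometry_jitter_frac=0.04,
        center_jitter_nm=200.0,
    )
    kw.update(overrides)
    return phantom.PhantomConfig(**kw)


def medium_phantom_config(**overrides) -> phantom.PhantomConfig:
    """A 0.6-scaled copy of the default geometry (same compartment volume
    ratios, so calibrated cohort statistics carry over) at ~5x the speed."""
    kw = dict(
        grid_shape=(64, 144, 144),
        voxel_size_nm=(400.0, 200.0, 200.0),
        cell_semiaxes_nm=(5400.0, 9000.0, 9000.0),
        nucleus_semiaxes_nm=(2400.0, 3300.0, 3300.0),
        nucleus_offset_nm=(0.0, 1500.0, 1500.0),
    )
    kw.update(overrides)
    return phantom.PhantomConfig(**kw)


@pytest.fixture
def small_config() -> phantom.PhantomConfig:
    return small_phantom_config()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
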