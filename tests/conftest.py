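import numpy as np
import pytest

from dixonfgt import (
    PhantomSpec,
    TissueProperties,
    generate_phantom,
    simulate_dixon_acquisition,
    two_point_separation,
)
from dixonfgt.image import VolumeImage
from dixonfgt.segment import body_mask, pectoral_cut_and_split

# small but anatomically sensible grid used by most pipeline tests
GRID = (64, 48, 36)
SPACING = (1.3, 1.3, 1.0)
CHEST_PLANE = 33


def make_spec(composition=None, seed=0, grid=GRID, spacing=SPACING,
              chest_plane=CHEST_PLANE):
    if composition is None:
        composition = {"kind": "blobs", "n_blobs": 25, "radius_mm": 6.0,
                       "v_inside": 1.0, "v_outside": 0.0}
    return PhantomSpec(
        grid_shape=grid, voxel_spacing_mm=spacing,
        chest_wall_plane_index=chest_plane, composition=composition,
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def blob_phantom():
    return generate_phantom(make_spec(seed=11))


@pytest.fixture(scope="session")
def single_peak_tissues():
    return TissueProperties().single_peak()


@pytest.fixture(scope="session")
def multi_peak_tissues():
    return TissueProperties()


def pipeline_masks(phantom, echoes, erosion_iters=1):
    """Segment an exam's in-phase magnitude and apply the pectoral cut."""
    ip_mag = VolumeImage(np.abs(echoes.in_phase.data), echoes.in_phase.spacing)
    mask = body_mask(ip_mag, threshold="auto", erosion_iters=erosion_iters)
    mask_l, mask_r = pectoral_cut_and_split(mask, phantom.chest_wall_plane_index)
    return {"L": mask_l, "R": mask_r}


@pytest.fixture(scope="session")
def clean_pd_exam(blob_phantom, single_peak_tissues):
    """Noise-free single-peak PD-weighted acquisition plus its recon."""
    echoes = simulate_dixon_acquisition(
        blob_phantom, single_peak_tissues, "hr-gre-pd", noise_sd=0.0
    )
    pair = two_point_separation(echoes, mode="complex")
    masks = pipeline_masks(blob_phantom, echoes)
    return {"echoes": echoes, "pair": pair, "masks": masks}
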