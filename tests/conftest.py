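"""Shared phantom fixtures.

Phantoms are generated once per session at reduced organ scale (a few
hundred micrometres of semi-axis at 2 um voxels) so the whole suite stays
fast; the geometry and intensity model are identical to full-scale
phantoms.
"""

import numpy as np
import pytest

from ovamap.phantom import PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def seg_phantom():
    """Noise-free phantom with non-touching follicles >= T5 (segmentation oracle)."""
    spec = PhantomSpec(
        organ_semi_axes=(350.0, 310.0, 260.0),
        voxel_size=2.0,
        per_stage_counts={"T5": 6, "T6": 3, "T7": 1},
        noise_sd=0.0,
        seed=7,
        vessel_specs=(),
    )
    vol, gt = build_phantom(spec)
    return spec, vol, gt


@pytest.fixture(scope="session")
def feature_phantom():
    """Noisy phantom containing every stage the pipeline can detect, plus CL."""
    spec = PhantomSpec(
        organ_semi_axes=(450.0, 400.0, 340.0),
        voxel_size=2.0,
        per_stage_counts={"T4": 2, "T5": 2, "T6": 2, "T7": 1, "T8": 1, "CL": 1},
        cl_diameter_range=(280.0, 320.0),
        noise_sd=5.0,
        seed=3,
        vessel_specs=(),
    )
    vol, gt = build_phantom(spec)
    return spec, vol, gt


@pytest.fixture()
def ellipsoid_mask():
    """A centred ellipsoid mask in an asymmetric box."""
    zz, yy, xx = np.ogrid[:60, :50, :40]
    return ((((zz - 29.5) / 25) ** 2 + ((yy - 24.5) / 20) ** 2
             + ((xx - 19.5) / 15) ** 2) <= 1)
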