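"""Shared fixtures: phantoms and small processed cohorts.

Session-scoped fixtures cache the expensive objects (aligned phantoms,
processed cohorts) so individual tests stay fast.
"""

import numpy as np
import pytest

from hemiasym import (
    PhantomSpec,
    ThresholdBand,
    align_and_extract,
    generate_cohort,
    generate_phantom,
    skull_strip,
)

BAND = ThresholdBand(60.0, 200.0)


@pytest.fixture(scope="session")
def symmetric_bundle():
    """Lesion-free, unposed, noise-free phantom: exactly mirror-symmetric."""
    return generate_phantom(PhantomSpec(label="NC", seed=7, n_lesions=0))


@pytest.fixture(scope="session")
def ad_bundle():
    """Posed, noisy phantom with strong unilateral lesions."""
    return generate_phantom(
        PhantomSpec(label="AD", seed=21, rotation_deg=4.0, shift=(8.0, -5.0), noise_sigma=2.0)
    )


@pytest.fixture(scope="session")
def ad_aligned(ad_bundle):
    """(aligned image, asymmetry map, pose) of the posed AD phantom."""
    stripped = skull_strip(ad_bundle.image, BAND)
    return align_and_extract(stripped)


@pytest.fixture(scope="session")
def small_cohort():
    """Balanced 5-per-class phantom cohort with default pose/noise."""
    return generate_cohort(5, seed=13)
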