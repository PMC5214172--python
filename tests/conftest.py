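from datetime import datetime, timezone

import pytest

import petcrosscal as pc

#: the default simulated acquisition instant (matches PhantomScene rendering)
ACQ = datetime(2013, 4, 1, 12, 0, tzinfo=timezone.utc)


@pytest.fixture(scope="session")
def default_scene() -> pc.PhantomScene:
    return pc.PhantomScene()


@pytest.fixture(scope="session")
def noiseless_pair(default_scene):
    """Smoothed noiseless PET volume and companion CT of the default scene."""
    return pc.simulate_measurement(
        default_scene, pc.PsfSpec(), pc.NoiseSpec(model="none", magnitude=0.0)
    )


@pytest.fixture(scope="session")
def pet_vol(noiseless_pair):
    return noiseless_pair[0]


@pytest.fixture(scope="session")
def ct_vol(noiseless_pair):
    return noiseless_pair[1]


@pytest.fixture(scope="session")
def phantom_cert() -> pc.SourceCertificate:
    """Imaging-phantom certificate referenced at the simulated scan instant.

    With the reference at the acquisition time, the known concentration at
    scan time equals the scene's 250 kBq/mL, so a perfect measurement has
    R exactly 1.
    """
    return pc.SourceCertificate(
        source_id="XC-TEST-1",
        nuclide="Ge-68",
        reference_datetime=ACQ,
        reference_activity_mbq=20.0,
        reference_concentration_kbq_ml=250.0,
        stated_uncertainty=0.025,
        active_diameter_mm=45.0,
        active_height_mm=45.0,
    )


@pytest.fixture(scope="session")
def dose_cert() -> pc.SourceCertificate:
    """Dose-calibrator source certificate (activity only, no concentration)."""
    return pc.SourceCertificate(
        source_id="DC-TEST-1",
        nuclide="Ge-68",
        reference_datetime=ACQ,
        reference_activity_mbq=0.90,
        stated_uncertainty=0.025,
    )
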