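import pytest

import acoustofocus as af


@pytest.fixture(scope="session")
def water():
    return af.WATER_20C


@pytest.fixture(scope="session")
def geometry():
    return af.ResonatorGeometry()


@pytest.fixture(scope="session")
def bead_4um():
    return af.polystyrene_sphere(4e-6, "4MP")


@pytest.fixture(scope="session")
def bead_1um():
    return af.polystyrene_sphere(1e-6, "1MP")


@pytest.fixture(scope="session")
def bead_500nm():
    return af.polystyrene_sphere(0.5e-6, "NP")


@pytest.fixture(scope="session")
def device_field(geometry, water):
    """Half-wave transverse mode at the track-derived energy density."""
    return af.DriveField.half_wave(geometry, water, energy_density=7.25)


@pytest.fixture(scope="session")
def operating_field(geometry, water):
    """Half-wave mode at the standard drive voltage (50.59 Vpp)."""
    return af.DriveField.half_wave(geometry, water, vpp=50.59)


@pytest.fixture(scope="session")
def streaming_solution(operating_field, geometry, water):
    """Cross-section streaming flow at the operating point (128 x 64 grid)."""
    f1 = af.first_order_field(operating_field, geometry, (128, 64))
    return af.solve_streaming(af.limiting_velocity(f1), geometry, water)
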