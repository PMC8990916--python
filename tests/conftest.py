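import pytest

from ssdekit import (
    Inclusion,
    PhantomSpec,
    abdomen_cohort_spec,
    chest_cohort_spec,
    render_phantom,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def water_spec():
    """Uniform water ellipse, AP=20 cm, LAT=30 cm."""
    return PhantomSpec(body_ap=20.0, body_lat=30.0, body_hu=0.0)


@pytest.fixture(scope="session")
def water_image(water_spec):
    return render_phantom(water_spec, pixel_spacing=0.1)


@pytest.fixture(scope="session")
def chest_spec():
    """Chest-like phantom: water body with two air-rich lung ellipses."""
    return PhantomSpec(
        body_ap=22.0,
        body_lat=32.0,
        body_hu=0.0,
        inclusions=(
            Inclusion(center=(0.0, -7.0), semi_axes=(7.0, 5.0), hu=-800.0),
            Inclusion(center=(0.0, 7.0), semi_axes=(7.0, 5.0), hu=-800.0),
        ),
    )


@pytest.fixture(scope="session")
def abdomen_spec():
    """Abdomen-like phantom: soft tissue slightly denser than water."""
    return PhantomSpec(body_ap=20.0, body_lat=30.0, body_hu=77.0)


@pytest.fixture(scope="session")
def chest_records():
    return simulate_cohort(chest_cohort_spec(seed=11))


@pytest.fixture(scope="session")
def abdomen_records():
    return simulate_cohort(abdomen_cohort_spec(seed=12))
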