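import pytest

from seegwm.phantom import (
    Ellipsoid,
    PhantomSpec,
    TubeTract,
    build_phantom,
    default_phantom_spec,
)
from seegwm.simulate import simulate_cohort


def small_spec(**overrides) -> PhantomSpec:
    """A 65^3 phantom whose voxel centers sit on integer world coordinates."""
    base = dict(
        shape=(65, 65, 65),
        brain_radius=26.0,
        gm_thickness=4.0,
        ventricle=Ellipsoid((0.0, -8.0, 0.0), (4.0, 6.0, 4.0)),
        tracts=(
            TubeTract(
                name="left_tube",
                hemisphere="left",
                centerline=((-12.0, -15.0, 0.0), (-12.0, 15.0, 0.0)),
                radius=8.0,
            ),
            TubeTract(
                name="right_tube",
                hemisphere="right",
                centerline=((12.0, -15.0, 0.0), (12.0, 15.0, 0.0)),
                radius=8.0,
            ),
            TubeTract(
                name="cross_band",
                hemisphere="commissural",
                centerline=((-18.0, 0.0, 0.0), (18.0, 0.0, 0.0)),
                radius=8.0,
            ),
        ),
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def small_phantom():
    return build_phantom(small_spec())


@pytest.fixture(scope="session")
def phantom128():
    """The full-size validation phantom (128^3, three tube tracts)."""
    return build_phantom(default_phantom_spec())


@pytest.fixture(scope="session")
def cohort20(phantom128):
    """A 20-patient simulated cohort (~1500 contacts) on the full phantom."""
    return simulate_cohort(phantom128, n_patients=20, seed=0)
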