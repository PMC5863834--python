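import numpy as np
import pytest

from pfcurve.flow_engine import FluidProperties
from pfcurve.geometry import (
    AreaProfile,
    IdealizedSpec,
    VesselSegment,
    VesselTree,
    make_idealized_stenosis,
)


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def profile_as80():
    return make_idealized_stenosis(IdealizedSpec(shape="concentric", as_percent=80))


@pytest.fixture(scope="session")
def tree_as80(profile_as80):
    return VesselTree.single_vessel(profile_as80)


def uniform_tube(diameter=3.0, length=30.0, n=61) -> AreaProfile:
    """Straight tube whose 'lesion' spans the middle third."""
    area = np.pi * diameter ** 2 / 4.0
    s = np.linspace(0.0, length, n)
    return AreaProfile(
        arclength=s,
        area=np.full(n, area),
        eccentricity=np.zeros(n),
        lesion_start=length / 3.0,
        lesion_end=2.0 * length / 3.0,
    )


def random_tree(rng: np.random.Generator) -> VesselTree:
    """A random 1-3 outlet tree of idealized stenosis segments."""
    n_daughters = int(rng.integers(0, 3))  # 0 -> single vessel
    root_profile = make_idealized_stenosis(
        IdealizedSpec(
            shape=rng.choice(["concentric", "eccentric"]),
            as_percent=float(rng.uniform(30, 90)),
            ref_diameter=float(rng.uniform(2.5, 4.0)),
        )
    )
    segments = {"root": VesselSegment("root", root_profile)}
    if n_daughters == 0:
        outlets = {"root": float(root_profile.area[-1])}
    else:
        outlets = {}
        for j in range(n_daughters):
            prof = make_idealized_stenosis(
                IdealizedSpec(
                    shape="concentric",
                    as_percent=float(rng.uniform(0, 60)),
                    ref_diameter=float(rng.uniform(2.0, 3.0)),
                )
            )
            sid = f"d{j}"
            segments[sid] = VesselSegment(sid, prof, parent="root")
            outlets[sid] = float(prof.area[-1])
    return VesselTree(segments=segments, outlet_areas=outlets, lesion_segment="root")
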