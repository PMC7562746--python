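import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from poreflux import (
    HarmonicBias,
    SimulationSpec,
    UmbrellaWindowData,
    CylinderRestraint,
    generate_us_dataset,
    get_fixture,
    place_windows,
)
from poreflux.pore_geometry import StructureFrame

BIN_EDGES = np.arange(-26.25, 26.26, 0.5)


def make_frame(coords, names=None, resnames=None, resnums=None, chains=None,
               elements=None, vdw=None, frame_index=0):
    """Minimal StructureFrame builder for geometry tests."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return StructureFrame(
        serial=np.arange(1, n + 1),
        name=np.array(names if names is not None else ["CA"] * n),
        resname=np.array(resnames if resnames is not None else ["ALA"] * n),
        resnum=np.array(resnums if resnums is not None else np.arange(1, n + 1)),
        chain=np.array(chains if chains is not None else ["A"] * n),
        coords=coords,
        vdw=np.array(vdw if vdw is not None else [1.7] * n),
        element=np.array(elements if elements is not None else ["C"] * n),
        frame_index=frame_index,
    )


def ring_frame(radius, z=0.0, vdw=1.7, phase=0.0, n=6, **kw):
    ang = phase + np.arange(n) * (2 * np.pi / n)
    coords = np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.full(n, z)]
    )
    return make_frame(coords, vdw=[vdw] * n, **kw)


@pytest.fixture(scope="session")
def toy_windows():
    """Three overlapping 200-sample windows on the flat fixture (oracle-sized)."""
    model = get_fixture("flat")
    wins = [HarmonicBias(z0, 5.0) for z0 in (-1.0, 0.0, 1.0)]
    spec = SimulationSpec(model=model, bias=None, n_steps=1000, sample_stride=5)
    return generate_us_dataset(model, wins, spec_defaults=spec, seed=1234)


@pytest.fixture(scope="session")
def us_dataset_38():
    """Full 105-window Brownian-dynamics dataset on the 3.8 kcal/mol barrier."""
    model = get_fixture("barrier_3.8")
    wins = place_windows(-26.0, 26.0, 0.5, 5.0)
    spec = SimulationSpec(model=model, bias=None)
    return generate_us_dataset(model, wins, spec_defaults=spec, seed=38)
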