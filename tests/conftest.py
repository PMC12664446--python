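"""Shared fixtures: coarse phantom, small detector geometry, simulators.

Everything is generated at run time from seeds; no stored data.  The
fixture phantom uses 0.1 mm voxels and a thicker spring wire so tests run
in seconds while preserving the production topology.
"""

import numpy as np
import pytest

from shuntscope import (AttenuationTable, PhantomSpec, ProjectionGeometry,
                        build_valve_phantom, fixture_phantom_spec)
from shuntscope.projector import FrameSimulator


@pytest.fixture(scope="session")
def attenuation():
    return AttenuationTable()


@pytest.fixture(scope="session")
def fixture_volume():
    """Coarse (0.1 mm) valve phantom for fast tests."""
    return build_valve_phantom(fixture_phantom_spec())


@pytest.fixture(scope="session")
def production_volume():
    """The default production phantom (0.05 mm voxels)."""
    return build_valve_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_geometry():
    """64x64 detector frame, same SOD/SDD, valve fills ~90% of the frame."""
    return ProjectionGeometry(pitch_mm=2.0, rows=64, cols=64)


@pytest.fixture(scope="session")
def simulator(fixture_volume, attenuation, small_geometry):
    return FrameSimulator(fixture_volume, attenuation, small_geometry,
                          n_angles=24)
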