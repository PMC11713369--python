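"""Shared fixtures: small scenes, sources and cheap transport runs."""

from __future__ import annotations

import numpy as np
import pytest

from brachyq.geometry import Region, Scene, Sphere, ir_scene, water_shell
from brachyq.physics_data import EnergySpectrum, load_spectrum
from brachyq.transport import SourceModel, TransportConfig, run_transport


@pytest.fixture(scope="session")
def cs137_line():
    return EnergySpectrum([0.662], [1.0], name="cs137")


@pytest.fixture(scope="session")
def ir_spectrum():
    return load_spectrum("ir192")


@pytest.fixture(scope="session")
def co60_spectrum():
    return load_spectrum("co60")


@pytest.fixture(scope="session")
def vacuum_shell_run(cs137_line):
    """Isotropic source in vacuum with thin shell tallies at 5 and 10 cm."""
    regs = [
        Region("c1", Sphere(np.zeros(3), 4.975), "vacuum"),
        Region("s1", Sphere(np.zeros(3), 5.025), "vacuum"),
        Region("c2", Sphere(np.zeros(3), 9.975), "vacuum"),
        Region("s2", Sphere(np.zeros(3), 10.025), "vacuum"),
    ]
    scene = Scene(regs, Region("ph", Sphere(np.zeros(3), 12.0), "vacuum"))
    src = SourceModel("isotropic_point", cs137_line)
    return run_transport(
        TransportConfig(scene=scene, source=src, n_histories=80_000, seed=7, tallies=("s1", "s2"))
    )


@pytest.fixture(scope="session")
def water_shell_run(cs137_line):
    """Full-physics monoenergetic run scoring a shell at 3 cm in water."""
    scene = ir_scene(water_shell(3.0))
    src = SourceModel("isotropic_point", cs137_line)
    return run_transport(
        TransportConfig(scene=scene, source=src, n_histories=120_000, seed=3, tallies=("voxel",))
    )
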