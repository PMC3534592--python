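"""Shared fixtures: session-scoped FEM solves (the expensive bits)."""

from __future__ import annotations

import numpy as np
import pytest

from dbareit.dn_map import delta_dn_from_data
from dbareit.forward_sim import (
    ElectrodeLayout,
    Inclusion,
    PhantomSpec,
    mesh_for_layout,
    solve_forward_cem,
    trig_patterns,
)


@pytest.fixture(scope="session")
def layout16() -> ElectrodeLayout:
    return ElectrodeLayout(L=16, r=1.0)


@pytest.fixture(scope="session")
def patterns16():
    return trig_patterns(16, 1.0)


@pytest.fixture(scope="session")
def mesh16(layout16):
    return mesh_for_layout(layout16, 6400, edges_per_electrode=6)


@pytest.fixture(scope="session")
def homog_data(mesh16, layout16, patterns16):
    """Unit-conductivity voltages on the session mesh."""
    return solve_forward_cem(
        mesh16, PhantomSpec(background_sigma=1.0), layout16, patterns16
    )


@pytest.fixture(scope="session")
def annulus_phantom() -> PhantomSpec:
    """Centered circular inclusion with known analytic DN eigenvalues."""
    return PhantomSpec(
        1.0, [Inclusion("circle", (0.0, 0.0), (0.45, 0.45), 1.3)]
    )


@pytest.fixture(scope="session")
def annulus_data(mesh16, layout16, patterns16, annulus_phantom):
    return solve_forward_cem(mesh16, annulus_phantom, layout16, patterns16)


@pytest.fixture(scope="session")
def annulus_dmap(annulus_data, homog_data, layout16, patterns16):
    return delta_dn_from_data(
        patterns16.T, annulus_data.V, patterns16.T, homog_data.V,
        layout16.A, layout=layout16,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
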