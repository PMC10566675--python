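"""Shared fixtures: expensive meshes and solves are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from tpcvibe import modal_fem as mf
from tpcvibe.geometry import MaterialCard
from tpcvibe.synthetic_data import make_beam_mesh, make_toy_tpc, toy_material_cards


@pytest.fixture(scope="session")
def stiff_card():
    return MaterialCard(2400.0, 25e9, 0.3)


@pytest.fixture(scope="session")
def toy():
    """Default toy structure with ground truth."""
    return make_toy_tpc()


@pytest.fixture(scope="session")
def toy_materials():
    return toy_material_cards()


@pytest.fixture(scope="session")
def toy_system(toy, toy_materials):
    mesh, truth = toy
    return mf.assemble_system(mesh, toy_materials, truth["base_nodes"])


@pytest.fixture(scope="session")
def toy_solution(toy_system):
    return mf.solve_modes(toy_system, 16)


@pytest.fixture(scope="session")
def small_beam(stiff_card):
    """Coarse quadratic beam with its clamp nodes."""
    mesh = make_beam_mesh(0.3, 0.1, 0.1, (3, 1, 1), order=10)
    fixed = np.flatnonzero(mesh.nodes[:, 0] < 1e-12)
    return mesh, {"stiff_bone": stiff_card}, fixed


@pytest.fixture(scope="session")
def slender_beam_solution(stiff_card):
    """Slender cantilever solve used by the analytic-oracle tests."""
    length, width = 1.0, 0.05
    mesh = make_beam_mesh(length, width, width, (25, 2, 2), order=10)
    fixed = np.flatnonzero(mesh.nodes[:, 0] < 1e-12)
    system = mf.assemble_system(mesh, {"stiff_bone": stiff_card}, fixed)
    sol = mf.solve_modes(system, 5)
    return dict(
        mesh=mesh, system=system, solution=sol, length=length, width=width,
        card=stiff_card,
    )
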