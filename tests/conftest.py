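"""Shared fixtures: phantoms, materials, memoized solves, and block phantoms.

Field solves are the expensive part of the suite, so solved scenarios are
cached per session and shared across tests.  Block phantoms (bars, cylinders)
are hand-built voxel grids with Dirichlet end faces used as analytic oracles.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import ccdosim as cd
from ccdosim.contact import BodyModelMode
from ccdosim.paths import CurrentPath
from ccdosim.phantom import ElectrodePlacement, VoxelPhantom
from ccdosim.solver import (
    ContactScenario, assemble_system, derive_fields, solve_potential,
)
from ccdosim.tissues import DispersionModel, MaterialSet


@pytest.fixture(scope="session")
def materials() -> MaterialSet:
    return cd.default_materials()


@pytest.fixture(scope="session")
def tiny_config():
    return cd.PhantomConfig.tiny()


@pytest.fixture(scope="session")
def tiny_phantom(tiny_config):
    return cd.build_phantom(tiny_config)


@pytest.fixture(scope="session")
def default_phantom():
    return cd.build_phantom(cd.PhantomConfig())


@pytest.fixture(scope="session")
def default_phantom_no_vessels():
    return cd.build_phantom(
        dataclasses.replace(cd.PhantomConfig(), vessel_channels=False))


@pytest.fixture(scope="session")
def solve_cached(materials):
    """Memoized scenario solver shared by the whole session."""
    cache: dict = {}

    def run(phantom, label, frequency=50.0, voltage=220.0,
            mode=BodyModelMode.INTERN, mats=None, tolerance=1e-10,
            method="auto"):
        mats_key = tuple(sorted(mats.sigma_scales.items())) if mats is not None \
            else None
        key = (id(phantom), label, frequency, voltage, mode.value,
               mats_key, tolerance, method)
        if key not in cache:
            path = cd.expand_paths([label])[0]
            scen = ContactScenario(path=path, frequency=frequency,
                                   touch_voltage=voltage, mode=mode)
            cache[key] = cd.solve_scenario(phantom, mats or materials, scen,
                                           tolerance=tolerance, method=method)
        return cache[key]

    return run


@pytest.fixture(scope="session")
def dose_cached(solve_cached):
    cache: dict = {}

    def run(phantom, label, **kw):
        sol = solve_cached(phantom, label, **kw)
        if id(sol) not in cache:
            cache[id(sol)] = cd.evaluate_solution(sol)
        return cache[id(sol)]

    return run


# -- block phantoms (analytic oracles) --------------------------------------

BLOCK_PATH = CurrentPath("SRC-SNK", frozenset({"SRC"}), frozenset({"SNK"}))


def block_phantom(labels: np.ndarray, spacing: float,
                  tissue_map: dict[int, str]) -> VoxelPhantom:
    """Voxel block with Dirichlet electrodes on the two x-end faces."""
    vox = np.argwhere(labels != 0)
    src = vox[vox[:, 0] == 0]
    snk = vox[vox[:, 0] == labels.shape[0] - 1]
    return VoxelPhantom(
        labels=labels, spacing=np.array([spacing] * 3, float),
        origin=np.zeros(3), tissue_map=tissue_map,
        electrode_sites={}, electrode_normals={},
        heart_axes=np.zeros((3, 2, 3)),
        electrodes={
            "SRC": ElectrodePlacement("SRC", BodyModelMode.INTERN, 1.0, src, src),
            "SNK": ElectrodePlacement("SNK", BodyModelMode.INTERN, 1.0, snk, snk),
        })


def constant_materials(**sigmas: float) -> MaterialSet:
    return MaterialSet(models={
        name: DispersionModel(name, "constant", s, 1.0)
        for name, s in sigmas.items()})


def solve_block(labels, spacing, mats, tissue_map, voltage=1.0, frequency=0.0,
                method="auto", tolerance=1e-10, with_fields=True):
    phantom = block_phantom(labels, spacing, tissue_map)
    scen = ContactScenario(path=BLOCK_PATH, frequency=frequency,
                           touch_voltage=voltage, mode=BodyModelMode.INTERN)
    system = assemble_system(phantom, mats, scen)
    sol = solve_potential(system, tolerance=tolerance, method=method)
    if with_fields:
        sol = derive_fields(sol)
    return sol, system


@pytest.fixture(scope="session")
def bar_solution():
    """Homogeneous bar, sigma = 0.5 S/m, 2 mm voxels, 1 V drive."""
    labels = np.ones((11, 5, 5), np.uint8)
    mats = constant_materials(m1=0.5)
    sol, system = solve_block(labels, 2.0, mats, {1: "m1"})
    return sol, system, mats
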