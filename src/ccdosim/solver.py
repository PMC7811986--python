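"""Electro-quasi-static voxel solver.

Below ~1 MHz the electric field in the body obeys the complex Laplace problem

    div( sigma*(x, f) grad(phi) ) = 0,   sigma* = sigma + j*2*pi*f*eps0*eps_r,

driven by Dirichlet electrode potentials (the touch voltage on the source
set, 0 V on the sink set) with homogeneous Neumann conditions at the body-air
surface (displacement currents through air are negligible at these
frequencies, so air is excluded from the domain entirely).

Discretization is finite-volume on the uniform voxel grid: the standard
7-point stencil with harmonic-mean face admittances, which keeps the normal
current continuous across material interfaces (an arithmetic mean would
overestimate current through thin resistive layers such as the contact-skin
slice).  The assembled operator is complex symmetric; for real sigma* (DC) it
is symmetric positive definite after Dirichlet elimination.

Solvers: sparse LU for small systems and as an oracle; Jacobi-preconditioned
CG (DC) or BiCGSTAB (AC) above the direct-size threshold.  Everything is
deterministic -- there is no randomness anywhere in the pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .contact import BodyModelMode
from .paths import CurrentPath
from .phantom import AIR, VoxelPhantom, place_electrode
from .tissues import MaterialSet

__all__ = [
    "ContactScenario", "LinearSystem", "FieldSolution", "ConvergenceError",
    "prepare_phantom", "assemble_system", "solve_potential", "derive_fields",
    "solve_scenario",
]


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual_history: Sequence[float] = ()):
        super().__init__(message)
        self.residual_history = list(residual_history)


@dataclass(frozen=True)
class ContactScenario:
    """Boundary conditions of one solve."""

    path: CurrentPath
    frequency: float          # Hz; DC is 0
    touch_voltage: float      # V
    mode: BodyModelMode       # TOTAL or INTERN

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise ValueError("frequency must be >= 0")
        if self.touch_voltage <= 0:
            raise ValueError("touch voltage must be > 0")
        if self.mode not in (BodyModelMode.TOTAL, BodyModelMode.INTERN):
            raise ValueError(
                "a solve needs a concrete body model (TOTAL or INTERN); "
                "resolve CASE_BY_CASE scenarios explicitly")


@dataclass
class LinearSystem:
    """Dirichlet-eliminated sparse system plus the grid bookkeeping."""

    matrix: sp.csr_matrix          # A_ff
    rhs: np.ndarray                # -A_fd x_d
    free_flat: np.ndarray          # flat grid indices of the unknowns
    dirichlet_flat: np.ndarray
    dirichlet_values: np.ndarray
    sigma_star: np.ndarray         # per-voxel complex conductivity grid
    shape: tuple[int, int, int]
    scenario: ContactScenario
    phantom: VoxelPhantom


@dataclass
class FieldSolution:
    """Complex potential (V) and, after derive_fields, E (V/m) and J (A/m^2)."""

    potential: np.ndarray               # grid, complex (0 in air)
    frequency: float
    residual: float
    scenario: ContactScenario
    phantom: VoxelPhantom
    sigma_star: np.ndarray
    iterations: int = 0
    e_field: np.ndarray | None = None   # grid + component axis (..., 3)
    j_field: np.ndarray | None = None


def prepare_phantom(phantom: VoxelPhantom, scenario: ContactScenario) -> VoxelPhantom:
    """Place electrodes at every source and sink site of the scenario."""
    for site in sorted(scenario.path.source_sites | scenario.path.sink_sites):
        phantom = place_electrode(phantom, site, scenario.mode, scenario.touch_voltage)
    return phantom


def _face_conductance(sig: np.ndarray, axis: int, spacing: np.ndarray) -> np.ndarray:
    """Harmonic-mean conductance [S] of the faces along ``axis``.

    sig is the per-voxel sigma* grid (0 in air); faces touching air get 0.
    Geometric factor: face area / center distance, converted from mm to m.
    """
    sl1 = [slice(None)] * 3
    sl2 = [slice(None)] * 3
    sl1[axis] = slice(0, -1)
    sl2[axis] = slice(1, None)
    s1 = sig[tuple(sl1)]
    s2 = sig[tuple(sl2)]
    denom = s1 + s2
    with np.errstate(divide="ignore", invalid="ignore"):
        hm = np.where(denom != 0, 2.0 * s1 * s2 / np.where(denom != 0, denom, 1), 0)
    hm = np.where((s1 == 0) | (s2 == 0), 0, hm)
    other = [a for a in range(3) if a != axis]
    geom = spacing[other[0]] * spacing[other[1]] / spacing[axis] * 1e-3
    return hm * geom


def assemble_system(
    phantom: VoxelPhantom,
    materials: MaterialSet,
    scenario: ContactScenario,
) -> LinearSystem:
    """Finite-volume assembly of div(sigma* grad phi) = 0 on the phantom.

    Requires electrodes already placed for every site of the scenario (use
    :func:`prepare_phantom` or :func:`solve_scenario`).  Air voxels are not
    unknowns; faces to air carry zero flux.  Electrode drive voxels become
    Dirichlet rows (eliminated from the system).
    """
    need = scenario.path.source_sites | scenario.path.sink_sites
    missing = sorted(need - set(phantom.electrodes))
    if missing:
        raise ValueError(f"electrodes not placed for sites: {missing}")
    for site in sorted(need):
        if phantom.electrodes[site].mode is not scenario.mode:
            raise ValueError(
                f"electrode {site} placed in {phantom.electrodes[site].mode}, "
                f"scenario wants {scenario.mode}")

    sig = materials.sigma_star_grid(phantom, scenario.frequency)
    if scenario.frequency == 0:
        sig = sig.real  # real-arithmetic fast path at DC
    shape = phantom.labels.shape
    n_grid = int(np.prod(shape))
    mask = phantom.labels != AIR

    dirichlet = np.zeros(shape, dtype=bool)
    dvalues = np.zeros(shape, dtype=float)
    for site in sorted(scenario.path.source_sites):
        c = phantom.electrodes[site].contact
        dirichlet[c[:, 0], c[:, 1], c[:, 2]] = True
        dvalues[c[:, 0], c[:, 1], c[:, 2]] = scenario.touch_voltage
    for site in sorted(scenario.path.sink_sites):
        c = phantom.electrodes[site].contact
        dirichlet[c[:, 0], c[:, 1], c[:, 2]] = True
        dvalues[c[:, 0], c[:, 1], c[:, 2]] = 0.0

    idx = np.arange(n_grid).reshape(shape)
    rows, cols, vals = [], [], []
    diag = np.zeros(n_grid, dtype=sig.dtype)
    for axis in range(3):
        g = _face_conductance(sig, axis, phantom.spacing)
        sl1 = [slice(None)] * 3
        sl2 = [slice(None)] * 3
        sl1[axis] = slice(0, -1)
        sl2[axis] = slice(1, None)
        live = g != 0
        i1 = idx[tuple(sl1)][live]
        i2 = idx[tuple(sl2)][live]
        gv = g[live]
        rows += [i1, i2]
        cols += [i2, i1]
        vals += [-gv, -gv]
        np.add.at(diag, i1, gv)
        np.add.at(diag, i2, gv)

    free = mask & ~dirichlet
    free_flat = np.flatnonzero(free)
    diri_flat = np.flatnonzero(dirichlet)
    rows.append(np.arange(n_grid))
    cols.append(np.arange(n_grid))
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_grid, n_grid))
    Aff = A[free_flat][:, free_flat]
    Afd = A[free_flat][:, diri_flat]
    b = -(Afd @ dvalues.ravel()[diri_flat]).astype(sig.dtype)
    return LinearSystem(
        matrix=Aff.tocsr(), rhs=b,
        free_flat=free_flat, dirichlet_flat=diri_flat,
        dirichlet_values=dvalues.ravel()[diri_flat],
        sigma_star=sig, shape=shape, scenario=scenario, phantom=phantom)


#: systems at or below this many unknowns are solved with sparse LU by default
DIRECT_LIMIT = 20_000


def solve_potential(
    system: LinearSystem,
    tolerance: float = 1e-8,
    max_iter: int = 20_000,
    method: str = "auto",
) -> FieldSolution:
    """Solve for the complex potential; relative residual <= ``tolerance``.

    ``method``: "auto" (direct below :data:`DIRECT_LIMIT` unknowns, else
    Krylov), "direct", or "iterative".  Deterministic for identical inputs.
    """
    A, b = system.matrix, system.rhs
    n = A.shape[0]
    if method == "auto":
        method = "direct" if n <= DIRECT_LIMIT else "iterative"

    bnorm = float(np.linalg.norm(b))
    if bnorm == 0:
        raise ValueError("zero right-hand side: no drive potential reaches the body")

    iterations = 0
    if method == "direct":
        x = spla.spsolve(A.tocsc(), b)
    elif method == "iterative":
        x, iterations = _krylov(A, b, tolerance, max_iter)
    else:
        raise ValueError(f"unknown method {method!r}")

    residual = float(np.linalg.norm(A @ x - b)) / bnorm
    if residual > tolerance:
        raise ConvergenceError(
            f"solver residual {residual:.3e} exceeds tolerance {tolerance:.1e} "
            f"({method}, {iterations} iterations)")

    phi = np.zeros(int(np.prod(system.shape)),
                   dtype=complex if np.iscomplexobj(system.sigma_star) else float)
    phi[system.free_flat] = x
    phi[system.dirichlet_flat] = system.dirichlet_values
    phi = phi.reshape(system.shape).astype(complex)
    return FieldSolution(
        potential=phi,
        frequency=system.scenario.frequency,
        residual=residual,
        scenario=system.scenario,
        phantom=system.phantom,
        sigma_star=system.sigma_star,
        iterations=iterations)


def _krylov(A, b, tolerance, max_iter):
    """Jacobi-preconditioned CG (real SPD) or BiCGSTAB (complex symmetric)."""
    M = sp.diags(1.0 / A.diagonal())
    counter = {"n": 0}
    history: list[float] = []

    def cb(_):
        counter["n"] += 1

    rtol = max(tolerance * 1e-2, 1e-14)
    if np.iscomplexobj(b) or np.iscomplexobj(A.data):
        x, info = spla.bicgstab(A, b, rtol=rtol, atol=0.0, maxiter=max_iter,
                                M=M, callback=cb)
    else:
        x, info = spla.cg(A, b, rtol=rtol, atol=0.0, maxiter=max_iter,
                          M=M, callback=cb)
    if info != 0:
        res = float(np.linalg.norm(A @ x - b) / np.linalg.norm(b))
        raise ConvergenceError(
            f"Krylov solver did not converge (info={info}, "
            f"{counter['n']} iterations, residual {res:.3e})",
            residual_history=history + [res])
    return x, counter["n"]


def derive_fields(solution: FieldSolution) -> FieldSolution:
    """Fill E = -grad(phi) [V/m] and J = sigma* E [A/m^2].

    Central differences at interior voxels, one-sided at the body surface
    (air neighbours are excluded; a voxel with no body neighbour along an
    axis gets zero component).  Components are complex phasors.
    """
    phi = solution.potential
    phantom = solution.phantom
    mask = phantom.labels != AIR
    spacing_m = phantom.spacing * 1e-3
    E = np.zeros(phi.shape + (3,), dtype=complex)
    for axis in range(3):
        up = _shifted(phi, axis, +1)
        dn = _shifted(phi, axis, -1)
        mup = _shifted(mask, axis, +1)
        mdn = _shifted(mask, axis, -1)
        h = spacing_m[axis]
        grad = np.zeros_like(phi)
        both = mup & mdn
        grad[both] = (up[both] - dn[both]) / (2 * h)
        up_only = mup & ~mdn
        grad[up_only] = (up[up_only] - phi[up_only]) / h
        dn_only = mdn & ~mup
        grad[dn_only] = (phi[dn_only] - dn[dn_only]) / h
        E[..., axis] = -grad
    E[~mask] = 0
    J = E * solution.sigma_star[..., None]
    return dataclasses.replace(solution, e_field=E, j_field=J)


def _shifted(arr: np.ndarray, axis: int, sign: int) -> np.ndarray:
    out = np.zeros_like(arr)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if sign > 0:
        src[axis] = slice(1, None)
        dst[axis] = slice(0, -1)
    else:
        src[axis] = slice(0, -1)
        dst[axis] = slice(1, None)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def solve_scenario(
    phantom: VoxelPhantom,
    materials: MaterialSet,
    scenario: ContactScenario,
    tolerance: float = 1e-8,
    max_iter: int = 20_000,
    method: str = "auto",
    with_fields: bool = True,
) -> FieldSolution:
    """Place electrodes, assemble, solve, and derive E and J."""
    prepared = prepare_phantom(phantom, scenario)
    system = assemble_system(prepared, materials, scenario)
    solution = solve_potential(system, tolerance=tolerance, max_iter=max_iter,
                               method=method)
    if with_fields:
        solution = derive_fields(solution)
    return solution
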