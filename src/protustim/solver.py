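"""DC volume-conductor solver on labeled voxel grids.

Solves the steady-state conduction problem ∇·(σ∇V) = 0 over the liquid
region with:

* insulating (zero normal flux) boundaries at substrate surfaces and at the
  domain truncation box (∇V·n = 0),
* a mixed (Robin) electrode–electrolyte condition σ∇V·n = g (V_metal − V) on
  metal surfaces, with surface conductance g in S/m², or its g → ∞ ideal
  (Dirichlet) limit,
* optionally a grounded top or grounded far-field box.

Discretization is a cell-centered finite-volume scheme on the uniform voxel
grid: interior face conductances are harmonic means of the adjacent voxel
conductivities times face area over spacing; electrode faces carry the
interface conductance in series with the half-cell bulk path, so the ideal
limit is the exact discrete Dirichlet condition at the metal face.  The
resulting system is symmetric positive definite and is solved by
Jacobi-preconditioned conjugate gradients with a fixed node ordering, so the
solve is deterministic.

By default only liquid voxels are unknowns: insulator faces are zero-flux,
which is the exact σ_insulator → 0 limit (the tabulated 1.31e-18 S/m is
indistinguishable from zero at machine precision, and keeping the insulator
block would add a floating, numerically singular subsystem).  Pass
``include_insulator=True`` to keep insulator voxels as unknowns with their
tabulated conductivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import (
    CONDUCTOR,
    GROUND,
    INSULATOR,
    LIQUID,
    NO_ELECTRODE,
    STIM,
    LabeledGrid,
    MaterialProps,
)

UM = 1e-6  # meters per micrometer


class ConvergenceError(RuntimeError):
    """Iterative solve failed to reach the requested residual."""


@dataclass(frozen=True)
class BoundarySpec:
    """Applied electrode potentials and interface model.

    ``g_interface`` is the electrode–electrolyte surface conductance g of the
    Robin condition σ∇V·n = g (V_metal − V), in S/m².  ``ideal=True`` takes
    the g → ∞ (Dirichlet) limit; field comparisons between geometries are run
    ideal by default so they do not hinge on the unknown interface constant.
    ``outer_boundary`` selects the truncation condition on the domain box:
    all-insulating, a grounded (0 V) top face, or grounded top + sides
    ("grounded_far", used for open-bath analytic comparisons).
    """

    v_metal_stim: float = 1.0
    v_metal_ground: float = 0.0
    g_interface: float = 1.0e3
    ideal: bool = False
    outer_boundary: Literal["insulating", "grounded_top", "grounded_far"] = "insulating"

    def __post_init__(self) -> None:
        if not self.ideal and self.g_interface <= 0:
            raise ValueError("g_interface must be > 0 (or set ideal=True)")
        if self.outer_boundary not in ("insulating", "grounded_top", "grounded_far"):
            raise ValueError(f"unknown outer_boundary {self.outer_boundary!r}")


@dataclass
class AssembledSystem:
    """Sparse SPD system A v = b over the solve region, plus the node map."""

    matrix: sp.csr_matrix
    rhs: np.ndarray
    index_of: np.ndarray        # voxel -> unknown index, -1 outside the solve region
    grid: LabeledGrid
    materials: MaterialProps
    boundary: BoundarySpec


@dataclass
class FieldSolution:
    """Nodal potential and derived current density on the grid.

    ``potential`` is V in volts per voxel: solved values in the liquid (and
    insulator, if included), the applied metal potential in conductor voxels,
    NaN elsewhere.  ``current_density`` is J = −σ∇V in A/m², shape
    (nx, ny, nz, 3), NaN outside the liquid.
    """

    potential: np.ndarray
    residual_norm: float
    boundary: BoundarySpec
    grid: LabeledGrid
    materials: MaterialProps
    index_of: np.ndarray
    current_density: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def liquid_mask(self) -> np.ndarray:
        return self.grid.labels == LIQUID

    def jmag(self) -> np.ndarray:
        if self.current_density is None:
            raise ValueError("current density not computed yet")
        return np.sqrt(np.sum(self.current_density**2, axis=-1))


def _metal_potential(boundary: BoundarySpec, electrode_id: int) -> float:
    return boundary.v_metal_stim if electrode_id == STIM else boundary.v_metal_ground


def _electrode_face_conductance(sigma_vox: float, h_m: float,
                                boundary: BoundarySpec) -> float:
    """Conductance (S) of one electrode face: interface g in series with the
    half-cell bulk path; ideal mode is the g → ∞ Dirichlet limit."""
    half_cell = 2.0 * sigma_vox / h_m  # per area
    if boundary.ideal:
        k = half_cell
    else:
        k = 1.0 / (1.0 / boundary.g_interface + 1.0 / half_cell)
    return k * h_m**2


def assemble_system(grid: LabeledGrid, materials: MaterialProps,
                    boundary: BoundarySpec,
                    include_insulator: bool = False) -> AssembledSystem:
    """Build the finite-volume system over liquid (and optionally insulator) voxels.

    Interior faces between two solve voxels get conductance
    A/h · harmonic_mean(σ₁, σ₂); faces adjoining a conductor voxel couple the
    node to that electrode's metal potential through the Robin face
    conductance; exterior faces are zero-flux, except Dirichlet 0 V on the
    top (and sides, for "grounded_far") when requested.  The matrix is
    symmetric and weakly diagonally dominant.
    """
    grid.validate()
    labels = grid.labels
    h_m = grid.spacing_um * UM
    solve_mask = labels == LIQUID
    if include_insulator:
        solve_mask |= labels == INSULATOR

    n = int(np.count_nonzero(solve_mask))
    if n == 0:
        raise ValueError("no solvable voxels in grid")
    index_of = np.full(grid.dims, -1, dtype=np.int64)
    index_of[solve_mask] = np.arange(n)

    sigma = materials.sigma_of(labels)
    diag = np.zeros(n)
    rhs = np.zeros(n)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    any_stim_face = False
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        lo, hi = tuple(sl_lo), tuple(sl_hi)

        both = solve_mask[lo] & solve_mask[hi]
        if np.any(both):
            s1 = sigma[lo][both]
            s2 = sigma[hi][both]
            c = (2.0 * s1 * s2 / (s1 + s2)) * h_m  # sigma_hm * A / h
            i1 = index_of[lo][both]
            i2 = index_of[hi][both]
            rows.append(i1)
            cols.append(i2)
            vals.append(-c)
            rows.append(i2)
            cols.append(i1)
            vals.append(-c)
            np.add.at(diag, i1, c)
            np.add.at(diag, i2, c)

        # faces between a solve voxel and a conductor voxel: Robin coupling
        for a, b in ((lo, hi), (hi, lo)):
            face = solve_mask[a] & (labels[b] == CONDUCTOR)
            if not np.any(face):
                continue
            idx = index_of[a][face]
            eids = grid.electrode_ids[b][face]
            svox = sigma[a][face]
            vmetal = np.where(
                eids == STIM, boundary.v_metal_stim, boundary.v_metal_ground
            )
            if np.any(eids == NO_ELECTRODE):
                raise ValueError("conductor voxel without electrode tag at interface")
            cond = np.array(
                [_electrode_face_conductance(s, h_m, boundary) for s in svox]
            )
            np.add.at(diag, idx, cond)
            np.add.at(rhs, idx, cond * vmetal)
            if np.any(eids == STIM):
                any_stim_face = True

    if not any_stim_face:
        raise ValueError("no liquid voxel adjacent to the stimulating electrode")

    # outer box Dirichlet faces (grounded top / far field)
    if boundary.outer_boundary in ("grounded_top", "grounded_far"):
        faces = [(2, -1)]
        if boundary.outer_boundary == "grounded_far":
            faces += [(0, 0), (0, -1), (1, 0), (1, -1)]
        for axis, side in faces:
            sl = [slice(None)] * 3
            sl[axis] = side
            sl = tuple(sl)
            face = solve_mask[sl]
            idx = index_of[sl][face]
            svox = sigma[sl][face]
            cond = (2.0 * svox / h_m) * h_m**2  # Dirichlet half-cell conductance
            np.add.at(diag, idx, cond)
            # V = 0 there: no rhs contribution

    all_rows = np.concatenate(rows + [np.arange(n)])
    all_cols = np.concatenate(cols + [np.arange(n)])
    all_vals = np.concatenate(vals + [diag])
    A = sp.csr_matrix((all_vals, (all_rows, all_cols)), shape=(n, n))
    A.sum_duplicates()

    if boundary.outer_boundary == "insulating" and not np.any(rhs != 0) and \
            boundary.v_metal_stim == boundary.v_metal_ground == 0:
        pass  # homogeneous problem; solution is trivially zero
    if np.all(diag == 0):
        raise ValueError("singular system: no boundary attachment")
    return AssembledSystem(A, rhs, index_of, grid, materials, boundary)


def solve_potential(system: AssembledSystem, tol: float = 1e-9,
                    max_iter: int = 20000) -> FieldSolution:
    """Conjugate-gradient solve to relative residual ≤ tol (Jacobi preconditioned)."""
    A, b = system.matrix, system.rhs
    d = A.diagonal()
    if np.any(d <= 0):
        raise ValueError("non-positive diagonal: system not SPD")
    M = sp.diags(1.0 / d)
    x, info = spla.cg(A, b, rtol=tol, atol=0.0, maxiter=max_iter, M=M)
    bnorm = np.linalg.norm(b)
    res = float(np.linalg.norm(A @ x - b) / (bnorm if bnorm > 0 else 1.0))
    if info != 0:
        raise ConvergenceError(
            f"CG did not converge in {max_iter} iterations (residual {res:.3e})"
        )

    V = np.full(system.grid.dims, np.nan)
    V[system.index_of >= 0] = x
    cond = system.grid.labels == CONDUCTOR
    V[cond] = np.where(
        system.grid.electrode_ids[cond] == STIM,
        system.boundary.v_metal_stim,
        system.boundary.v_metal_ground,
    )
    sol = FieldSolution(
        potential=V,
        residual_norm=res,
        boundary=system.boundary,
        grid=system.grid,
        materials=system.materials,
        index_of=system.index_of,
    )
    sol.current_density = compute_current_density(sol)
    return sol


def compute_current_density(solution: FieldSolution) -> np.ndarray:
    """J = −σ∇V (A/m²) on liquid voxels; NaN elsewhere.

    Each component is the mean of the two discrete face fluxes of the
    finite-volume scheme along that axis: harmonic-mean conductance between
    liquid neighbours (which reduces to the central difference in the
    interior), the Robin/Dirichlet face flux at electrode surfaces, and zero
    at insulating faces — so the field is exactly the one the solver
    conserves, one-sided only where the discretization itself is.
    """
    V = solution.potential
    grid = solution.grid
    labels = grid.labels
    h_m = grid.spacing_um * UM
    liquid = labels == LIQUID
    sigma_l = solution.materials.sigma_liquid
    boundary = solution.boundary
    k_elec_per_area = _electrode_face_conductance(sigma_l, h_m, boundary) / h_m**2

    J = np.full(grid.dims + (3,), np.nan)
    for axis in range(3):
        # face flux toward the +axis neighbour (A/m², positive = current
        # flowing in +axis direction), per voxel; 0 at insulating faces
        flux_p = np.zeros(grid.dims)
        flux_m = np.zeros(grid.dims)
        Vp = np.roll(V, -1, axis=axis)
        Vm = np.roll(V, 1, axis=axis)
        lab_p = np.roll(labels, -1, axis=axis)
        lab_m = np.roll(labels, 1, axis=axis)
        interior_p = np.zeros(grid.dims, dtype=bool)
        interior_m = np.zeros(grid.dims, dtype=bool)
        sl = [slice(None)] * 3
        sl[axis] = slice(None, -1)
        interior_p[tuple(sl)] = True
        sl = [slice(None)] * 3
        sl[axis] = slice(1, None)
        interior_m[tuple(sl)] = True

        ll = interior_p & (lab_p == LIQUID)
        flux_p[ll] = sigma_l * (V[ll] - Vp[ll]) / h_m
        lc = interior_p & (lab_p == CONDUCTOR)
        flux_p[lc] = -k_elec_per_area * (Vp[lc] - V[lc])  # Vp = metal potential

        ll = interior_m & (lab_m == LIQUID)
        flux_m[ll] = sigma_l * (Vm[ll] - V[ll]) / h_m
        lc = interior_m & (lab_m == CONDUCTOR)
        flux_m[lc] = k_elec_per_area * (Vm[lc] - V[lc])

        J[..., axis] = np.where(liquid, 0.5 * (flux_p + flux_m), np.nan)
    return J


def electrode_current(solution: FieldSolution, electrode_id: int) -> float:
    """Total current (A) leaving the tagged metal into the liquid.

    Sums the Robin face fluxes k·(V_metal − V_node)·A over every face between
    a solve voxel and a conductor voxel carrying ``electrode_id``; positive
    means current flows from the metal into the electrolyte.
    """
    grid = solution.grid
    if electrode_id not in (STIM, GROUND):
        raise KeyError(f"unknown electrode id {electrode_id}")
    if not np.any(grid.electrode_ids == electrode_id):
        raise KeyError(f"grid has no electrode with id {electrode_id}")
    labels = grid.labels
    h_m = grid.spacing_um * UM
    solve_mask = ~np.isnan(solution.potential) & (labels != CONDUCTOR)
    sigma = solution.materials.sigma_of(labels)
    vmetal = _metal_potential(solution.boundary, electrode_id)

    total = 0.0
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        lo, hi = tuple(sl_lo), tuple(sl_hi)
        for a, b in ((lo, hi), (hi, lo)):
            face = (
                solve_mask[a]
                & (labels[b] == CONDUCTOR)
                & (solution.grid.electrode_ids[b] == electrode_id)
            )
            if not np.any(face):
                continue
            vnode = solution.potential[a][face]
            svox = sigma[a][face]
            cond = np.array(
                [
                    _electrode_face_conductance(s, h_m, solution.boundary)
                    for s in svox
                ]
            )
            total += float(np.sum(cond * (vmetal - vnode)))
    return total


def boundary_current(solution: FieldSolution) -> float:
    """Current (A) leaving the domain through grounded outer faces (0 if none)."""
    if solution.boundary.outer_boundary == "insulating":
        return 0.0
    grid = solution.grid
    h_m = grid.spacing_um * UM
    sigma = solution.materials.sigma_of(grid.labels)
    faces = [(2, -1)]
    if solution.boundary.outer_boundary == "grounded_far":
        faces += [(0, 0), (0, -1), (1, 0), (1, -1)]
    total = 0.0
    for axis, side in faces:
        sl = [slice(None)] * 3
        sl[axis] = side
        sl = tuple(sl)
        mask = ~np.isnan(solution.potential[sl]) & (grid.labels[sl] != CONDUCTOR)
        v = solution.potential[sl][mask]
        s = sigma[sl][mask]
        total += float(np.sum((2.0 * s / h_m) * h_m**2 * v))
    return total


def solve(grid: LabeledGrid, materials: MaterialProps | None = None,
          boundary: BoundarySpec | None = None, tol: float = 1e-9,
          max_iter: int = 20000, include_insulator: bool = False) -> FieldSolution:
    """Assemble and solve in one call with default materials/boundaries."""
    materials = materials or MaterialProps()
    boundary = boundary or BoundarySpec(ideal=True)
    system = assemble_system(grid, materials, boundary, include_insulator)
    return solve_potential(system, tol=tol, max_iter=max_iter)


def solution_summary(solution: FieldSolution) -> dict:
    """Scalar summary (currents, residual, extrema) as a JSON-ready dict."""
    liquid = solution.liquid_mask
    i_stim = electrode_current(solution, STIM)
    i_gnd = electrode_current(solution, GROUND)
    i_box = boundary_current(solution)
    return {
        "stim_current_A": i_stim,
        "ground_current_A": i_gnd,
        "outer_boundary_current_A": i_box,
        "net_current_A": i_stim + i_gnd - i_box,
        "residual_norm": solution.residual_norm,
        "v_min_liquid": float(np.nanmin(solution.potential[liquid])),
        "v_max_liquid": float(np.nanmax(solution.potential[liquid])),
        "jmag_max_liquid": float(np.nanmax(solution.jmag()[liquid])),
    }


def save_summary_json(path, solution: FieldSolution) -> None:
    with open(path, "w") as fh:
        json.dump(solution_summary(solution), fh, indent=2)
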