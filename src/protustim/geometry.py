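"""Voxel geometries for protuberant subretinal microelectrode structures.

The structures modeled here are hexagonal wells etched in an insulating
substrate, with a planar stimulating electrode disc at the bottom, zero to
four "mushroom" pillars (cylindrical stem plus a wider flat cap) standing on
the electrode, and a grounded return plane at the well rim, perforated by the
well opening.  Everything else is physiological liquid.

Coordinate convention: array axes are (x, y, z) with z the depth axis normal
to the implant plane and y the well-width axis along which line profiles are
taken.  z = 0 is the top surface of the stimulating electrode disc (the well
floor); positive z points away from the substrate into the liquid.  Voxel
(i, j, k) has its physical center at ``origin + (i + 0.5, j + 0.5, k + 0.5) *
spacing_um``.

A configuration family is coded X/Y/Z: X = well length (hexagon flat-to-flat
width), Y = planar electrode diameter, Z = pillar base (stem) diameter, all
in micrometers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import yaml

# material labels
LIQUID = 0
INSULATOR = 1
CONDUCTOR = 2

# electrode tags
NO_ELECTRODE = 0
STIM = 1
GROUND = 2

MATERIAL_NAMES = {LIQUID: "liquid", INSULATOR: "insulator", CONDUCTOR: "conductor"}


class GeometryError(ValueError):
    """Raised when a structure cannot be realized (layout exceeds electrode...)."""


class ResolutionError(ValueError):
    """Raised when the voxel spacing is too coarse to resolve a feature."""


@dataclass(frozen=True)
class StructureConfig:
    """One well/electrode/pillar configuration (the X/Y/Z family).

    Parameters
    ----------
    well_length_um:
        X — flat-to-flat width of the hexagonal well, µm.
    electrode_diameter_um:
        Y — diameter of the planar stimulating electrode disc, µm.
    pillar_base_diameter_um:
        Z — diameter of the cylindrical pillar stem, µm.
    n_protuberances:
        Number of mushroom pillars on the electrode, 0–4.
    pillar_height_um:
        Total pillar height including the cap (≈7 µm for the fabricated
        devices).
    cap_diameter_um:
        Diameter of the flat cap disc terminating each pillar (the measured
        mushroom tops are ~15 µm wide over a ~10.5 µm stem).
    well_depth_um:
        Depth of the well from rim to floor.  Must exceed the pillar height
        so the mushrooms stay inside the cavity; the default leaves a liquid
        region ~2.5× the pillar height between the caps and the rim.
    ground_grid_thickness_um:
        Thickness of the electroplated return plane sitting on the rim.
    inter_cavity_separation_um:
        Wall width between neighbouring cavities on a full array (kept for
        provenance; single-cavity grids use it as the lateral liquid/substrate
        border beyond the well).
    cavity_cross_section:
        "hexagon" (fabricated shape) or "circle" (axisymmetric variant used
        for analytic cross-checks).
    """

    well_length_um: float
    electrode_diameter_um: float
    pillar_base_diameter_um: float
    n_protuberances: int = 0
    pillar_height_um: float = 7.0
    cap_diameter_um: float = 15.0
    well_depth_um: float = 25.0
    ground_grid_thickness_um: float = 10.0
    inter_cavity_separation_um: float = 16.0
    cavity_cross_section: str = "hexagon"

    def __post_init__(self) -> None:
        x, y, z = (
            self.well_length_um,
            self.electrode_diameter_um,
            self.pillar_base_diameter_um,
        )
        positives = (
            x, y, z, self.pillar_height_um, self.cap_diameter_um,
            self.well_depth_um, self.ground_grid_thickness_um,
            self.inter_cavity_separation_um,
        )
        if any(v <= 0 for v in positives):
            raise ValueError("all dimensions must be strictly positive")
        if not y < x:
            raise ValueError(f"electrode diameter Y={y} must be < well length X={x}")
        if not z < y:
            raise ValueError(f"pillar base Z={z} must be < electrode diameter Y={y}")
        if self.n_protuberances not in (0, 1, 2, 3, 4):
            raise ValueError("n_protuberances must be in {0,1,2,3,4}")
        if self.cap_diameter_um < self.pillar_base_diameter_um:
            raise ValueError("cap diameter must be >= pillar base diameter")
        if self.cavity_cross_section not in ("hexagon", "circle"):
            raise ValueError("cavity_cross_section must be 'hexagon' or 'circle'")

    @property
    def code(self) -> str:
        """The X/Y/Z identification code, e.g. ``'100/80/12'``."""
        def fmt(v: float) -> str:
            return str(int(v)) if float(v).is_integer() else str(v)
        return "/".join(
            fmt(v)
            for v in (
                self.well_length_um,
                self.electrode_diameter_um,
                self.pillar_base_diameter_um,
            )
        )


@dataclass(frozen=True)
class MaterialProps:
    """Homogeneous, isotropic material parameters of the model.

    Defaults are the simulation parameters used throughout: physiological
    liquid 1.47e-2 S/m, insulating polymer 1.31e-18 S/m, electroplated metal
    45.6e6 S/m.  Relative permittivities are stored for completeness but the
    solve is DC steady state, so they are never used.
    """

    sigma_liquid: float = 1.47e-2
    sigma_insulator: float = 1.31e-18
    sigma_conductor: float = 45.6e6
    eps_r_liquid: float = 81.0
    eps_r_insulator: float = 3.4

    def __post_init__(self) -> None:
        if min(self.sigma_liquid, self.sigma_insulator, self.sigma_conductor) <= 0:
            raise ValueError("conductivities must be > 0")
        if not (self.sigma_insulator < self.sigma_liquid < self.sigma_conductor):
            raise ValueError("expected sigma_insulator << sigma_liquid << sigma_conductor")

    def sigma_of(self, labels: np.ndarray) -> np.ndarray:
        table = np.array(
            [self.sigma_liquid, self.sigma_insulator, self.sigma_conductor]
        )
        return table[labels]


@dataclass
class LabeledGrid:
    """Regular voxel grid with per-voxel material and electrode tags.

    ``labels`` holds LIQUID / INSULATOR / CONDUCTOR, ``electrode_ids`` holds
    NO_ELECTRODE / STIM / GROUND; electrode tags only appear on conductor
    voxels.  ``origin`` is the physical coordinate (µm) of the lower corner of
    voxel (0, 0, 0); ``meta`` records the construction parameters (well
    center, floor level, ...) so downstream analysis can place sampling lines
    without re-deriving the geometry.
    """

    spacing_um: float
    labels: np.ndarray
    electrode_ids: np.ndarray
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)

    def centers(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates (µm) along one axis."""
        n = self.labels.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing_um

    def validate(self) -> None:
        if self.labels.shape != self.electrode_ids.shape:
            raise ValueError("labels and electrode_ids shapes differ")
        tagged = self.electrode_ids != NO_ELECTRODE
        if np.any(self.labels[tagged] != CONDUCTOR):
            raise ValueError("electrode-tagged voxel with non-conductor material")
        if not np.any(self.electrode_ids == STIM) or not np.any(
            self.electrode_ids == GROUND
        ):
            raise ValueError("grid must contain both a stimulating and a ground electrode")

    def material_volume_um3(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.spacing_um**3


def protuberance_layout(n: int, electrode_diameter_um: float,
                        radius_fraction: float = 0.5) -> list[tuple[float, float]]:
    """Deterministic (x, y) pillar-center coordinates relative to the well center.

    ``n`` = 0 gives no pillars; 1 the electrode center; 2 a symmetric pair on
    the y (well-width) axis so that sampling lines cross both; 3 an
    equilateral triangle with one vertex toward +y; 4 a square with vertices
    on the diagonals (mirror-symmetric in both x and y).  Off-center pillars
    sit at ``radius_fraction`` of the electrode radius.
    """
    if n not in (0, 1, 2, 3, 4):
        raise ValueError("n must be in {0,1,2,3,4}")
    r = radius_fraction * electrode_diameter_um / 2.0
    if n == 0:
        return []
    if n == 1:
        return [(0.0, 0.0)]
    if n == 2:
        return [(0.0, -r), (0.0, r)]
    if n == 3:
        angles = np.deg2rad([90.0, 210.0, 330.0])
        return [(float(r * np.cos(a)), float(r * np.sin(a))) for a in angles]
    d = r / np.sqrt(2.0)
    return [(-d, -d), (-d, d), (d, -d), (d, d)]


def standard_configs(n_protuberances: int = 0) -> list[StructureConfig]:
    """The fabricated X/Y/Z configuration family.

    Well widths span 100 down to 60 µm and pillar bases 12 down to 8 µm; the
    three size codes attested on the fabricated devices are 100/80/12,
    80/60/10 and 60/40/8, each produced with 0–4 protuberances per cavity.
    """
    sizes = [(100.0, 80.0, 12.0), (80.0, 60.0, 10.0), (60.0, 40.0, 8.0)]
    return [
        StructureConfig(x, y, z, n_protuberances=n_protuberances)
        for x, y, z in sizes
    ]


def _in_hexagon(x: np.ndarray, y: np.ndarray, flat_to_flat: float) -> np.ndarray:
    # regular hexagon, flats normal to +-y (well width = flat_to_flat along y)
    r = flat_to_flat / 2.0
    s3 = np.sqrt(3.0)
    return (
        (np.abs(y) <= r)
        & (np.abs(s3 * x + y) <= 2 * r)
        & (np.abs(s3 * x - y) <= 2 * r)
    )


def build_structure(config: StructureConfig, spacing_um: float,
                    margin_um: float, substrate_um: float = 6.0,
                    lateral_border_um: float | None = None) -> LabeledGrid:
    """Voxelize one cavity structure.

    Bottom to top: insulating substrate slab; stimulating electrode disc
    (one voxel thick, diameter Y) on the well floor; ``n_protuberances``
    mushroom pillars tagged as stimulating electrode; substrate walls up to
    the rim; conductor ground plane of the configured thickness at the rim,
    perforated by the well opening; liquid everywhere else up to
    ``margin_um`` above the ground plane.

    ``spacing_um`` must resolve a pillar stem with at least 3 voxels and
    ``margin_um`` must be at least one well length (a liquid bath above the
    implant).  Voxels are labeled by their center point.
    """
    if spacing_um > config.pillar_base_diameter_um / 3.0:
        raise ResolutionError(
            f"spacing {spacing_um} µm too coarse: need <= Z/3 = "
            f"{config.pillar_base_diameter_um / 3.0:.3g} µm"
        )
    if margin_um < config.well_length_um:
        raise ValueError("margin_um must be >= well_length_um (liquid bath above implant)")
    if config.pillar_height_um >= config.well_depth_um:
        raise GeometryError("pillars must stay inside the well (height < depth)")

    centers = protuberance_layout(
        config.n_protuberances, config.electrode_diameter_um
    )
    cap_r = config.cap_diameter_um / 2.0
    elec_r = config.electrode_diameter_um / 2.0
    for cx, cy in centers:
        if np.hypot(cx, cy) + cap_r > elec_r + 1e-9:
            raise GeometryError("protuberance layout exceeds the electrode disc")

    h = spacing_um
    half_w = config.well_length_um / 2.0 + (
        lateral_border_um
        if lateral_border_um is not None
        else config.inter_cavity_separation_um
    )
    nxy = int(np.ceil(2 * half_w / h))
    z_top = config.well_depth_um + config.ground_grid_thickness_um + margin_um
    nz = int(np.ceil((substrate_um + z_top) / h))
    # origin so that the well axis is at (0, 0) and z=0 at the well floor
    ox = oy = -nxy * h / 2.0
    oz = -substrate_um
    origin = (ox, oy, oz)

    xc = ox + (np.arange(nxy) + 0.5) * h
    zc = oz + (np.arange(nz) + 0.5) * h
    X, Y = np.meshgrid(xc, xc, indexing="ij")
    if config.cavity_cross_section == "hexagon":
        in_well = _in_hexagon(X, Y, config.well_length_um)
    else:
        in_well = np.hypot(X, Y) <= config.well_length_um / 2.0
    R = np.hypot(X, Y)

    labels = np.full((nxy, nxy, nz), LIQUID, dtype=np.uint8)
    electrode_ids = np.zeros_like(labels)

    t_elec = h  # electrode disc: one voxel layer just below the floor level
    z_ground_lo = config.well_depth_um
    z_ground_hi = z_ground_lo + config.ground_grid_thickness_um
    stem_h = max(config.pillar_height_um - 2.0, config.pillar_height_um / 2.0)

    for k, z in enumerate(zc):
        if z < -t_elec:  # substrate slab below the electrode layer
            labels[:, :, k] = INSULATOR
        elif z < 0:  # electrode layer: metal disc, substrate elsewhere
            disc = R <= elec_r
            labels[:, :, k] = np.where(disc, CONDUCTOR, INSULATOR)
            electrode_ids[:, :, k] = np.where(disc, STIM, NO_ELECTRODE)
        elif z < z_ground_lo:  # inside the well depth: walls + pillars
            labels[~in_well, k] = INSULATOR
            for cx, cy in centers:
                rr = np.hypot(X - cx, Y - cy)
                if z < stem_h:
                    pill = rr <= config.pillar_base_diameter_um / 2.0
                elif z < config.pillar_height_um:
                    pill = rr <= cap_r
                else:
                    continue
                labels[pill, k] = CONDUCTOR
                electrode_ids[pill, k] = STIM
        elif z < z_ground_hi:  # ground plane, perforated by the well opening
            labels[~in_well, k] = CONDUCTOR
            electrode_ids[~in_well, k] = GROUND
        # else: liquid bath

    grid = LabeledGrid(
        spacing_um=h,
        labels=labels,
        electrode_ids=electrode_ids,
        origin=origin,
        meta={
            "config": dataclasses.asdict(config),
            "code": config.code,
            "floor_z_um": 0.0,
            "well_depth_um": config.well_depth_um,
            "ground_top_um": z_ground_hi,
            "ground_bottom_um": z_ground_lo,
            "pillar_top_um": config.pillar_height_um if centers else 0.0,
            "pillar_centers_um": centers,
            "margin_um": margin_um,
        },
    )
    grid.validate()
    return grid


# ---------------------------------------------------------------------------
# config file + VTK I/O

_CONFIG_FIELDS = [f.name for f in dataclasses.fields(StructureConfig)]


def load_structure_config(path) -> StructureConfig:
    """Read a StructureConfig from a flat key/value YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_CONFIG_FIELDS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return StructureConfig(**raw)


def save_structure_config(config: StructureConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def write_vtk_structured_points(path, grid: LabeledGrid,
                                fields: dict[str, np.ndarray] | None = None) -> None:
    """Write the grid (and optional per-voxel scalar fields) as legacy ASCII VTK.

    STRUCTURED_POINTS with CELL_DATA; always includes the material labels and
    electrode tags.  Suitable for ParaView/VisIt inspection.
    """
    nx, ny, nz = grid.dims
    h = grid.spacing_um
    data = {"material": grid.labels, "electrode": grid.electrode_ids}
    if fields:
        data.update(fields)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("protustim labeled grid\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        fh.write(f"ORIGIN {grid.origin[0]} {grid.origin[1]} {grid.origin[2]}\n")
        fh.write(f"SPACING {h} {h} {h}\n")
        fh.write(f"CELL_DATA {nx * ny * nz}\n")
        for name, arr in data.items():
            arr = np.asarray(arr)
            if arr.shape != grid.dims:
                raise ValueError(f"field {name!r} shape {arr.shape} != grid dims")
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            flat = arr.astype(float).transpose(2, 1, 0).ravel()
            np.savetxt(fh, flat.reshape(-1, 1), fmt="%.7g")
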