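"""Parametric chamber + microscaffold-array geometry and its voxelization.

The culture chamber is a shallow rectangular cavity (default 6 x 3 x 0.5 mm)
perfused along +x, with a 2 x 8 array of porous photopolymerized
microscaffolds (500 x 500 x 40 um, pores 50 x 50 x 20 um framed by
elliptical-cross-section beams) sitting on the floor at mid-width.
Longitudinal symmetry about y = 0 lets the solvers work on half the chamber.

Coordinates: x = flow direction (inlet face at x = 0), y = lateral with the
symmetry plane at y = 0, z = height with the chamber floor at z = 0.
All lengths SI (meters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._mac import MacGrid

__all__ = [
    "ChamberSpec", "MicrostructureSpec", "ScaffoldArraySpec", "GridSpec",
    "LabeledGrid", "ProbeSet", "UnitCellGrid",
    "FLUID", "POROUS_ARRAY", "FLAT_STRIP_FLOOR", "WALL",
    "build_chamber_grid", "compute_lattice_metrics", "build_probe_set",
    "build_unit_cell_geometry",
]

# voxel region labels
FLUID = 0
POROUS_ARRAY = 1
FLAT_STRIP_FLOOR = 2     # bottom-layer fluid voxels carrying the flat-culture surface sink
WALL = 3

REGION_NAMES = {FLUID: "FLUID", POROUS_ARRAY: "POROUS_ARRAY",
                FLAT_STRIP_FLOOR: "FLAT_STRIP_FLOOR", WALL: "WALL"}


class ConfigurationError(ValueError):
    """A geometric configuration that cannot be realised."""


@dataclass(frozen=True)
class ChamberSpec:
    """Culture-chamber envelope and inlet/outlet ports."""

    length_x: float = 6e-3
    width_y: float = 3e-3
    height_z: float = 0.5e-3
    inlet_diameter: float = 0.76e-3
    inlet_height: float = 3e-3
    half_model: bool = True

    def __post_init__(self):
        for name in ("length_x", "width_y", "height_z", "inlet_diameter",
                     "inlet_height"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    @property
    def inlet_area(self) -> float:
        """Cross-section of one inlet port, m^2."""
        return np.pi * (self.inlet_diameter / 2.0) ** 2

    @property
    def sim_width(self) -> float:
        """Width of the simulated domain (half width if half_model)."""
        return self.width_y / 2.0 if self.half_model else self.width_y


@dataclass(frozen=True)
class MicrostructureSpec:
    """One porous microscaffold: a lattice of box pores framed by beams."""

    footprint_x: float = 500e-6
    footprint_y: float = 500e-6
    height: float = 40e-6
    pore_x: float = 50e-6
    pore_y: float = 50e-6
    pore_z: float = 20e-6
    beam_axial: float = 4.9e-6     # vertical semi-axis x2 of the beam ellipse
    beam_lateral: float = 1.0e-6   # horizontal

    def __post_init__(self):
        for name in ("footprint_x", "footprint_y", "height", "pore_x",
                     "pore_y", "pore_z"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for num, den, what in ((self.footprint_x, self.pore_x, "footprint_x/pore_x"),
                               (self.footprint_y, self.pore_y, "footprint_y/pore_y"),
                               (self.height, self.pore_z, "height/pore_z")):
            r = num / den
            if abs(r - round(r)) > 1e-9:
                raise ConfigurationError(
                    f"pores must tile the microstructure exactly; {what} = {r}")

    @property
    def pores_per_row(self) -> int:
        return round(self.footprint_x / self.pore_x)

    @property
    def n_layers(self) -> int:
        return round(self.height / self.pore_z)


@dataclass(frozen=True)
class ScaffoldArraySpec:
    """Placement of microscaffolds in the chamber: rows straddling y = 0,
    columns equally spaced along x."""

    n_rows: int = 2
    n_cols: int = 8
    pitch_x: float | None = None       # default: chamber length / n_cols
    lateral_offset: float = 250e-6     # row-centre distance from y = 0
    microstructure: MicrostructureSpec = field(default_factory=MicrostructureSpec)

    def resolved_pitch(self, chamber: ChamberSpec) -> float:
        if self.pitch_x is not None:
            return self.pitch_x
        return chamber.length_x / max(self.n_cols, 1)

    def footprints(self, chamber: ChamberSpec) -> list[tuple[int, int, float, float, float, float]]:
        """(row, col, x0, x1, y0, y1) boxes; row 0 is the +y row.

        In a half model only the +y row is returned.
        """
        ms = self.microstructure
        pitch = self.resolved_pitch(chamber)
        boxes = []
        x_center0 = chamber.length_x / 2.0 - (self.n_cols - 1) * pitch / 2.0
        rows_y = []
        if self.n_rows >= 1:
            rows_y.append(self.lateral_offset)
        if self.n_rows >= 2:
            rows_y.append(-self.lateral_offset)
        for extra in range(2, self.n_rows):
            # additional rows stack outward in +y (unused by the reference design)
            rows_y.append(self.lateral_offset + (extra - 1) * ms.footprint_y)
        for r, ycen in enumerate(rows_y):
            if chamber.half_model and ycen < 0:
                continue
            for c in range(self.n_cols):
                xc = x_center0 + c * pitch
                boxes.append((r, c,
                              xc - ms.footprint_x / 2, xc + ms.footprint_x / 2,
                              ycen - ms.footprint_y / 2, ycen + ms.footprint_y / 2))
        return boxes

    def validate_against(self, chamber: ChamberSpec) -> None:
        for (_, _, x0, x1, y0, y1) in self.footprints(chamber):
            if x0 < -1e-12 or x1 > chamber.length_x + 1e-12:
                raise ConfigurationError(
                    "scaffold array exceeds the chamber footprint along x")
            if abs(y0) > chamber.width_y / 2 + 1e-12 or abs(y1) > chamber.width_y / 2 + 1e-12:
                raise ConfigurationError(
                    "scaffold array exceeds the chamber footprint along y")
        if self.microstructure.height > chamber.height_z:
            raise ConfigurationError("microstructures taller than the chamber")


@dataclass(frozen=True)
class GridSpec:
    """Chamber-grid resolution control.

    z spacing is graded: cells of ``dz_fine`` up to ``z_fine_limit`` (shear
    and all probes live in the bottom 50 um), geometric coarsening above.
    """

    dx: float = 50e-6
    dy: float = 50e-6
    dz_fine: float = 5e-6
    z_fine_limit: float = 50e-6
    growth: float = 1.2

    def __post_init__(self):
        if min(self.dx, self.dy, self.dz_fine) <= 0 or self.growth <= 1:
            raise ConfigurationError("grid spacings must be > 0, growth > 1")


@dataclass
class LabeledGrid:
    """Structured voxel grid with per-voxel region labels."""

    grid: MacGrid
    labels: np.ndarray                      # (nx, ny, nz) uint8
    chamber: ChamberSpec
    array: ScaffoldArraySpec
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.grid.shape

    def region_volume(self, *regions: int) -> float:
        mask = np.isin(self.labels, regions)
        return float(self.grid.cell_volumes()[mask].sum())

    def strip_area(self) -> float:
        """Floor area of the flat-culture strip, m^2."""
        mask2d = self.labels[:, :, 0] == FLAT_STRIP_FLOOR
        A = self.grid.dx[:, None] * self.grid.dy[None, :]
        return float(A[mask2d].sum())

    def array_mask(self) -> np.ndarray:
        return self.labels == POROUS_ARRAY

    def hydrodynamic_solid(self) -> np.ndarray:
        return self.labels == WALL


def _insert_edges(faces: np.ndarray, edges, min_gap: float) -> np.ndarray:
    """Insert geometric edge coordinates into a face array, snapping faces
    that fall within ``min_gap`` of an edge onto it (keeps cells well-sized)."""
    faces = np.asarray(faces, dtype=float).copy()
    lo, hi = faces[0], faces[-1]
    for e in edges:
        if e <= lo + 1e-15 or e >= hi - 1e-15:
            continue
        i = int(np.argmin(np.abs(faces - e)))
        if abs(faces[i] - e) <= min_gap and i not in (0, faces.size - 1):
            faces[i] = e
        elif np.min(np.abs(faces - e)) > 1e-15:
            faces = np.sort(np.append(faces, e))
    return faces


def _graded_z(height: float, gs: GridSpec) -> np.ndarray:
    n_fine = int(round(min(gs.z_fine_limit, height) / gs.dz_fine))
    zf = [i * gs.dz_fine for i in range(n_fine + 1)]
    rest = height - zf[-1]
    if rest > 1e-12:
        widths = []
        wcur = gs.dz_fine * gs.growth
        acc = 0.0
        while acc < rest:
            widths.append(wcur)
            acc += wcur
            wcur *= gs.growth
        widths = np.array(widths) * (rest / acc)   # stretch to fit exactly
        zf.extend(zf[-1] + np.cumsum(widths))
    zf = np.asarray(zf, dtype=float)
    zf[-1] = height
    return zf


def build_chamber_grid(chamber: ChamberSpec, array: ScaffoldArraySpec,
                       resolution: GridSpec | None = None,
                       strip_mode: str = "beside_array") -> LabeledGrid:
    """Discretise the chamber into a labeled rectilinear voxel grid.

    ``strip_mode`` controls where the flat-culture floor strip sits:
    ``beside_array`` (floor lateral to the array, spanning the array's x
    extent — the default) or ``all_flat`` (every floor voxel outside the
    scaffold footprints).
    """
    resolution = resolution or GridSpec()
    ms = array.microstructure
    if array.n_cols > 0:
        array.validate_against(chamber)
        if resolution.dz_fine > ms.height / 4:
            raise ConfigurationError(
                "resolution too coarse: need >= 4 cells across the "
                f"{ms.height*1e6:.0f} um scaffold height (dz_fine <= "
                f"{ms.height/4*1e6:.2f} um)")
        if resolution.dx > ms.footprint_x / 2 or resolution.dy > ms.footprint_y / 2:
            raise ConfigurationError(
                "resolution too coarse: need >= 2 cells across each "
                "scaffold footprint")

    L = chamber.length_x
    W = chamber.sim_width
    H = chamber.height_z
    nx = max(int(round(L / resolution.dx)), 2)
    xf = np.linspace(0.0, L, nx + 1)
    boxes_pre = array.footprints(chamber)
    # snap grid lines onto footprint edges so the porous block is conforming
    xedges = sorted({round(b[i], 12) for b in boxes_pre for i in (2, 3)})
    xf = _insert_edges(xf, xedges, resolution.dx / 4)
    yedges = sorted({round(abs(b[i]), 12) * s
                     for b in boxes_pre for i in (4, 5)
                     for s in ((1,) if chamber.half_model else (1, -1))
                     if not (chamber.half_model and b[i] < 0)})
    if chamber.half_model:
        nyh = max(int(round(W / resolution.dy)), 2)
        yf = np.linspace(0.0, W, nyh + 1)
    else:
        nyh = max(int(round((W / 2) / resolution.dy)), 1)
        half = np.linspace(0.0, W / 2, nyh + 1)
        yf = np.concatenate([-half[::-1], half[1:]])   # mirror-symmetric faces
    yf = _insert_edges(yf, yedges, resolution.dy / 4)
    zf = _graded_z(H, resolution)
    zedges = [ms.height] if array.n_cols > 0 else []
    zf = _insert_edges(zf, zedges, resolution.dz_fine / 4)
    grid = MacGrid(xf, yf, zf)

    labels = np.full(grid.shape, FLUID, dtype=np.uint8)
    xc, yc, zc = grid.xc, grid.yc, grid.zc
    boxes = array.footprints(chamber)
    in_array_xy = np.zeros((xc.size, yc.size), dtype=bool)
    for (_, _, x0, x1, y0, y1) in boxes:
        mx = (xc > x0) & (xc < x1)
        my = (yc > y0) & (yc < y1)
        in_array_xy |= mx[:, None] & my[None, :]
    mz = zc < ms.height
    labels[in_array_xy[:, :, None] & mz[None, None, :]] = POROUS_ARRAY

    # flat-culture strip on the floor
    if strip_mode == "all_flat":
        strip2d = ~in_array_xy
    elif strip_mode == "beside_array":
        if boxes:
            ax0 = min(b[2] for b in boxes)
            ax1 = max(b[3] for b in boxes)
            ay1 = max(max(abs(b[4]), abs(b[5])) for b in boxes)
            sx = (xc > ax0) & (xc < ax1)
            sy = np.abs(yc) > ay1
            strip2d = sx[:, None] & sy[None, :]
        else:
            strip2d = np.zeros((xc.size, yc.size), dtype=bool)
    else:
        raise ConfigurationError(f"unknown strip_mode {strip_mode!r}")
    floor = labels[:, :, 0]
    sel = strip2d & (floor == FLUID)
    floor[sel] = FLAT_STRIP_FLOOR
    labels[:, :, 0] = floor

    meta = {"strip_mode": strip_mode, "n_footprints": len(boxes),
            "half_model": chamber.half_model}
    lg = LabeledGrid(grid=grid, labels=labels, chamber=chamber, array=array,
                     meta=meta)

    vol = lg.region_volume(FLUID, POROUS_ARRAY, FLAT_STRIP_FLOOR)
    target = L * W * H
    if abs(vol - target) > 5e-3 * target:
        raise ConfigurationError("grid volume does not close the chamber volume")
    return lg


# ---------------------------------------------------------------------------
# lattice metrics & permeability inputs
# ---------------------------------------------------------------------------

def _ellipse_area(a_full: float, b_full: float) -> float:
    return np.pi * (a_full / 2.0) * (b_full / 2.0)


def _ellipse_perimeter(a_full: float, b_full: float) -> float:
    a, b = a_full / 2.0, b_full / 2.0
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))


def compute_lattice_metrics(ms: MicrostructureSpec) -> dict:
    """Solid fraction, porosity and specific surface of the beam lattice.

    The lattice is modeled as elliptical-cross-section beams (vertical axis
    ``beam_axial``, horizontal ``beam_lateral``) along every edge of the
    rectangular pore tiling; junction overlap is neglected (beams are
    slender: overlap is O(beam^2/pore^2) of the solid volume).
    """
    if ms.beam_lateral < 0 or ms.beam_axial < 0:
        raise ConfigurationError("beam dimensions must be >= 0")
    if ms.beam_lateral >= min(ms.pore_x, ms.pore_y) or \
            ms.beam_axial >= 2 * ms.pore_z:
        raise ConfigurationError("beams thicker than pores")
    V = ms.pore_x * ms.pore_y * ms.pore_z
    # each pore cell owns one edge-length per axis (edges shared by 4 cells)
    L_tot = ms.pore_x + ms.pore_y + ms.pore_z
    A = _ellipse_area(ms.beam_axial, ms.beam_lateral)
    sf = A * L_tot / V
    if sf >= 1:
        raise ConfigurationError("beam lattice denser than its bounding volume")
    P = _ellipse_perimeter(ms.beam_axial, ms.beam_lateral) if A > 0 else 0.0
    return {
        "solid_fraction": float(sf),
        "porosity": float(1.0 - sf),
        "specific_surface": float(P * L_tot / V),
        "fiber_radius": float(np.sqrt(ms.beam_axial * ms.beam_lateral) / 2.0),
    }


# ---------------------------------------------------------------------------
# probes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Probe:
    microstructure: int     # 1-based, counted from the inlet
    pore: int               # 1-based along +x within the microstructure
    height_um: float
    x: float
    y: float
    z: float


@dataclass
class ProbeSet:
    """Velocity probes at pore centres and shear probes on the outlet-side
    pore face, both at 10/20/40 um height."""

    velocity: list[Probe]
    shear: list[Probe]       # x,y,z = centre of the outlet-side pore face
    microstructures: tuple = (1, 4, 8)
    pores: tuple = (1, 5, 10)
    heights_um: tuple = (10.0, 20.0, 40.0)


def build_probe_set(chamber: ChamberSpec, array: ScaffoldArraySpec,
                    microstructures=(1, 4, 8), pores=(1, 5, 10),
                    heights_um=(10.0, 20.0, 40.0)) -> ProbeSet:
    """Probe points: pore centres of the first/fifth/tenth pore in the
    first/fourth/eighth microstructure (counted from the inlet), in the +y
    row, at 10/20/40 um from the floor."""
    ms = array.microstructure
    if array.n_cols < max(microstructures):
        raise ConfigurationError(
            f"probe microstructure index {max(microstructures)} outside the "
            f"{array.n_cols}-column array")
    if ms.pores_per_row < max(pores):
        raise ConfigurationError(
            f"probe pore index {max(pores)} outside the "
            f"{ms.pores_per_row}-pore microstructure")
    boxes = {(t[0], t[1]): t[2:] for t in array.footprints(chamber)}
    # use the +y row (row index 0)
    vel, shear = [], []
    for m in microstructures:
        x0, x1, y0, y1 = boxes[(0, m - 1)]
        ycen = 0.5 * (y0 + y1)
        for pp in pores:
            xc = x0 + (pp - 0.5) * ms.pore_x
            xface = x0 + pp * ms.pore_x       # outlet-side pore face
            for h in heights_um:
                z = h * 1e-6
                if z > chamber.height_z:
                    raise ConfigurationError("probe above the chamber")
                vel.append(Probe(m, pp, h, xc, ycen, z))
                shear.append(Probe(m, pp, h, xface, ycen, z))
    return ProbeSet(velocity=vel, shear=shear,
                    microstructures=tuple(microstructures),
                    pores=tuple(pores), heights_um=tuple(heights_um))


# ---------------------------------------------------------------------------
# resolved pore-scale unit cell
# ---------------------------------------------------------------------------

@dataclass
class UnitCellGrid:
    """One pore column with resolved (voxelized) beams and free fluid above."""

    grid: MacGrid
    solid: np.ndarray
    ms: MicrostructureSpec
    clearance: float
    lateral: str
    meta: dict = field(default_factory=dict)

    @property
    def beam_layer_z(self) -> list[float]:
        return [i * self.ms.pore_z for i in range(self.ms.n_layers + 1)]


def build_unit_cell_geometry(ms: MicrostructureSpec, spacing: float = 2.5e-6,
                             clearance: float = 40e-6,
                             lateral: str = "periodic",
                             top: str = "symmetry",
                             growth: float = 1.2) -> UnitCellGrid:
    """Voxelize one pore column (pore_x x pore_y x height + clearance above).

    Horizontal beams run along the pore edges at every layer plane
    (z = 0, pore_z, ..., height) and vertical posts along the pore corners.
    Beams keep their full vertical (``beam_axial``) extent — the voxel
    layers within ``beam_axial/2`` of each plane are solid — while the 1 um
    lateral dimension, thinner than one voxel at the default 2.5 um spacing,
    is inflated to a single voxel (with a warning and a metadata record).

    ``top`` selects the upper closure: ``symmetry`` (free slip at
    height+clearance) or ``wall`` (the chamber ceiling, for full-column
    cells); z spacing stays at ``spacing`` through the cage and coarsens
    geometrically above it.
    """
    if lateral not in ("periodic", "symmetry"):
        raise ConfigurationError("lateral faces must be 'periodic' or 'symmetry'")
    if top not in ("symmetry", "wall"):
        raise ConfigurationError("top closure must be 'symmetry' or 'wall'")
    if spacing > min(ms.pore_x, ms.pore_y, ms.pore_z) / 4:
        raise ConfigurationError("unit-cell spacing too coarse for the pore")
    inflated = False
    if spacing > ms.beam_lateral and ms.beam_lateral > 0:
        warnings.warn(
            f"unit-cell spacing {spacing*1e6:.2f} um cannot resolve the "
            f"{ms.beam_lateral*1e6:.2f} um beams; beams inflated to one voxel",
            RuntimeWarning, stacklevel=2)
        inflated = True

    H = ms.height + clearance
    nx = max(round(ms.pore_x / spacing), 4)
    ny = max(round(ms.pore_y / spacing), 4)
    z_fine_top = min(ms.height + 2 * spacing + ms.beam_axial, H)
    nzf = int(np.ceil(z_fine_top / spacing))
    zf = [i * spacing for i in range(nzf + 1)]
    rest = H - zf[-1]
    if rest > spacing * 1e-9:
        widths = []
        wcur = spacing * growth
        acc = 0.0
        while acc < rest:
            widths.append(wcur)
            acc += wcur
            wcur *= growth
        widths = np.asarray(widths) * (rest / acc)
        zf.extend(zf[-1] + np.cumsum(widths))
    zf = np.asarray(zf, dtype=float)
    zf[-1] = H
    g = MacGrid(np.linspace(0, ms.pore_x, nx + 1),
                np.linspace(0, ms.pore_y, ny + 1), zf)
    solid = np.zeros(g.shape, dtype=bool)
    layer_voxels: dict[float, list[int]] = {}
    if ms.beam_lateral > 0 and ms.beam_axial > 0:
        zc = g.zc
        layers = [i * ms.pore_z for i in range(ms.n_layers + 1)]
        half_ax = ms.beam_axial / 2.0
        for zl in layers:
            ks = np.where(np.abs(zc - zl) < half_ax)[0]
            if ks.size == 0:      # thin beams on a coarse grid: one voxel
                if zl == 0:
                    ks = np.array([0])
                else:
                    ks = np.array([int(np.searchsorted(g.zf, zl - 1e-12)) - 1])
            layer_voxels[zl] = [int(k) for k in ks]
            for k in ks:
                solid[:, 0, k] = True          # beam along x at the y = 0 edge
                solid[0, :, k] = True          # beam along y at the x = 0 edge
                if lateral == "symmetry":
                    solid[:, ny - 1, k] = True
        # vertical posts along the pore corners, z <= scaffold height
        kz = zc < ms.height
        solid[0, 0, kz] = True
        if lateral == "symmetry":
            solid[0, ny - 1, kz] = True
    meta = {"spacing": spacing, "inflated_beams": inflated,
            "solid_voxels": int(solid.sum()), "layer_voxels": layer_voxels,
            "top": top}
    return UnitCellGrid(grid=g, solid=solid, ms=ms, clearance=clearance,
                        lateral=lateral, meta=meta)
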