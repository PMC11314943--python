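"""Bed-frame coordinate system, radar specifications and grid geometry.

The bed frame has its origin at the headboard-left corner of the mattress:
x runs across the 90 cm width, y runs along the 196 cm length from headboard
to foot.  All geometry is in centimetres except radar range quantities
(``bin_length``, ``max_range``), which follow hardware convention in metres.

Eight canonical radar slots surround the bed: three at the headboard
(HL, HC, HR, left/centre/right, boresight looking down the bed in +y) and
five along one long side (S1..S5, cranial to caudal, boresight looking
across the bed in +x).  Each radar reports a 1D fast-time range profile;
its useful field of view is a sector of +/-65 degrees about boresight.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "CANONICAL_RADAR_ORDER",
    "RadarSpec",
    "GridSpec",
    "cell_center",
    "distance_map",
    "azimuth_mask",
    "default_placement",
    "save_geometry",
    "load_geometry",
]

#: Canonical ordering of the eight radar slots; view stacks and ensemble
#: masks index radars in this order.
CANONICAL_RADAR_ORDER = ("HL", "HC", "HR", "S1", "S2", "S3", "S4", "S5")

# Hardware defaults: 9.87 m frame, 1536 bins -> 0.643 cm bin spacing.
_DEFAULT_MAX_RANGE_M = 9.87
_DEFAULT_N_BINS = 1536


@dataclass(frozen=True)
class RadarSpec:
    """One radar's pose and acquisition parameters.

    Parameters
    ----------
    radar_id : str
        Slot name; canonical slots are HL, HC, HR, S1..S5 but custom ids
        are allowed.
    position : tuple of float
        (x, y) in cm in the bed frame, optionally (x, y, z) for 3D mode.
    boresight : tuple of float
        Pointing direction in the bed plane; need not be normalised.
    azimuth_half_angle : float
        Half-width of the usable sector in degrees (default 65).
    bin_length : float
        Range extent of one fast-time bin, metres.
    n_bins : int
        Fast-time bins per frame.
    max_range : float
        Total unambiguous range, metres; must equal bin_length * n_bins
        within 1%.
    frame_rate : float
        Slow-time frame rate, Hz.
    """

    radar_id: str
    position: tuple
    boresight: tuple
    azimuth_half_angle: float = 65.0
    bin_length: float = _DEFAULT_MAX_RANGE_M / _DEFAULT_N_BINS
    n_bins: int = _DEFAULT_N_BINS
    max_range: float = _DEFAULT_MAX_RANGE_M
    frame_rate: float = 20.0

    def __post_init__(self):
        if not (0.0 < self.azimuth_half_angle <= 90.0):
            raise ValueError("azimuth_half_angle must lie in (0, 90] degrees")
        if self.bin_length <= 0:
            raise ValueError("bin_length must be positive")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if abs(self.bin_length * self.n_bins - self.max_range) > 0.01 * self.max_range:
            raise ValueError(
                f"bin_length * n_bins = {self.bin_length * self.n_bins:.4f} m "
                f"inconsistent with max_range = {self.max_range:.4f} m (>1% off)"
            )
        bx, by = self.boresight[0], self.boresight[1]
        if bx == 0.0 and by == 0.0:
            raise ValueError("boresight must be a nonzero vector")

    @property
    def xy(self) -> np.ndarray:
        """Planar position, cm."""
        return np.asarray(self.position[:2], dtype=float)

    @property
    def z(self) -> float:
        """Height above the bed plane, cm (0 if planar)."""
        return float(self.position[2]) if len(self.position) > 2 else 0.0

    @property
    def bin_length_cm(self) -> float:
        return self.bin_length * 100.0


@dataclass(frozen=True)
class GridSpec:
    """Regular bed-aligned grid on which echo maps are evaluated.

    Defaults cover the 90 x 196 cm mattress at one range-bin (0.643 cm)
    per cell, giving a 139 x 304 grid.
    """

    origin: tuple = (0.0, 0.0)
    extent: tuple = (90.0, 196.0)
    cell_size: float = 0.643

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_x(self) -> int:
        return int((self.extent[0] - self.origin[0]) / self.cell_size)

    @property
    def n_y(self) -> int:
        return int((self.extent[1] - self.origin[1]) / self.cell_size)

    @property
    def shape(self) -> tuple:
        """(n_x, n_y) — across-width, along-length."""
        return (self.n_x, self.n_y)


def cell_center(grid: GridSpec, i: int, j: int):
    """Centre coordinates (x, y) in cm of cell (i, j).

    Cell (i, j) spans ``origin + [i, i+1) x [j, j+1) * cell_size``; the
    centre convention avoids zero-distance artefacts for radars placed at
    the grid origin.
    """
    if not (0 <= i < grid.n_x) or not (0 <= j < grid.n_y):
        raise IndexError(f"cell index ({i}, {j}) outside grid {grid.shape}")
    x = grid.origin[0] + (i + 0.5) * grid.cell_size
    y = grid.origin[1] + (j + 0.5) * grid.cell_size
    return (x, y)


def _cell_center_arrays(grid: GridSpec):
    """Vectorised cell centres: X, Y arrays of shape (n_x, n_y), cm."""
    xs = grid.origin[0] + (np.arange(grid.n_x) + 0.5) * grid.cell_size
    ys = grid.origin[1] + (np.arange(grid.n_y) + 0.5) * grid.cell_size
    return np.meshgrid(xs, ys, indexing="ij")


def distance_map(radar: RadarSpec, grid: GridSpec, mode: str = "planar") -> np.ndarray:
    """Euclidean distance (cm) from every cell centre to the radar.

    ``mode='planar'`` ignores heights (the echo-map algorithm is strictly
    2D); ``mode='3d'`` includes the radar's z offset above the bed plane.
    Returns an (n_x, n_y) array.
    """
    if mode not in ("planar", "3d"):
        raise ValueError(f"unknown distance mode {mode!r}")
    X, Y = _cell_center_arrays(grid)
    rx, ry = radar.xy
    d2 = (X - rx) ** 2 + (Y - ry) ** 2
    if mode == "3d":
        d2 = d2 + radar.z**2
    return np.sqrt(d2)


def azimuth_mask(radar: RadarSpec, grid: GridSpec) -> np.ndarray:
    """Boolean (n_x, n_y) array: True where a cell lies inside the radar's
    azimuth sector.

    A cell is inside when the angle between the boresight and the
    radar-to-cell vector is at most ``azimuth_half_angle``.  A cell whose
    centre coincides with the radar position (zero direction vector) is
    defined inside.
    """
    X, Y = _cell_center_arrays(grid)
    rx, ry = radar.xy
    vx, vy = X - rx, Y - ry
    norm = np.hypot(vx, vy)
    bx, by = radar.boresight[0], radar.boresight[1]
    bnorm = math.hypot(bx, by)
    if bnorm == 0.0:
        raise ValueError("boresight must be a nonzero vector")
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (vx * bx + vy * by) / (norm * bnorm)
    cos_lim = math.cos(math.radians(radar.azimuth_half_angle))
    mask = cosang >= cos_lim - 1e-12
    mask[norm == 0.0] = True
    return mask


def default_placement(
    *,
    edge_offset: float = 20.0,
    side_spacing: float = 15.0,
    side_y0: float = 30.0,
    head_xs: tuple = (20.0, 45.0, 70.0),
    heights: bool = False,
) -> list:
    """The canonical eight-radar arrangement around the bed.

    HL, HC, HR sit 20 cm behind the headboard edge (y = -20), boresight +y;
    S1..S5 sit 20 cm out from the left long edge (x = -20) at 15 cm spacing
    starting at y = 30 cm (upper-body biased), boresight +x.  With
    ``heights=True`` positions gain z: 108 - 60 = 48 cm above the mattress
    for head radars and 78 - 60 = 18 cm for side radars (headboard radars
    are mounted higher to clear the headboard).
    """
    head_z = 108.0 - 60.0
    side_z = 78.0 - 60.0
    radars = []
    for rid, hx in zip(("HL", "HC", "HR"), head_xs):
        pos = (hx, -edge_offset, head_z) if heights else (hx, -edge_offset)
        radars.append(RadarSpec(radar_id=rid, position=pos, boresight=(0.0, 1.0)))
    for k in range(5):
        y = side_y0 + k * side_spacing
        pos = (-edge_offset, y, side_z) if heights else (-edge_offset, y)
        radars.append(RadarSpec(radar_id=f"S{k + 1}", position=pos, boresight=(1.0, 0.0)))
    # canonical order HL HC HR S1..S5
    return radars


# --- JSON config round-trip ------------------------------------------------
# Geometry configs store radar poses in cm and range parameters in metres,
# mirroring the dataclass field names.

def save_geometry(path, radars, grid: GridSpec | None = None) -> None:
    obj = {"radars": [asdict(r) for r in radars]}
    if grid is not None:
        obj["grid"] = asdict(grid)
    Path(path).write_text(json.dumps(obj, indent=2))


def load_geometry(path):
    """Returns (list of RadarSpec, GridSpec or None)."""
    obj = json.loads(Path(path).read_text())
    radars = [
        RadarSpec(**{**d, "position": tuple(d["position"]), "boresight": tuple(d["boresight"])})
        for d in obj["radars"]
    ]
    grid = None
    if "grid" in obj:
        g = obj["grid"]
        grid = GridSpec(origin=tuple(g["origin"]), extent=tuple(g["extent"]), cell_size=g["cell_size"])
    return radars, grid
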