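"""Device geometry, chemoattractant gradient, and synthetic image generation.

The migration chip holds two mirrored arrays of narrow migration channels
(30 µm wide, 1 mm long by default, 450 per side) connecting serum-free side
loading channels to a serum-containing central channel.  Cells seeded at the
loading entrances migrate up the linear chemoattractant gradient toward the
centre; the assay read-out is the per-channel migration frontier.

This module renders ground-truthed, end-point fluorescence micrographs of
such a device: a bright-field plane showing the channel layout, a green
(FITC, live stain) plane and a red (TRITC, dead stain) plane, all 8-bit.
Every rendered cell is recorded with its channel, distance from the loading
entrance, viability, radius and peak intensity, so detection and frontier
measurements can be scored against exact truth.

Coordinates: images are (row, col) arrays with one pixel per
``pixel_size_um`` micrometres (1 µm/px by default, so pixels and µm
coincide).  Left-side channels run in +x (increasing column), right-side
channels in -x; the distance origin of every channel is its loading-side
entrance.  Rendering is 2-D top-view; channel heights (5 µm migration,
40 µm main) are metadata only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "DeviceGeometry",
    "GroundTruthCell",
    "DebrisObject",
    "SyntheticScene",
    "RenderedImage",
    "linear_gradient",
    "sample_scene",
    "render",
    "channel_template_mask",
    "ground_truth_frontiers",
    "write_tiff",
    "write_ground_truth_csv",
]

Side = Literal["left", "right"]

#: pixels each channel ROI extends past the channel exit into the central
#: band, so a cell whose centre sits exactly at the exit is still captured.
ROI_OVERSHOOT_PX = 8


@dataclass(frozen=True)
class DeviceGeometry:
    """Physical layout of the migration chip plus pixel calibration.

    Defaults reproduce the published device: 900 migration channels
    (450 per side), each 30 µm wide and 1 mm long.  ``channel_height_um``
    and ``main_channel_height_um`` are recorded for completeness but play
    no role in 2-D rendering.
    """

    n_channels_per_side: int = 450
    n_sides: int = 2
    channel_width_um: float = 30.0
    channel_length_um: float = 1000.0
    channel_pitch_um: float = 40.0
    main_channel_width_um: float = 200.0
    channel_height_um: float = 5.0
    main_channel_height_um: float = 40.0
    pixel_size_um: float = 1.0
    margin_px: int = 10
    image_shape_px: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for name in (
            "channel_width_um",
            "channel_length_um",
            "channel_pitch_um",
            "main_channel_width_um",
            "pixel_size_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.channel_pitch_um <= self.channel_width_um:
            raise ValueError("channel_pitch_um must exceed channel_width_um")
        if self.n_channels_per_side < 1 or self.n_sides not in (1, 2):
            raise ValueError("need >=1 channel per side and 1 or 2 sides")
        if self.image_shape_px is None:
            object.__setattr__(self, "image_shape_px", self._default_shape())
        rows, cols = self.image_shape_px
        min_rows, min_cols = self._default_shape()
        if rows < min_rows or cols < min_cols:
            raise ValueError(
                f"image_shape_px {self.image_shape_px} cannot hold the "
                f"channel array (needs at least {(min_rows, min_cols)})"
            )

    # -- derived pixel quantities ------------------------------------
    @property
    def total_channels(self) -> int:
        return self.n_channels_per_side * self.n_sides

    @property
    def length_px(self) -> float:
        return self.channel_length_um / self.pixel_size_um

    @property
    def width_px(self) -> float:
        return self.channel_width_um / self.pixel_size_um

    @property
    def pitch_px(self) -> float:
        return self.channel_pitch_um / self.pixel_size_um

    @property
    def central_px(self) -> float:
        return self.main_channel_width_um / self.pixel_size_um

    def _default_shape(self) -> tuple[int, int]:
        rows = int(np.ceil(2 * self.margin_px + self.n_channels_per_side * self.pitch_px))
        ncols = 2 * self.margin_px + self.n_sides * self.length_px
        if self.n_sides == 2:
            ncols += self.central_px
        return rows, int(np.ceil(ncols))

    # -- channel placement -------------------------------------------
    def channel_rows(self, channel_index: int) -> tuple[int, int]:
        """Half-open pixel row span of one channel strip."""
        if not 0 <= channel_index < self.n_channels_per_side:
            raise ValueError("channel_index out of range")
        r0 = int(round(self.margin_px + channel_index * self.pitch_px))
        return r0, int(round(r0 + self.width_px))

    def entrance_col(self, side: Side) -> float:
        """Column coordinate of the loading-side entrance line."""
        if side == "left":
            return float(self.margin_px)
        if self.n_sides != 2:
            raise ValueError("geometry has no right side")
        return float(self.margin_px + 2 * self.length_px + self.central_px)

    def axis_sign(self, side: Side) -> int:
        return 1 if side == "left" else -1

    def cell_col(self, side: Side, distance_um: float) -> float:
        return self.entrance_col(side) + self.axis_sign(side) * (
            distance_um / self.pixel_size_um
        )

    # -- serialization ------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DeviceGeometry":
        raw = json.loads(Path(path).read_text())
        if raw.get("image_shape_px") is not None:
            raw["image_shape_px"] = tuple(raw["image_shape_px"])
        return cls(**raw)


@dataclass(frozen=True)
class GroundTruthCell:
    """One rendered cell with its exact placement and appearance."""

    channel_index: int
    side: Side
    distance_um: float
    viability: Literal["live", "dead"]
    radius_um: float
    peak_intensity: int


@dataclass(frozen=True)
class DebrisObject:
    """Small sub-threshold-footprint object emulating debris/defects."""

    channel_index: int
    side: Side
    distance_um: float
    radius_um: float
    peak_intensity: int


@dataclass(frozen=True)
class SyntheticScene:
    geometry: DeviceGeometry
    cells: tuple[GroundTruthCell, ...]
    debris: tuple[DebrisObject, ...]
    noise_sd: float
    seed: int
    #: number of cells the two-component draw assigned to the migratory
    #: (distance = L) component; None for other distance models.
    n_migratory_assigned: int | None = None

    @property
    def debris_count(self) -> int:
        return len(self.debris)


@dataclass(frozen=True)
class RenderedImage:
    """Three co-registered 8-bit planes of one device micrograph."""

    bright_field: np.ndarray
    live_fluor: np.ndarray
    dead_fluor: np.ndarray

    def __post_init__(self) -> None:
        shapes = {p.shape for p in self.planes.values()}
        if len(shapes) != 1:
            raise ValueError("plane shapes differ")
        for name, plane in self.planes.items():
            if plane.dtype != np.uint8:
                raise ValueError(f"{name} plane must be 8-bit (uint8)")

    @property
    def planes(self) -> dict[str, np.ndarray]:
        return {
            "bright_field": self.bright_field,
            "live_fluor": self.live_fluor,
            "dead_fluor": self.dead_fluor,
        }


def linear_gradient(
    c_central: float, c_side: float, x_um: float, L_um: float
) -> float:
    """Chemoattractant concentration at position ``x_um`` along a channel.

    Steady-state 1-D diffusion between fixed boundary concentrations gives a
    linear profile from the serum-free side channel (``x = 0``) to the
    serum-containing central channel (``x = L``).
    """
    if L_um <= 0:
        raise ValueError("channel length must be positive")
    if not 0 <= x_um <= L_um:
        raise ValueError(f"x={x_um} outside channel [0, {L_um}]")
    return c_side + (c_central - c_side) * (x_um / L_um)


# ---------------------------------------------------------------------------
# scene sampling
# ---------------------------------------------------------------------------

_DISTANCE_MODELS = ("point_mass_at_entrance", "uniform", "exponential", "two_component")

#: clearance kept between supra-threshold footprints so neighbouring objects
#: never 8-connect after thresholding.
MIN_GAP_PX = 3.0
_MAX_TRIES = 500

_DEBRIS_RADIUS_UM = 2.0  # supra-threshold footprint ~15 px < 20-px cell minimum
_CELL_PEAK_RANGE = (150, 256)
_DEBRIS_PEAK_RANGE = (60, 140)


def _draw_distance(
    rng: np.random.Generator, model: str, params: dict, L: float
) -> tuple[float, bool]:
    """Return (distance_um, is_migratory_component)."""
    if model == "point_mass_at_entrance":
        return 0.0, False
    if model == "uniform":
        lo = params.get("low", 0.0)
        hi = params.get("high", L)
        return float(rng.uniform(lo, hi)), False
    if model == "exponential":
        scale = params.get("scale", L / 4)
        for _ in range(100):
            d = rng.exponential(scale)
            if d <= L:
                return float(d), False
        return float(L), False
    if model == "two_component":
        frac = params.get("migratory_fraction", 0.1)
        if rng.random() < frac:
            return float(L), True
        lo = params.get("low", 0.0)
        hi = params.get("high", L)
        return float(rng.uniform(lo, hi)), False
    raise ValueError(f"unknown distance model {model!r}; choose from {_DISTANCE_MODELS}")


def sample_scene(
    geometry: DeviceGeometry,
    n_cells: int,
    distance_dist: str = "uniform",
    dist_params: dict | None = None,
    dead_fraction: float = 0.0,
    debris_count: int = 0,
    noise_sd: float = 0.0,
    seed: int = 0,
    snap_to_grid: bool = False,
) -> SyntheticScene:
    """Draw a ground-truthed random cell placement on the chip.

    Cells are assigned to uniformly random channels; their distance from the
    loading entrance follows ``distance_dist`` (one of
    ``point_mass_at_entrance``, ``uniform``, ``exponential``,
    ``two_component``).  Placement is rejection-sampled so footprints within
    a channel keep a ``MIN_GAP_PX`` clearance; infeasible packings raise
    after a bounded number of retries.  Identical parameters and seed
    reproduce the identical scene.

    With ``snap_to_grid`` cell centres are rounded to whole pixels, which
    makes the rendered spots grid-symmetric so centroid detection is exact;
    use it for zero-error oracle comparisons.  Default placements are
    continuous (sub-pixel), as on a real microscope.
    """
    if not 0 <= dead_fraction <= 1:
        raise ValueError("dead_fraction must be in [0, 1]")
    if n_cells < 0 or debris_count < 0:
        raise ValueError("counts must be non-negative")
    params = dict(dist_params or {})
    rng = np.random.default_rng(seed)
    L = geometry.channel_length_um

    def snap(d: float) -> float:
        if not snap_to_grid:
            return d
        px = geometry.pixel_size_um
        return float(min(round(d / px) * px, L))
    sides: tuple[Side, ...] = ("left", "right")[: geometry.n_sides]

    # occupied intervals per (side, channel): list of (centre_um, radius_um)
    occupied: dict[tuple[str, int], list[tuple[float, float]]] = {}

    def fits(key: tuple[str, int], centre: float, radius: float) -> bool:
        gap_um = MIN_GAP_PX * geometry.pixel_size_um
        return all(
            abs(centre - c) >= radius + r + gap_um for c, r in occupied.get(key, [])
        )

    cells: list[GroundTruthCell] = []
    n_migratory = 0
    track_migratory = distance_dist == "two_component"
    for _ in range(n_cells):
        radius = float(rng.uniform(5.0, 7.5))
        peak = int(rng.integers(*_CELL_PEAK_RANGE))
        dead = bool(rng.random() < dead_fraction)
        dist, migratory = _draw_distance(rng, distance_dist, params, L)
        dist = snap(dist)
        placed = False
        for attempt in range(_MAX_TRIES):
            if attempt > 0 and not migratory:
                # redraw position but keep the recorded component assignment
                while True:
                    dist, redraw_migratory = _draw_distance(
                        rng, distance_dist, params, L
                    )
                    if not redraw_migratory:
                        break
                dist = snap(dist)
            side = sides[int(rng.integers(len(sides)))]
            channel = int(rng.integers(geometry.n_channels_per_side))
            if fits((side, channel), dist, radius):
                occupied.setdefault((side, channel), []).append((dist, radius))
                cells.append(
                    GroundTruthCell(
                        channel_index=channel,
                        side=side,
                        distance_um=dist,
                        viability="dead" if dead else "live",
                        radius_um=radius,
                        peak_intensity=peak,
                    )
                )
                if migratory:
                    n_migratory += 1
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell after {_MAX_TRIES} tries: "
                "packing infeasible for the requested density"
            )

    debris: list[DebrisObject] = []
    for _ in range(debris_count):
        peak = int(rng.integers(*_DEBRIS_PEAK_RANGE))
        placed = False
        for _ in range(_MAX_TRIES):
            dist = float(rng.uniform(0, L))
            side = sides[int(rng.integers(len(sides)))]
            channel = int(rng.integers(geometry.n_channels_per_side))
            if fits((side, channel), dist, _DEBRIS_RADIUS_UM):
                occupied.setdefault((side, channel), []).append(
                    (dist, _DEBRIS_RADIUS_UM)
                )
                debris.append(
                    DebrisObject(channel, side, dist, _DEBRIS_RADIUS_UM, peak)
                )
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place debris: packing infeasible")

    return SyntheticScene(
        geometry=geometry,
        cells=tuple(cells),
        debris=tuple(debris),
        noise_sd=float(noise_sd),
        seed=int(seed),
        n_migratory_assigned=n_migratory if track_migratory else None,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def channel_template_mask(geometry: DeviceGeometry) -> np.ndarray:
    """Boolean mask of all channel regions (migration channels + central band)."""
    mask = np.zeros(geometry.image_shape_px, dtype=bool)
    c0 = geometry.margin_px
    for i in range(geometry.n_channels_per_side):
        r0, r1 = geometry.channel_rows(i)
        mask[r0:r1, int(c0) : int(round(c0 + geometry.length_px))] = True
        if geometry.n_sides == 2:
            rc0 = int(round(c0 + geometry.length_px + geometry.central_px))
            mask[r0:r1, rc0 : int(round(rc0 + geometry.length_px))] = True
    if geometry.n_sides == 2:
        b0 = int(round(c0 + geometry.length_px))
        b1 = int(round(b0 + geometry.central_px))
        rows0 = geometry.channel_rows(0)[0]
        rows1 = geometry.channel_rows(geometry.n_channels_per_side - 1)[1]
        mask[rows0:rows1, b0:b1] = True
    return mask


def _draw_spot(
    plane: np.ndarray, row: float, col: float, radius_px: float, peak: float
) -> None:
    """Stamp an anti-aliased disk: full ``peak`` core, 1-px soft rim."""
    r0 = max(int(np.floor(row - radius_px - 1)), 0)
    r1 = min(int(np.ceil(row + radius_px + 2)), plane.shape[0])
    c0 = max(int(np.floor(col - radius_px - 1)), 0)
    c1 = min(int(np.ceil(col + radius_px + 2)), plane.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - row, cc - col)
    coverage = np.clip(radius_px + 0.5 - d, 0.0, 1.0)
    patch = peak * coverage
    np.maximum(plane[r0:r1, c0:c1], patch, out=plane[r0:r1, c0:c1])


_BF_CHANNEL_LEVEL = 80.0
_BF_OBJECT_LEVEL = 160.0


def render(scene: SyntheticScene) -> RenderedImage:
    """Render a scene into the three 8-bit micrograph planes.

    Live cells are stamped into the live (FITC) plane; dead cells into both
    the dead (TRITC) plane and, at the same peak, the live plane — emulating
    the residual green signal of dying cells that makes TRITC-based
    exclusion a real filtering step.  Debris appears in the live plane only.
    Gaussian read noise of sd ``scene.noise_sd`` is added to every plane and
    the result clipped to [0, 255].
    """
    geom = scene.geometry
    shape = geom.image_shape_px
    bright = channel_template_mask(geom).astype(np.float64) * _BF_CHANNEL_LEVEL
    live = np.zeros(shape, dtype=np.float64)
    dead = np.zeros(shape, dtype=np.float64)

    for cell in scene.cells:
        r0, r1 = geom.channel_rows(cell.channel_index)
        row = (r0 + r1) / 2.0
        col = geom.cell_col(cell.side, cell.distance_um)
        radius_px = cell.radius_um / geom.pixel_size_um
        _draw_spot(bright, row, col, radius_px, _BF_OBJECT_LEVEL)
        _draw_spot(live, row, col, radius_px, cell.peak_intensity)
        if cell.viability == "dead":
            _draw_spot(dead, row, col, radius_px, cell.peak_intensity)
    for deb in scene.debris:
        r0, r1 = geom.channel_rows(deb.channel_index)
        row = (r0 + r1) / 2.0
        col = geom.cell_col(deb.side, deb.distance_um)
        radius_px = deb.radius_um / geom.pixel_size_um
        _draw_spot(bright, row, col, radius_px, _BF_OBJECT_LEVEL)
        _draw_spot(live, row, col, radius_px, deb.peak_intensity)

    planes = []
    noise_rng = np.random.default_rng(scene.seed + 1)
    for plane in (bright, live, dead):
        if scene.noise_sd > 0:
            plane = plane + noise_rng.normal(0.0, scene.noise_sd, size=shape)
        planes.append(np.clip(np.rint(plane), 0, 255).astype(np.uint8))
    return RenderedImage(*planes)


# ---------------------------------------------------------------------------
# ground truth summaries and I/O
# ---------------------------------------------------------------------------


def ground_truth_frontiers(scene: SyntheticScene) -> pd.DataFrame:
    """Exact per-channel live count and frontier distance for a scene.

    This is the manual-measurement-equivalent oracle the automated pipeline
    is validated against: for every channel the farthest live cell's
    distance (0 when the channel holds no live cell).
    """
    geom = scene.geometry
    sides: tuple[Side, ...] = ("left", "right")[: geom.n_sides]
    rows = []
    live = [c for c in scene.cells if c.viability == "live"]
    for side in sides:
        for idx in range(geom.n_channels_per_side):
            mine = [c for c in live if c.side == side and c.channel_index == idx]
            frontier = max((c.distance_um for c in mine), default=0.0)
            rows.append(
                {
                    "channel_index": idx,
                    "side": side,
                    "n_live": len(mine),
                    "frontier_distance_um": frontier,
                }
            )
    return pd.DataFrame(rows)


def write_tiff(image: RenderedImage, path: str | Path) -> None:
    """Write the three planes as a multi-page 8-bit grayscale TIFF."""
    stack = np.stack([image.bright_field, image.live_fluor, image.dead_fluor])
    tifffile.imwrite(path, stack, photometric="minisblack")


def write_ground_truth_csv(scene: SyntheticScene, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "channel_index": c.channel_index,
                "side": c.side,
                "distance_um": c.distance_um,
                "viability": c.viability,
                "radius_um": c.radius_um,
                "peak_intensity": c.peak_intensity,
            }
            for c in scene.cells
        ]
    ).to_csv(path, index=False)
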