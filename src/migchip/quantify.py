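"""Automated per-channel cell detection and migration-frontier measurement.

Reimplements the chip's five-step image analysis: (1) import a multi-plane
TIFF micrograph, (2) segment the migration channels using the known device
template (optionally registered to the bright-field plane by translation),
(3) call cells as connected blocks of supra-threshold "bright pixels" in the
live-stain plane, (4) reject small blocks (noise, debris, defects) and
dead-stained cells, (5) mark the farthest live cell in each channel as that
channel's migration frontier.  Only the central block of channels per side
(300 of 450 by default) is flagged for downstream analysis.

Also provides the single-cell sphere-chip counter: connected bright regions
whose equivalent-area diameter exceeds 40 µm are scored as spheres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .chipmodel import ROI_OVERSHOOT_PX, DeviceGeometry, RenderedImage, channel_template_mask

__all__ = [
    "QuantConfig",
    "ChannelROI",
    "DetectedObject",
    "ChannelResult",
    "SphereCount",
    "load_image",
    "segment_channels",
    "find_bright_pixels",
    "detect_objects",
    "classify_viability",
    "channel_frontier",
    "quantify_device",
    "classify_populations",
    "count_spheres",
    "results_to_frame",
]


@dataclass(frozen=True)
class QuantConfig:
    """Tunable detection parameters.

    ``live_threshold``/``dead_threshold`` are the strict lower bounds for a
    pixel to count as bright in the FITC/TRITC planes.  A connected block
    needs at least ``min_bright_pixels`` bright pixels to be called a cell
    (a 10 µm cell covers ~78 px at 1 µm/px, so 20 rejects debris while
    keeping dim cells).  ``reach_tolerance_um`` absorbs sub-pixel centroid
    discretisation when deciding whether a frontier reached the channel
    exit; frontiers within it are snapped to the full channel length.
    """

    live_threshold: int = 50
    dead_threshold: int = 50
    min_bright_pixels: int = 20
    pixel_size_um: float = 1.0
    central_window: int = 300
    connectivity: Literal[4, 8] = 8
    reach_tolerance_um: float = 1.0

    def __post_init__(self) -> None:
        for name in ("live_threshold", "dead_threshold"):
            if not 0 <= getattr(self, name) <= 255:
                raise ValueError(f"{name} must be in [0, 255]")
        if self.min_bright_pixels < 1:
            raise ValueError("min_bright_pixels must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass(frozen=True)
class ChannelROI:
    channel_index: int
    side: Literal["left", "right"]
    entrance_px: tuple[float, float]  # (row, col) of the loading entrance
    axis_direction: tuple[float, float]  # unit (drow, dcol) toward the centre
    bbox_px: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open
    length_um: float

    def contains(self, row: float, col: float) -> bool:
        r0, c0, r1, c1 = self.bbox_px
        return r0 <= row < r1 and c0 <= col < c1


@dataclass(frozen=True)
class DetectedObject:
    channel_index: int
    side: Literal["left", "right"]
    centroid_px: tuple[float, float]
    bright_pixel_count: int
    cls: Literal["live", "dead", "rejected"]
    # footprint pixel coordinates, kept for viability overlap tests
    footprint: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)


@dataclass(frozen=True)
class ChannelResult:
    channel_index: int
    side: Literal["left", "right"]
    n_live: int
    frontier_distance_um: float
    reached_central: bool
    used_in_analysis: bool


@dataclass(frozen=True)
class SphereCount:
    n_seeded_wells: int
    n_spheres: int
    sphere_rate: float
    diameters_um: tuple[float, ...]


# ---------------------------------------------------------------------------
# step 1: TIFF import
# ---------------------------------------------------------------------------


def load_image(path: str | Path) -> RenderedImage:
    """Read a 1- or 3-page 8-bit grayscale TIFF into named planes.

    Page order for 3-page files is bright-field, live (FITC), dead (TRITC).
    A single-page file is taken as the live plane with empty companions
    (a warning is issued).
    """
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - tifffile message suffices
        raise ValueError(f"could not read TIFF {path!r}: {exc}") from exc
    data = np.asarray(data)
    if data.dtype != np.uint8:
        raise ValueError(f"expected 8-bit TIFF, got dtype {data.dtype}")
    if data.ndim == 2:
        warnings.warn(
            "single-page TIFF: treating it as the live (FITC) plane with "
            "empty bright-field and dead planes",
            stacklevel=2,
        )
        empty = np.zeros_like(data)
        return RenderedImage(empty, data, empty.copy())
    if data.ndim == 3 and data.shape[0] == 3:
        return RenderedImage(data[0], data[1], data[2])
    raise ValueError(
        f"expected 1 or 3 pages of equal shape, got array of shape {data.shape}"
    )


# ---------------------------------------------------------------------------
# step 2: channel segmentation
# ---------------------------------------------------------------------------


def _template_rois(geometry: DeviceGeometry, offset: tuple[int, int] = (0, 0)) -> list[ChannelROI]:
    dr, dc = offset
    rois: list[ChannelROI] = []
    L_px = geometry.length_px
    pad = min(ROI_OVERSHOOT_PX, geometry.margin_px)
    sides = ("left", "right")[: geometry.n_sides]
    for side in sides:
        sign = geometry.axis_sign(side)
        ent_col = geometry.entrance_col(side) + dc
        for i in range(geometry.n_channels_per_side):
            r0, r1 = geometry.channel_rows(i)
            r0, r1 = r0 + dr, r1 + dr
            if side == "left":
                c0 = int(round(ent_col - pad))
                c1 = int(round(ent_col + L_px + ROI_OVERSHOOT_PX))
            else:
                c0 = int(round(ent_col - L_px - ROI_OVERSHOOT_PX))
                c1 = int(round(ent_col + pad))
            rois.append(
                ChannelROI(
                    channel_index=i,
                    side=side,
                    entrance_px=(float((r0 + r1) / 2.0), float(ent_col)),
                    axis_direction=(0.0, float(sign)),
                    bbox_px=(r0, c0, r1, c1),
                    length_um=geometry.channel_length_um,
                )
            )
    return rois


def _registration_offset(bright_field: np.ndarray, template: np.ndarray) -> tuple[int, int]:
    """Integer shift maximizing circular cross-correlation template->image."""
    a = bright_field.astype(np.float64) - float(bright_field.mean())
    b = template.astype(np.float64) - float(template.mean())
    corr = np.fft.irfft2(
        np.fft.rfft2(a) * np.conj(np.fft.rfft2(b)), s=a.shape
    )
    dr, dc = np.unravel_index(int(np.argmax(corr)), corr.shape)
    if dr > a.shape[0] // 2:
        dr -= a.shape[0]
    if dc > a.shape[1] // 2:
        dc -= a.shape[1]
    return int(dr), int(dc)


def segment_channels(
    image: RenderedImage,
    geometry: DeviceGeometry,
    registration: Literal["none", "translation"] = "none",
) -> list[ChannelROI]:
    """Place one ROI per migration channel from the device template.

    With ``registration='translation'`` the template is first shifted by the
    integer offset that maximises cross-correlation between the channel
    template mask and the bright-field plane, compensating stage offsets.
    """
    if image.bright_field.shape != tuple(geometry.image_shape_px):
        raise ValueError(
            f"image shape {image.bright_field.shape} does not match geometry "
            f"{geometry.image_shape_px}"
        )
    offset = (0, 0)
    if registration == "translation":
        template = channel_template_mask(geometry).astype(np.float64)
        offset = _registration_offset(image.bright_field, template)
    elif registration != "none":
        raise ValueError("registration must be 'none' or 'translation'")
    rois = _template_rois(geometry, offset)
    rows, cols = image.bright_field.shape
    for roi in rois:
        r0, c0, r1, c1 = roi.bbox_px
        if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
            raise ValueError(
                f"channel template exceeds image bounds after registration "
                f"offset {offset}"
            )
    return rois


# ---------------------------------------------------------------------------
# steps 3-4: bright pixels, object calling, false-event exclusion
# ---------------------------------------------------------------------------


def find_bright_pixels(plane: np.ndarray, threshold: int) -> np.ndarray:
    """Bright-pixel mask: strictly greater than the threshold."""
    return np.asarray(plane) > threshold


def _label_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def detect_objects(
    mask: np.ndarray,
    config: QuantConfig,
    rois: Sequence[ChannelROI],
) -> list[DetectedObject]:
    """Call connected bright-pixel blocks within the channel ROIs as cells.

    Blocks with at least ``min_bright_pixels`` pixels are valid objects;
    smaller blocks are returned with ``cls='rejected'`` (noise, debris,
    device defects).  Each object is assigned to the ROI containing its
    centroid; blocks whose centroid lies outside every ROI are dropped.
    """
    labels, n = ndimage.label(mask, structure=_label_structure(config.connectivity))
    if n == 0:
        return []
    counts = np.bincount(labels.ravel())[1:]
    centroids = ndimage.center_of_mass(mask, labels, index=np.arange(1, n + 1))
    slices = ndimage.find_objects(labels)

    r0s = np.array([r.bbox_px[0] for r in rois])
    c0s = np.array([r.bbox_px[1] for r in rois])
    r1s = np.array([r.bbox_px[2] for r in rois])
    c1s = np.array([r.bbox_px[3] for r in rois])

    objects: list[DetectedObject] = []
    for lab in range(1, n + 1):
        row, col = centroids[lab - 1]
        hit = np.flatnonzero((r0s <= row) & (row < r1s) & (c0s <= col) & (col < c1s))
        if hit.size == 0:
            continue
        roi = rois[int(hit[0])]
        sl = slices[lab - 1]
        local = labels[sl] == lab
        rr, cc = np.nonzero(local)
        footprint = (rr + sl[0].start, cc + sl[1].start)
        count = int(counts[lab - 1])
        objects.append(
            DetectedObject(
                channel_index=roi.channel_index,
                side=roi.side,
                centroid_px=(float(row), float(col)),
                bright_pixel_count=count,
                cls="live" if count >= config.min_bright_pixels else "rejected",
                footprint=footprint,
            )
        )
    return objects


def classify_viability(
    objects: Sequence[DetectedObject],
    live_mask: np.ndarray,
    dead_mask: np.ndarray,
) -> list[DetectedObject]:
    """Mark objects overlapping the dead-stain (TRITC) mask as dead.

    Any supra-threshold dead-plane pixel inside an object's footprint marks
    it dead; dead objects are excluded from frontier computation.  Rejected
    objects are passed through unchanged.
    """
    out: list[DetectedObject] = []
    for obj in objects:
        if obj.cls == "rejected":
            out.append(obj)
            continue
        rr, cc = obj.footprint
        cls = "dead" if bool(dead_mask[rr, cc].any()) else "live"
        out.append(replace(obj, cls=cls))
    return out


# ---------------------------------------------------------------------------
# step 5: migration frontier
# ---------------------------------------------------------------------------


def channel_frontier(
    roi: ChannelROI,
    live_objects: Sequence[DetectedObject],
    config: QuantConfig,
    used_in_analysis: bool = True,
) -> ChannelResult:
    """Frontier distance of one channel: the farthest live cell's centroid.

    Displacement is the along-axis component of each centroid relative to
    the entrance line, in µm, clamped to [0, L].  Empty channels score 0
    (cells remained at the loading position).  Frontiers within
    ``reach_tolerance_um`` of the exit are snapped to L and flagged as
    having reached the central channel.
    """
    L = roi.length_um
    best = 0.0
    for obj in live_objects:
        if obj.cls != "live":
            continue
        drow = obj.centroid_px[0] - roi.entrance_px[0]
        dcol = obj.centroid_px[1] - roi.entrance_px[1]
        disp = (
            drow * roi.axis_direction[0] + dcol * roi.axis_direction[1]
        ) * config.pixel_size_um
        best = max(best, disp)
    reached = best >= L - config.reach_tolerance_um
    distance = L if reached else min(max(best, 0.0), L)
    return ChannelResult(
        channel_index=roi.channel_index,
        side=roi.side,
        n_live=sum(1 for o in live_objects if o.cls == "live"),
        frontier_distance_um=distance,
        reached_central=reached,
        used_in_analysis=used_in_analysis,
    )


def _central_window_indices(n_per_side: int, window: int) -> range:
    if window > n_per_side:
        raise ValueError("central_window exceeds channels per side")
    start = (n_per_side - window) // 2
    return range(start, start + window)


def quantify_device(
    image: RenderedImage,
    geometry: DeviceGeometry,
    config: QuantConfig | None = None,
    registration: Literal["none", "translation"] = "none",
) -> list[ChannelResult]:
    """Run the full pipeline over every migration channel of one device.

    Returns one :class:`ChannelResult` per channel; ``used_in_analysis`` is
    set only for the ``central_window`` channels per side nearest the array
    midline (the chip's uniform-loading region).
    """
    config = config or QuantConfig()
    rois = segment_channels(image, geometry, registration)
    live_mask = find_bright_pixels(image.live_fluor, config.live_threshold)
    dead_mask = find_bright_pixels(image.dead_fluor, config.dead_threshold)
    objects = detect_objects(live_mask, config, rois)
    objects = classify_viability(objects, live_mask, dead_mask)

    by_channel: dict[tuple[str, int], list[DetectedObject]] = {}
    for obj in objects:
        by_channel.setdefault((obj.side, obj.channel_index), []).append(obj)

    window = set(_central_window_indices(geometry.n_channels_per_side, config.central_window))
    results = [
        channel_frontier(
            roi,
            by_channel.get((roi.side, roi.channel_index), []),
            config,
            used_in_analysis=roi.channel_index in window,
        )
        for roi in rois
    ]
    return results


def classify_populations(
    results: Sequence[ChannelResult],
) -> dict[str, list[tuple[str, int]]]:
    """Split analysed channels into migratory / non-migratory populations.

    A channel is migratory when its frontier reached the central channel;
    the partition is restricted to channels inside the central window.
    """
    migratory, non_migratory = [], []
    for res in results:
        if not res.used_in_analysis:
            continue
        key = (res.side, res.channel_index)
        (migratory if res.reached_central else non_migratory).append(key)
    return {"migratory": migratory, "non_migratory": non_migratory}


def results_to_frame(results: Sequence[ChannelResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "channel_index": r.channel_index,
                "side": r.side,
                "n_live": r.n_live,
                "frontier_distance_um": r.frontier_distance_um,
                "reached_central": r.reached_central,
                "used_in_analysis": r.used_in_analysis,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# sphere chip
# ---------------------------------------------------------------------------


def count_spheres(
    plane: np.ndarray,
    threshold: int,
    pixel_size_um: float,
    min_diameter_um: float = 40.0,
    n_seeded_wells: int | None = None,
    connectivity: Literal[4, 8] = 8,
) -> SphereCount:
    """Count single-cell-derived spheres larger than ``min_diameter_um``.

    Connected supra-threshold regions are measured by equivalent-area
    diameter ``2 * sqrt(area_px / pi) * pixel_size_um``; only regions above
    the diameter cut-off are scored as spheres.  ``sphere_rate`` is spheres
    per seeded single-cell well.
    """
    if n_seeded_wells is None or n_seeded_wells <= 0:
        raise ValueError("n_seeded_wells must be a positive count")
    mask = find_bright_pixels(plane, threshold)
    labels, n = ndimage.label(mask, structure=_label_structure(connectivity))
    diameters: list[float] = []
    if n:
        areas = np.bincount(labels.ravel())[1:]
        diameters = sorted(
            float(2.0 * np.sqrt(a / np.pi) * pixel_size_um) for a in areas
        )
    n_spheres = sum(1 for d in diameters if d > min_diameter_um)
    return SphereCount(
        n_seeded_wells=int(n_seeded_wells),
        n_spheres=n_spheres,
        sphere_rate=n_spheres / n_seeded_wells,
        diameters_um=tuple(diameters),
    )
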