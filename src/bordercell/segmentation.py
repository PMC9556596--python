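"""Decomposition of a border-cell cluster into subcellular F-actin regions.

A migrating border-cell group carries F-actin in three distinct subcellular
compartments: finger-like *protrusions* extending from the cluster,
a peripheral supracellular actomyosin *cable* running along the outer rim
(possibly interrupted by dim "broken" sections), and inner cell-to-cell
*contacts*.  This module reproduces the semi-automatic decomposition:

1. foreground segmentation of the whole group (Otsu threshold, hole
   filling, largest connected component),
2. protrusion / main-body split by morphological opening,
3. cable tracing along the body rim, split into per-cell arcs at
   user-clicked boundary landmarks and into intact vs broken runs by a
   local intensity criterion,
4. contact labelling as the brightest path between two clicked endpoints.

Coordinate convention: points are (x, y) pairs with x rightward and y
downward, 0-based; image arrays are indexed ``[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.graph import route_through_array
from skimage.morphology import disk


class SegmentationError(ValueError):
    """Raised when an image cannot be decomposed as requested."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class TimelapseStack:
    """Calibrated fluorescence time-lapse.

    ``frames`` has shape (T, C, H, W); single-channel data is stored with
    C = 1.  Calibration (pixel size, frame interval) always travels with
    the pixels so downstream stages can report physical units.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_names: list[str] = field(default_factory=lambda: ["actin"])
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 3:  # (T, H, W) -> single channel
            self.frames = self.frames[:, None, :, :]
        if self.frames.ndim != 4:
            raise ValueError("frames must have shape (T, C, H, W) or (T, H, W)")
        if self.frames.shape[0] < 1:
            raise ValueError("stack needs at least one frame")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration must be strictly positive")
        if len(self.channel_names) != self.frames.shape[1]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return int(self.frames.shape[2]), int(self.frames.shape[3])

    def channel(self, name: str) -> np.ndarray:
        """Return the (T, H, W) array for a named channel."""
        return self.frames[:, self.channel_names.index(name)]


@dataclass
class Landmarks:
    """The 'semi-automatic' click points.

    ``boundary_points`` are the cell-to-cell boundary junctions on the
    cluster rim, clicked clockwise starting at one side of the leader
    protrusion.  ``contact_endpoints`` holds (start, end) pixel pairs for
    each inner contact.
    """

    boundary_points: np.ndarray  # (N, 2) int, (x, y)
    contact_endpoints: list[tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        self.boundary_points = np.asarray(self.boundary_points, dtype=int)
        if self.boundary_points.ndim != 2 or self.boundary_points.shape[1] != 2:
            raise ValueError("boundary_points must be an (N, 2) array")


@dataclass
class CableSegment:
    """One maximal run of rim pixels, intact (bright cable) or broken."""

    cell_index: int
    polyline: np.ndarray  # (N, 2) int, (x, y), ordered clockwise
    intact: bool
    length_um: float
    mean_intensity: float | None = None


@dataclass
class Contact:
    """Inner cell-to-cell contact: brightest path dilated to a ribbon."""

    polyline: np.ndarray  # (N, 2) int, (x, y)
    mask: np.ndarray  # bool (H, W)
    mean_intensity: float | None
    area_um2: float


@dataclass
class RegionSet:
    """Labelled subcellular regions of one cluster frame."""

    body_mask: np.ndarray  # bool (H, W)
    protrusion_labels: np.ndarray  # int (H, W); 0 = not a protrusion
    cable_segments: list[CableSegment]
    contacts: list[Contact]
    cell_count: int
    pixel_size_um: float

    @property
    def protrusion_ids(self) -> list[int]:
        ids = np.unique(self.protrusion_labels)
        return [int(i) for i in ids if i != 0]

    @property
    def protrusion_mask(self) -> np.ndarray:
        return self.protrusion_labels > 0

    @property
    def group_mask(self) -> np.ndarray:
        return self.body_mask | self.protrusion_mask

    def cable_mask(self, half_width_px: int = 1) -> np.ndarray:
        """Binary band around intact cable polylines, clipped to the body."""
        band = _polyline_band(
            [s.polyline for s in self.cable_segments if s.intact],
            self.body_mask.shape,
            half_width_px,
        )
        return band & self.body_mask

    def broken_mask(self, half_width_px: int = 1) -> np.ndarray:
        band = _polyline_band(
            [s.polyline for s in self.cable_segments if not s.intact],
            self.body_mask.shape,
            half_width_px,
        )
        return band & self.body_mask

    def contact_mask(self) -> np.ndarray:
        out = np.zeros(self.body_mask.shape, dtype=bool)
        for c in self.contacts:
            out |= c.mask
        return out


def _polyline_band(polylines, shape, half_width_px: int) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for pl in polylines:
        pl = np.asarray(pl, dtype=int)
        if pl.size:
            out[pl[:, 1], pl[:, 0]] = True
    if half_width_px > 0 and out.any():
        out = ndimage.binary_dilation(out, structure=disk(half_width_px))
    return out


# ---------------------------------------------------------------------------
# rim tracing helper (shared with the synthetic generator)
# ---------------------------------------------------------------------------


def trace_rim(mask: np.ndarray) -> np.ndarray:
    """Ordered closed pixel polyline of the mask boundary, clockwise.

    Returns an (N, 2) int array of (x, y) vertices; the polyline is closed
    implicitly (last vertex connects back to the first).  Clockwise is
    meant on screen, i.e. with y pointing down.
    """
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise SegmentationError("mask has no boundary contour")
    contour = max(contours, key=len)  # (row, col) float
    pts = np.round(contour[:, ::-1]).astype(int)  # -> (x, y)
    # contour rounding can land one pixel outside the mask; snap those
    # vertices onto the nearest 8-neighbour mask pixel
    H, W = mask.shape
    pts[:, 0] = np.clip(pts[:, 0], 0, W - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, H - 1)
    mask_b = np.asarray(mask, dtype=bool)
    for i, (x, y) in enumerate(pts):
        if mask_b[y, x]:
            continue
        for dx, dy in ((0, 1), (0, -1), (1, 0), (-1, 0),
                       (1, 1), (1, -1), (-1, 1), (-1, -1)):
            nx, ny = x + dx, y + dy
            if 0 <= nx < W and 0 <= ny < H and mask_b[ny, nx]:
                pts[i] = (nx, ny)
                break
    # drop consecutive duplicates introduced by rounding/snapping
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
    pts = pts[keep]
    if len(pts) > 1 and np.all(pts[0] == pts[-1]):
        pts = pts[:-1]
    # shoelace with y-down: positive area == clockwise on screen
    x, y = pts[:, 0].astype(float), pts[:, 1].astype(float)
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 < 0:
        pts = pts[::-1]
    return pts


def polyline_length_px(pts: np.ndarray, closed: bool = False) -> float:
    """Summed inter-vertex Euclidean step length, in pixels."""
    pts = np.asarray(pts, dtype=float)
    if len(pts) < 2:
        return 0.0
    d = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
    if closed:
        d += float(np.linalg.norm(pts[0] - pts[-1]))
    return float(d)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def project_zstack(zstack: np.ndarray, method: str = "max") -> np.ndarray:
    """Project a (Z, H, W) stack to a single plane by per-pixel max or mean."""
    zstack = np.asarray(zstack)
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise SegmentationError("z-stack must be a non-empty (Z, H, W) array")
    if method == "max":
        return zstack.max(axis=0)
    if method == "mean":
        return zstack.mean(axis=0)
    raise SegmentationError(f"unknown projection method {method!r}")


def subtract_background(
    frame: np.ndarray,
    bg="auto",
    group_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Subtract the sample-free background level and clamp at zero.

    ``bg`` is either ``"auto"`` (mean of the lowest-decile pixels) or a
    rectangle ``(x0, y0, x1, y1)`` (half-open) lying outside the group.
    """
    frame = np.asarray(frame, dtype=float)
    if isinstance(bg, str):
        if bg != "auto":
            raise SegmentationError(f"unknown background mode {bg!r}")
        cutoff = np.quantile(frame, 0.10)
        level = float(frame[frame <= cutoff].mean())
    else:
        x0, y0, x1, y1 = (int(v) for v in bg)
        if x1 <= x0 or y1 <= y0:
            raise SegmentationError("background rectangle is empty")
        if group_mask is not None and group_mask[y0:y1, x0:x1].any():
            raise SegmentationError("background rectangle overlaps the group mask")
        level = float(frame[y0:y1, x0:x1].mean())
    return np.clip(frame - level, 0.0, None)


def segment_group(frame: np.ndarray) -> np.ndarray:
    """Whole-group mask: Otsu threshold, fill holes, keep the largest blob."""
    frame = np.asarray(frame, dtype=float)
    if not np.any(frame > 0):
        raise SegmentationError("frame is empty; cannot segment a group")
    thr = threshold_otsu(frame)
    fg = frame > thr
    if not fg.any():
        raise SegmentationError("no foreground above the Otsu threshold")
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg)
    if n == 0:
        raise SegmentationError("no connected foreground component")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def decompose_protrusions(
    group_mask: np.ndarray,
    pixel_size_um: float,
    opening_radius_um: float = 2.0,
    min_protrusion_area_um2: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a group mask into main body and labelled protrusions.

    The body is the largest component of the morphological opening of the
    mask with a disk of ``opening_radius_um``; protrusions are the
    connected components of mask minus body whose area reaches
    ``min_protrusion_area_um2``.  Smaller residues are merged back into
    the body so body and protrusions always partition the input mask.
    """
    group_mask = np.asarray(group_mask, dtype=bool)
    if not group_mask.any():
        raise SegmentationError("group mask is empty")
    radius_px = max(1, int(round(opening_radius_um / pixel_size_um)))
    opened = ndimage.binary_opening(group_mask, structure=disk(radius_px))
    opened &= group_mask
    if not opened.any():
        raise SegmentationError(
            f"opening with radius {opening_radius_um} um erased the whole mask; "
            "try a smaller opening radius"
        )
    labels, n = ndimage.label(opened)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    body = labels == (int(np.argmax(sizes)) + 1)

    residue = group_mask & ~body
    res_labels, n_res = ndimage.label(residue)
    min_area_px = min_protrusion_area_um2 / pixel_size_um**2
    protrusions = np.zeros_like(res_labels)
    next_id = 1
    for i in range(1, n_res + 1):
        comp = res_labels == i
        if comp.sum() >= min_area_px:
            protrusions[comp] = next_id
            next_id += 1
        else:
            body |= comp
    return body, protrusions


def _rim_band_intensity(
    frame: np.ndarray, rim: np.ndarray, body_mask: np.ndarray
) -> np.ndarray:
    """Per-vertex intensity sampled on a 3-px band inward of the rim.

    For each vertex the local tangent is estimated from its neighbours
    and the frame is averaged over the vertex and the two pixels along
    the inward normal (the segmented boundary sits at the outer edge of
    the peripheral cable, so the band must reach into it).
    """
    H, W = frame.shape
    n = len(rim)
    prev_pts = rim[np.arange(-1, n - 1)]
    next_pts = rim[(np.arange(n) + 1) % n]
    tangent = (next_pts - prev_pts).astype(float)
    norm = np.linalg.norm(tangent, axis=1)
    norm[norm == 0] = 1.0
    tangent /= norm[:, None]
    normal = np.stack([tangent[:, 1], -tangent[:, 0]], axis=1)
    offset = np.round(normal).astype(int)
    # orient each offset toward the body interior
    probe = rim + offset
    px = np.clip(probe[:, 0], 0, W - 1)
    py = np.clip(probe[:, 1], 0, H - 1)
    inward = np.where(body_mask[py, px][:, None], 1, -1)
    offset = offset * inward
    vals = np.zeros(n)
    for depth in (0, 1, 2):
        p = rim + depth * offset
        px = np.clip(p[:, 0], 0, W - 1)
        py = np.clip(p[:, 1], 0, H - 1)
        vals += frame[py, px]
    return vals / 3.0


def trace_cables(
    frame: np.ndarray,
    body_mask: np.ndarray,
    landmarks: Landmarks,
    pixel_size_um: float,
    cable_intensity_threshold: float = 1.1,
    snap_px: float = 3.0,
) -> list[CableSegment]:
    """Trace the supracellular cable along the body rim.

    The body boundary polyline is split at the (snapped) boundary
    landmarks into per-cell arcs, clockwise in the order clicked.  Within
    each arc, maximal runs of rim pixels whose local band intensity
    reaches ``cable_intensity_threshold`` times the group-mean intensity
    are intact cable segments; runs below it are broken segments.
    """
    frame = np.asarray(frame, dtype=float)
    rim = trace_rim(body_mask)
    band_int = _rim_band_intensity(frame, rim, body_mask)
    group_mean = float(frame[body_mask].mean())
    threshold = cable_intensity_threshold * group_mean
    bright = band_int >= threshold
    # circular 7-vertex majority vote: suppresses speckle runs up to 3 px
    # without shifting the boundaries of longer intact/broken runs
    votes = sum(np.roll(bright, k) for k in range(-3, 4))
    bright = votes >= 4

    # snap each landmark to the nearest rim vertex
    pts = landmarks.boundary_points
    idx = []
    for k, p in enumerate(pts):
        d = np.linalg.norm(rim - p[None, :], axis=1)
        j = int(np.argmin(d))
        if d[j] > snap_px:
            raise SegmentationError(
                f"landmark {k} at {tuple(int(v) for v in p)} is {d[j]:.1f} px from "
                f"the body boundary (snap tolerance {snap_px} px)"
            )
        idx.append(j)

    # rotate the rim so landmark 0 is vertex 0, then cut at the others
    n = len(rim)
    shift = idx[0]
    rim = np.roll(rim, -shift, axis=0)
    bright = np.roll(bright, -shift)
    cuts = sorted((j - shift) % n for j in idx)

    segments: list[CableSegment] = []
    for cell, (a, b) in enumerate(zip(cuts, cuts[1:] + [n + cuts[0]])):
        arc_idx = np.arange(a, b) % n
        arc_pts = rim[arc_idx]
        arc_bright = bright[arc_idx]
        start = 0
        for stop in range(1, len(arc_idx) + 1):
            if stop == len(arc_idx) or arc_bright[stop] != arc_bright[start]:
                pl = arc_pts[start:stop]
                segments.append(
                    CableSegment(
                        cell_index=cell,
                        polyline=pl,
                        intact=bool(arc_bright[start]),
                        length_um=polyline_length_px(pl) * pixel_size_um,
                        mean_intensity=float(frame[pl[:, 1], pl[:, 0]].mean()),
                    )
                )
                start = stop
    return segments


def label_contacts(
    frame: np.ndarray,
    contact_endpoints,
    body_mask: np.ndarray,
    pixel_size_um: float,
    half_width_px: int = 2,
) -> list[Contact]:
    """Label inner cell-to-cell contacts as brightest paths between clicks.

    The path minimises the accumulated cost 1/(1 + intensity) inside the
    body mask (geometric step weighting, so on a flat field the path is
    the straight line); it is then dilated to a ribbon of the given
    half-width.
    """
    frame = np.asarray(frame, dtype=float)
    cost = 1.0 / (1.0 + frame)
    cost[~body_mask] = 1e9  # keep paths inside the cluster
    contacts = []
    for k, (p0, p1) in enumerate(contact_endpoints):
        p0 = tuple(int(v) for v in p0)
        p1 = tuple(int(v) for v in p1)
        for p in (p0, p1):
            if not body_mask[p[1], p[0]]:
                raise SegmentationError(
                    f"contact {k} endpoint {p} lies outside the body mask"
                )
        if p0 == p1:
            path = np.array([p0])
        else:
            indices, _ = route_through_array(
                cost, (p0[1], p0[0]), (p1[1], p1[0]),
                fully_connected=True, geometric=True,
            )
            path = np.array(indices)[:, ::-1]  # (row, col) -> (x, y)
        mask = _polyline_band([path], frame.shape, half_width_px) & body_mask
        contacts.append(
            Contact(
                polyline=path,
                mask=mask,
                mean_intensity=float(frame[mask].mean()),
                area_um2=float(mask.sum()) * pixel_size_um**2,
            )
        )
    return contacts


def build_region_set(
    frame: np.ndarray,
    landmarks: Landmarks,
    pixel_size_um: float,
    opening_radius_um: float = 2.0,
    min_protrusion_area_um2: float = 5.0,
    cable_intensity_threshold: float = 1.1,
    snap_px: float = 3.0,
    contact_half_width_px: int = 2,
) -> RegionSet:
    """Full decomposition of one background-subtracted frame."""
    group = segment_group(frame)
    body, protrusions = decompose_protrusions(
        group, pixel_size_um, opening_radius_um, min_protrusion_area_um2
    )
    segments = trace_cables(
        frame, body, landmarks, pixel_size_um, cable_intensity_threshold, snap_px
    )
    contacts = label_contacts(
        frame, landmarks.contact_endpoints, body, pixel_size_um, contact_half_width_px
    )
    return RegionSet(
        body_mask=body,
        protrusion_labels=protrusions,
        cable_segments=segments,
        contacts=contacts,
        cell_count=max(1, len(landmarks.boundary_points)),
        pixel_size_um=pixel_size_um,
    )
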