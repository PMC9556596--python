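"""Particle image velocimetry of actin flows and derived flow statistics.

Displacements of the actin network between consecutive frames are
estimated by windowed cross-correlation: a small *source* patch around
each grid point is compared against every integer placement inside a
larger *search* patch of the next frame, using the zero-normalized
(Pearson) cross-correlation coefficient.  The shift maximising the
coefficient is the displacement estimate; estimates whose peak
coefficient does not exceed the cutoff ``c0`` are discarded.  Kept
estimates are spread to every pixel of the cell outline by a truncated
Gaussian weighting, optionally smoothed in time, and summarised as
divergence maps (network sinks are strongly negative), retrograde /
anterograde labels relative to cell motion, per-region occurrence rates
and rose histograms of flow direction.

Default method constants: source window 1.4 um^2, search window
2.4 um^2, c0 = 0.5, spatial Gaussian kernel 6 um (sigma 1.2 um),
temporal kernel 20 s (sigma 10 s).  Velocities are stored in um/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from scipy.stats import spearmanr

RETROGRADE = -1
UNCLASSIFIED = 0
ANTEROGRADE = 1


class FlowError(ValueError):
    pass


def round_to_odd(x: float) -> int:
    """Nearest odd integer (>= 1)."""
    return max(1, 2 * int(round((x - 1) / 2)) + 1)


@dataclass
class PIVConfig:
    """Method constants of the cross-correlation flow analysis."""

    source_area_um2: float = 1.4
    search_area_um2: float = 2.4
    corr_threshold_c0: float = 0.5
    spatial_kernel_size_um: float = 6.0
    spatial_sigma_um: float = 1.2
    temporal_kernel_s: float = 20.0
    temporal_sigma_s: float = 10.0
    grid_stride_px: int | None = None  # default: source window side
    subpixel: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.corr_threshold_c0 < 1:
            raise ValueError("corr_threshold_c0 must lie in (0, 1)")
        if self.search_area_um2 <= self.source_area_um2:
            raise ValueError("search window must be larger than source window")

    def source_side_px(self, pixel_size_um: float) -> int:
        return round_to_odd(np.sqrt(self.source_area_um2) / pixel_size_um)

    def search_side_px(self, pixel_size_um: float) -> int:
        side = round_to_odd(np.sqrt(self.search_area_um2) / pixel_size_um)
        return max(side, self.source_side_px(pixel_size_um) + 2)


@dataclass
class SparseFlow:
    """Kept PIV estimates on the source-window grid."""

    x: np.ndarray  # grid centre columns (px)
    y: np.ndarray  # grid centre rows (px)
    u: np.ndarray  # um/min
    v: np.ndarray  # um/min
    corr: np.ndarray
    n_candidates: int  # grid points evaluated before c0 filtering

    @property
    def n_kept(self) -> int:
        return int(len(self.x))


@dataclass
class FlowField:
    """Dense per-pixel velocity field (um/min) with validity mask."""

    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    corr: np.ndarray | None = None
    frame_index: int = 0

    def speed(self) -> np.ndarray:
        s = np.hypot(self.u, self.v)
        s[~self.valid] = 0.0
        return s


@dataclass
class DivergenceMap:
    div: np.ndarray  # min^-1
    valid: np.ndarray


@dataclass
class FlowSummary:
    occurrence: dict  # region class -> mean fraction of pixels with strong flow
    mean_speed: dict  # region class -> mean valid speed (um/min)
    retro_antero: dict  # {"retrograde": frac, "anterograde": frac}
    angle_hist: dict | None  # {"bin_edges_deg": [...], "counts": [...]}
    divergence_stats: dict
    strong_speed_threshold_um_per_min: float | None = None


# ---------------------------------------------------------------------------
# displacement estimation
# ---------------------------------------------------------------------------


def _zncc_stack(source: np.ndarray, windows: np.ndarray) -> np.ndarray:
    """ZNCC of one source patch against a (K, K, h, w) stack of patches."""
    s = source - source.mean()
    s_norm = np.sqrt((s**2).sum())
    w = windows - windows.mean(axis=(-2, -1), keepdims=True)
    w_norm = np.sqrt((w**2).sum(axis=(-2, -1)))
    num = (w * s).sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / (w_norm * s_norm)
    corr[~np.isfinite(corr)] = -np.inf
    return corr


def _argmax_displacement(corr: np.ndarray, margin: int) -> tuple[int, int, float]:
    """Best shift with deterministic tie-breaking.

    Among coefficient ties (exact equality), the smallest displacement
    magnitude wins, then lexicographic (dy, dx).
    """
    best = corr.max()
    ties = np.argwhere(corr == best)
    dy = ties[:, 0] - margin
    dx = ties[:, 1] - margin
    order = np.lexsort((dx, dy, dx**2 + dy**2))
    i = order[0]
    return int(dy[i]), int(dx[i]), float(best)


def _parabolic_offset(cm: float, c0: float, cp: float) -> float:
    denom = cm - 2 * c0 + cp
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))


def piv_frame_pair(
    frame_t: np.ndarray,
    frame_t1: np.ndarray,
    cell_mask: np.ndarray,
    cfg: PIVConfig,
    pixel_size_um: float,
    frame_interval_s: float,
    frame_index: int = 0,
) -> SparseFlow:
    """Estimate network displacements between two frames on a regular grid.

    Grid points are source-window centres inside ``cell_mask`` whose
    search window fits in the image.  Displacements are integer-pixel
    argmax shifts of the ZNCC map (optional 3-point parabolic subpixel
    refinement), converted to um/min, and kept only when the peak
    coefficient exceeds ``c0``.
    """
    f0 = np.asarray(frame_t, dtype=float)
    f1 = np.asarray(frame_t1, dtype=float)
    if f0.shape != f1.shape:
        raise FlowError("frames must have the same shape")
    H, W = f0.shape
    src = cfg.source_side_px(pixel_size_um)
    sea = cfg.search_side_px(pixel_size_um)
    if sea > min(H, W):
        raise FlowError("search window larger than the image")
    if not np.asarray(cell_mask, dtype=bool).any():
        raise FlowError("cell mask is empty")
    sh, hh = src // 2, sea // 2
    margin = hh - sh
    stride = cfg.grid_stride_px or src
    to_um_min = pixel_size_um * 60.0 / frame_interval_s

    xs_, ys_, us, vs, cs = [], [], [], [], []
    n_candidates = 0
    for cy in range(hh, H - hh, stride):
        for cx in range(hh, W - hh, stride):
            if not cell_mask[cy, cx]:
                continue
            source = f0[cy - sh : cy + sh + 1, cx - sh : cx + sh + 1]
            n_candidates += 1
            if source.std() == 0:
                continue
            search = f1[cy - hh : cy + hh + 1, cx - hh : cx + hh + 1]
            windows = sliding_window_view(search, (src, src))
            corr = _zncc_stack(source, windows)
            dy, dx, best = _argmax_displacement(corr, margin)
            if not best > cfg.corr_threshold_c0:
                continue
            fdx, fdy = float(dx), float(dy)
            if cfg.subpixel:
                iy, ix = dy + margin, dx + margin
                if 0 < ix < corr.shape[1] - 1 and np.all(np.isfinite(corr[iy, ix - 1 : ix + 2])):
                    fdx += _parabolic_offset(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1])
                if 0 < iy < corr.shape[0] - 1 and np.all(np.isfinite(corr[iy - 1 : iy + 2, ix])):
                    fdy += _parabolic_offset(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix])
            xs_.append(cx)
            ys_.append(cy)
            us.append(fdx * to_um_min)
            vs.append(fdy * to_um_min)
            cs.append(best)
    return SparseFlow(
        x=np.array(xs_, dtype=int),
        y=np.array(ys_, dtype=int),
        u=np.array(us, dtype=float),
        v=np.array(vs, dtype=float),
        corr=np.array(cs, dtype=float),
        n_candidates=n_candidates,
    )


# ---------------------------------------------------------------------------
# dense interpolation and smoothing
# ---------------------------------------------------------------------------


def _truncated_gaussian_kernel(size_px: int, sigma_px: float) -> np.ndarray:
    """Gaussian kernel truncated at the stated size, circular support."""
    r = size_px // 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    k = np.exp(-(xx**2 + yy**2) / (2 * sigma_px**2))
    k[xx**2 + yy**2 > r**2] = 0.0
    return k


def interpolate_dense(
    sparse: SparseFlow,
    cell_mask: np.ndarray,
    cfg: PIVConfig,
    pixel_size_um: float,
    frame_index: int = 0,
) -> FlowField:
    """Spread sparse estimates over the cell outline by Gaussian weighting.

    Every in-mask pixel receives the weighted average of the kept
    estimates within the (truncated) kernel radius, with weights
    renormalized over the estimates actually available; pixels with no
    estimate in range are flagged invalid.  With zero kept estimates the
    whole field is invalid (not an error).
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    shape = cell_mask.shape
    u = np.zeros(shape)
    v = np.zeros(shape)
    w_corr = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    if sparse.n_kept:
        size_px = round_to_odd(cfg.spatial_kernel_size_um / pixel_size_um)
        sigma_px = cfg.spatial_sigma_um / pixel_size_um
        kernel = _truncated_gaussian_kernel(size_px, sigma_px)
        grid_u = np.zeros(shape)
        grid_v = np.zeros(shape)
        grid_c = np.zeros(shape)
        grid_w = np.zeros(shape)
        grid_u[sparse.y, sparse.x] = sparse.u
        grid_v[sparse.y, sparse.x] = sparse.v
        grid_c[sparse.y, sparse.x] = sparse.corr
        grid_w[sparse.y, sparse.x] = 1.0
        num_u = ndimage.convolve(grid_u, kernel, mode="constant")
        num_v = ndimage.convolve(grid_v, kernel, mode="constant")
        num_c = ndimage.convolve(grid_c, kernel, mode="constant")
        den = ndimage.convolve(grid_w, kernel, mode="constant")
        valid = (den > 0) & cell_mask
        u[valid] = num_u[valid] / den[valid]
        v[valid] = num_v[valid] / den[valid]
        w_corr[valid] = num_c[valid] / den[valid]
    return FlowField(u=u, v=v, valid=valid, corr=w_corr, frame_index=frame_index)


def temporal_smooth(
    fields: list[FlowField], cfg: PIVConfig, frame_interval_s: float
) -> list[FlowField]:
    """Per-pixel Gaussian smoothing of a field series over time.

    The kernel spans ``temporal_kernel_s`` (offsets within half the kernel
    length) with ``temporal_sigma_s``; weights are renormalized at the
    series ends and invalid samples are excluded from the weight sum.
    """
    if not fields:
        return []
    half = int(cfg.temporal_kernel_s / 2 / frame_interval_s)
    offsets = np.arange(-half, half + 1)
    weights = np.exp(-((offsets * frame_interval_s) ** 2) / (2 * cfg.temporal_sigma_s**2))
    n = len(fields)
    out = []
    for t in range(n):
        num_u = np.zeros_like(fields[t].u)
        num_v = np.zeros_like(fields[t].v)
        den = np.zeros_like(fields[t].u)
        for off, w in zip(offsets, weights):
            s = t + off
            if not 0 <= s < n:
                continue
            m = fields[s].valid
            num_u[m] += w * fields[s].u[m]
            num_v[m] += w * fields[s].v[m]
            den[m] += w
        valid = den > 0
        u = np.zeros_like(num_u)
        v = np.zeros_like(num_v)
        u[valid] = num_u[valid] / den[valid]
        v[valid] = num_v[valid] / den[valid]
        out.append(
            FlowField(u=u, v=v, valid=valid, corr=fields[t].corr,
                      frame_index=fields[t].frame_index)
        )
    return out


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def divergence(field: FlowField, pixel_size_um: float) -> DivergenceMap:
    """del . V by central differences, in min^-1.

    Defined only where the pixel and all four axis neighbours are valid.
    """
    u, v, m = field.u, field.v, field.valid
    div = np.zeros_like(u)
    valid = np.zeros_like(m)
    valid[1:-1, 1:-1] = (
        m[1:-1, 1:-1]
        & m[1:-1, 2:] & m[1:-1, :-2]
        & m[2:, 1:-1] & m[:-2, 1:-1]
    )
    dudx = np.zeros_like(u)
    dvdy = np.zeros_like(v)
    dudx[1:-1, 1:-1] = (u[1:-1, 2:] - u[1:-1, :-2]) / (2 * pixel_size_um)
    dvdy[1:-1, 1:-1] = (v[2:, 1:-1] - v[:-2, 1:-1]) / (2 * pixel_size_um)
    div[valid] = dudx[valid] + dvdy[valid]
    return DivergenceMap(div=div, valid=valid)


def classify_direction(field: FlowField, motion_vector) -> np.ndarray:
    """Label each valid pixel retrograde (-1) / anterograde (+1) / 0.

    The sign of the cosine between the local flow and the instantaneous
    direction of cell motion decides the label; zero-magnitude flow or an
    exactly perpendicular flow stays unclassified.
    """
    motion = np.asarray(motion_vector, dtype=float)
    if np.linalg.norm(motion) == 0:
        raise FlowError("motion vector must be nonzero")
    dot = field.u * motion[0] + field.v * motion[1]
    labels = np.zeros(field.u.shape, dtype=np.int8)
    labels[field.valid & (dot < 0)] = RETROGRADE
    labels[field.valid & (dot > 0)] = ANTEROGRADE
    return labels


def flow_occurrence(
    fields: list[FlowField],
    region_masks: dict,
    strong_speed_threshold_um_per_min: float,
    frame_interval_s: float | None = None,
) -> dict:
    """Fraction of each region showing strong flow, averaged per minute.

    For every frame and region class, the fraction of region pixels whose
    valid flow speed reaches the threshold is computed; fractions are
    binned into one-minute windows (when the frame interval is given) and
    the per-minute means are averaged.  Empty region classes are absent
    from the result.
    """
    out = {}
    for name, mask in region_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            continue
        fracs = []
        for f in fields:
            strong = f.valid & (f.speed() >= strong_speed_threshold_um_per_min)
            fracs.append(float(strong[mask].sum() / mask.sum()))
        fracs = np.asarray(fracs)
        if frame_interval_s:
            per_min = max(1, int(round(60.0 / frame_interval_s)))
            bins = [fracs[i : i + per_min].mean() for i in range(0, len(fracs), per_min)]
            out[name] = float(np.mean(bins))
        else:
            out[name] = float(fracs.mean())
    return out


def default_strong_threshold(fields: list[FlowField]) -> float:
    """Default 'strong flow' cut-off: half the 95th-percentile speed."""
    speeds = np.concatenate([f.speed()[f.valid] for f in fields if f.valid.any()])
    if speeds.size == 0:
        return 0.0
    return float(0.5 * np.percentile(speeds, 95))


def angle_histogram(
    field: FlowField,
    region_mask: np.ndarray,
    protrusion_axis,
    bins: int = 24,
) -> tuple[np.ndarray, np.ndarray]:
    """Rose histogram of flow directions relative to the protrusion axis.

    Angles are measured in a frame where the protrusion axis maps to 90
    degrees, so flow along the axis (anterograde) lands at 90 deg and
    flow against it (retrograde) at 270 deg.  Zero vectors are excluded.
    Returns (bin_edges_deg, counts).
    """
    axis = np.asarray(protrusion_axis, dtype=float)
    if np.linalg.norm(axis) == 0:
        raise FlowError("protrusion axis must be nonzero")
    m = field.valid & np.asarray(region_mask, dtype=bool)
    u, v = field.u[m], field.v[m]
    nz = (u != 0) | (v != 0)
    u, v = u[nz], v[nz]
    dot = axis[0] * u + axis[1] * v
    cross = axis[0] * v - axis[1] * u
    ang = (90.0 + np.degrees(np.arctan2(cross, dot))) % 360.0
    edges = np.linspace(0.0, 360.0, bins + 1)
    counts, _ = np.histogram(ang, bins=edges)
    return edges, counts


def sink_signal_correlation(
    div_series: list[DivergenceMap],
    second_channel_series: np.ndarray,
    cable_mask: np.ndarray,
) -> tuple[float, int, bool]:
    """Rank correlation between network sinks and a second signal at cables.

    Correlates the per-frame mean negative divergence (-div over valid
    cable pixels) with the per-frame mean second-channel intensity over
    the cable mask, by Spearman rank correlation.  Returns
    (rho, n, defined); a constant series makes the correlation undefined
    and is flagged rather than reported as zero.
    """
    cable_mask = np.asarray(cable_mask, dtype=bool)
    if len(div_series) != len(second_channel_series):
        raise FlowError("series must have the same length")
    if len(div_series) < 3:
        raise FlowError("correlation needs at least 3 time points")
    sinks, signal = [], []
    for dmap, frame in zip(div_series, second_channel_series):
        m = dmap.valid & cable_mask
        sinks.append(float((-dmap.div[m]).mean()) if m.any() else np.nan)
        signal.append(float(np.asarray(frame, dtype=float)[cable_mask].mean()))
    sinks = np.asarray(sinks)
    signal = np.asarray(signal)
    ok = np.isfinite(sinks)
    sinks, signal = sinks[ok], signal[ok]
    if len(sinks) < 3 or np.ptp(sinks) == 0 or np.ptp(signal) == 0:
        return float("nan"), int(len(sinks)), False
    rho, _ = spearmanr(sinks, signal)
    return float(rho), int(len(sinks)), True


def summarize_flow(
    fields: list[FlowField],
    region_masks: dict,
    motion_vector=None,
    protrusion_axis=None,
    strong_speed_threshold_um_per_min: float | None = None,
    frame_interval_s: float | None = None,
    div_series: list[DivergenceMap] | None = None,
) -> FlowSummary:
    """Region-wise flow summary across a field series."""
    thr = (
        strong_speed_threshold_um_per_min
        if strong_speed_threshold_um_per_min is not None
        else default_strong_threshold(fields)
    )
    occurrence = flow_occurrence(fields, region_masks, thr, frame_interval_s)
    mean_speed = {}
    for name, mask in region_masks.items():
        mask = np.asarray(mask, dtype=bool)
        vals = np.concatenate([f.speed()[f.valid & mask] for f in fields])
        if vals.size:
            mean_speed[name] = float(vals.mean())
    retro_antero = {}
    if motion_vector is not None:
        n_valid = retro = antero = 0
        for f in fields:
            labels = classify_direction(f, motion_vector)
            n_valid += int(f.valid.sum())
            retro += int((labels == RETROGRADE).sum())
            antero += int((labels == ANTEROGRADE).sum())
        if n_valid:
            retro_antero = {
                "retrograde": retro / n_valid,
                "anterograde": antero / n_valid,
            }
    angle_hist = None
    if protrusion_axis is not None and region_masks:
        mask = next(iter(region_masks.values()))
        total = None
        edges = None
        for f in fields:
            edges, counts = angle_histogram(f, mask, protrusion_axis)
            total = counts if total is None else total + counts
        angle_hist = {"bin_edges_deg": edges.tolist(), "counts": total.tolist()}
    div_stats = {}
    if div_series:
        vals = np.concatenate([d.div[d.valid] for d in div_series])
        if vals.size:
            div_stats = {
                "mean": float(vals.mean()),
                "min": float(vals.min()),
                "negative_fraction": float((vals < 0).mean()),
            }
    return FlowSummary(
        occurrence=occurrence,
        mean_speed=mean_speed,
        retro_antero=retro_antero,
        angle_hist=angle_hist,
        divergence_stats=div_stats,
        strong_speed_threshold_um_per_min=thr,
    )


def analyze_stack(
    frames: np.ndarray,
    cell_mask: np.ndarray,
    cfg: PIVConfig,
    pixel_size_um: float,
    frame_interval_s: float,
    temporal: bool = True,
) -> list[FlowField]:
    """PIV + dense interpolation (+ temporal smoothing) over a movie."""
    fields = []
    for t in range(len(frames) - 1):
        sparse = piv_frame_pair(
            frames[t], frames[t + 1], cell_mask, cfg, pixel_size_um,
            frame_interval_s, frame_index=t,
        )
        fields.append(interpolate_dense(sparse, cell_mask, cfg, pixel_size_um, t))
    if temporal and len(fields) > 1:
        fields = temporal_smooth(fields, cfg, frame_interval_s)
    return fields
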