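"""Group-level morphometrics, photobleaching correction and classification.

A border-cell group is summarised by a handful of scalars — the fraction
of its area held in protrusions, the discontinuity of its peripheral
actin cable, the protrusion count, total area and migration speed — and
assigned to one of three morphology categories:

* **tight**: protrusion area fraction < 10% and cable discontinuity <= 8%,
* **loose**: protrusion area fraction > 25% and cable discontinuity >= 25%,
* **balanced**: 10-25% protrusion area and 8% < discontinuity < 25%.

Combinations outside these bands (e.g. low protrusion fraction with a
badly broken cable) are reported as ``unclassified`` rather than being
forced into the nearest category.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .segmentation import RegionSet, TimelapseStack


class MetricsError(ValueError):
    pass


@dataclass
class ClassifierConfig:
    """Category boundaries on the (protrusion fraction, discontinuity) plane.

    Bound inclusivity follows the printed definitions exactly: tight is
    strict on the fraction and inclusive on the discontinuity; loose is
    strict on the fraction and inclusive on the discontinuity.
    """

    tight_max_protrusion_frac: float = 0.10  # exclusive
    tight_max_discontinuity: float = 0.08  # inclusive
    loose_min_protrusion_frac: float = 0.25  # exclusive
    loose_min_discontinuity: float = 0.25  # inclusive

    def __post_init__(self) -> None:
        if not (
            self.tight_max_protrusion_frac < self.loose_min_protrusion_frac
            and self.tight_max_discontinuity < self.loose_min_discontinuity
        ):
            raise ValueError("tight bounds must lie below loose bounds on both axes")


@dataclass
class GroupMetrics:
    protrusion_area_fraction: float
    cable_discontinuity: float
    protrusion_count: int
    total_area_um2: float
    speed_um_per_min: float
    category: str = "unclassified"
    per_region_intensity: dict = field(default_factory=dict)
    per_position_intensity: dict = field(default_factory=dict)


@dataclass
class RegionIntensity:
    """Mean, summed and group-mean-relative intensity per region class."""

    mean: dict
    total: dict
    relative: dict


@dataclass
class BleachFit:
    """Monoexponential photobleaching fit of the frame-mean series."""

    tau_s: float | None
    amplitude: float | None
    corrected: bool


# ---------------------------------------------------------------------------


def region_mean_intensity(frame: np.ndarray, regions: RegionSet) -> RegionIntensity:
    """Per-region intensity read-outs from a background-subtracted frame.

    ``relative`` divides each class mean by the mean intensity over the
    whole group mask, making values comparable across frames.  Empty
    region classes are reported as ``None``, never as zero.
    """
    frame = np.asarray(frame, dtype=float)
    masks = {
        "contacts": regions.contact_mask(),
        "cables": regions.cable_mask(),
        "protrusions": regions.protrusion_mask,
    }
    group_mean = float(frame[regions.group_mask].mean())
    mean, total, relative = {}, {}, {}
    for name, mask in masks.items():
        if not mask.any():
            mean[name] = total[name] = relative[name] = None
            continue
        vals = frame[mask]
        mean[name] = float(vals.mean())
        total[name] = float(vals.sum())
        relative[name] = float(vals.mean() / group_mean) if group_mean > 0 else None
    return RegionIntensity(mean=mean, total=total, relative=relative)


def cable_periphery_ratio(intensity: RegionIntensity) -> float:
    """Cable share of the total peripheral (cable + protrusion) signal.

    Uses summed, not mean, intensities.
    """
    cable = intensity.total.get("cables") or 0.0
    prot = intensity.total.get("protrusions") or 0.0
    if cable + prot == 0:
        raise MetricsError("cable and protrusion totals are both zero")
    return cable / (cable + prot)


def cable_discontinuity(regions: RegionSet) -> float:
    """Broken-rim length over total rim length (cables + broken sections)."""
    broken = sum(s.length_um for s in regions.cable_segments if not s.intact)
    total = sum(s.length_um for s in regions.cable_segments)
    if total == 0:
        raise MetricsError("cable segments have zero total length")
    return broken / total


def morphology_summary(regions: RegionSet, pixel_size_um: float | None = None):
    """Protrusion area fraction, protrusion count and total area (um^2)."""
    ps = pixel_size_um if pixel_size_um is not None else regions.pixel_size_um
    body_px = int(regions.body_mask.sum())
    prot_px = int(regions.protrusion_mask.sum())
    fraction = prot_px / (body_px + prot_px)
    return fraction, len(regions.protrusion_ids), (body_px + prot_px) * ps**2


def migration_speed(centroids_um: np.ndarray, frame_interval_s: float) -> float:
    """Mean migration speed from the first and third time points (um/min)."""
    centroids_um = np.asarray(centroids_um, dtype=float)
    if len(centroids_um) < 3:
        raise MetricsError("migration speed needs at least 3 time points")
    dist = float(np.linalg.norm(centroids_um[2] - centroids_um[0]))
    return dist / (2 * frame_interval_s) * 60.0


def migration_speed_series(
    centroids_um: np.ndarray, frame_interval_s: float
) -> np.ndarray:
    """Sliding-window (stride 1) variant of the first-to-third-frame rule."""
    centroids_um = np.asarray(centroids_um, dtype=float)
    if len(centroids_um) < 3:
        raise MetricsError("migration speed needs at least 3 time points")
    d = np.linalg.norm(centroids_um[2:] - centroids_um[:-2], axis=1)
    return d / (2 * frame_interval_s) * 60.0


def classify_group(
    protrusion_area_fraction: float,
    cable_discontinuity: float,
    cfg: ClassifierConfig | None = None,
) -> str:
    """Assign tight / loose / balanced / unclassified from the two axes."""
    cfg = cfg or ClassifierConfig()
    f, d = protrusion_area_fraction, cable_discontinuity
    if not (0 <= f <= 1 and 0 <= d <= 1):
        raise MetricsError("fractions must lie in [0, 1]")
    if f < cfg.tight_max_protrusion_frac and d <= cfg.tight_max_discontinuity:
        return "tight"
    if f > cfg.loose_min_protrusion_frac and d >= cfg.loose_min_discontinuity:
        return "loose"
    if (
        cfg.tight_max_protrusion_frac <= f <= cfg.loose_min_protrusion_frac
        and cfg.tight_max_discontinuity < d < cfg.loose_min_discontinuity
    ):
        return "balanced"
    return "unclassified"


def bleach_correct(stack: TimelapseStack) -> tuple[TimelapseStack, list[BleachFit]]:
    """Correct photobleaching by a monoexponential fit of frame means.

    For each channel the frame-mean series is fitted to A*exp(-t/tau) by
    least squares on the log means; each frame is divided by its fitted
    decay relative to frame 0.  A channel whose fit shows no decay
    (tau <= 0, i.e. brightening) is returned unchanged and flagged.
    """
    if stack.n_frames < 3:
        raise MetricsError("bleach correction needs at least 3 frames")
    t = np.arange(stack.n_frames) * stack.frame_interval_s
    frames = stack.frames.copy()
    fits: list[BleachFit] = []
    for c in range(frames.shape[1]):
        means = frames[:, c].mean(axis=(1, 2))
        if np.any(means <= 0):
            raise MetricsError("nonpositive frame means; subtract background first")
        slope, intercept = np.polyfit(t, np.log(means), 1)
        if slope >= -1e-12:  # flat or brightening: nothing to correct
            fits.append(BleachFit(tau_s=None, amplitude=None, corrected=False))
            continue
        tau = -1.0 / slope
        decay = np.exp(-t / tau)
        frames[:, c] /= (decay / decay[0])[:, None, None]
        fits.append(
            BleachFit(tau_s=float(tau), amplitude=float(np.exp(intercept)), corrected=True)
        )
    corrected = replace(stack, frames=frames)
    return corrected, fits


def assign_cell_positions(
    cell_centroids: np.ndarray, motion_direction: np.ndarray
) -> list[str]:
    """Label cells front / middle / rear along the direction of motion.

    Centroids are projected onto the motion axis and split into terciles
    of the projected coordinate (front = highest third).  With fewer than
    three cells the extremes are used: the maximum projection is front,
    the minimum rear; a single cell is front.
    """
    cell_centroids = np.asarray(cell_centroids, dtype=float)
    motion = np.asarray(motion_direction, dtype=float)
    if np.linalg.norm(motion) == 0:
        raise MetricsError("motion direction must be nonzero")
    if len(cell_centroids) == 0:
        raise MetricsError("need at least one cell")
    proj = cell_centroids @ (motion / np.linalg.norm(motion))
    n = len(proj)
    if n == 1:
        return ["front"]
    if n == 2:
        return ["front" if p == proj.max() else "rear" for p in proj]
    order = np.argsort(proj, kind="stable")  # ascending: rear first
    labels = [""] * n
    groups = np.array_split(order, 3)
    for name, idx in zip(("rear", "middle", "front"), groups):
        for i in idx:
            labels[i] = name
    return labels


def intensity_centroid_um(frame: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Intensity-weighted centroid of a background-subtracted frame, in um.

    Weighting by intensity keeps the centre estimate subpixel-accurate
    when the group drifts by fractions of a pixel between frames.
    """
    frame = np.asarray(frame, dtype=float)
    total = frame.sum()
    if total <= 0:
        raise MetricsError("frame has no signal; cannot locate group centre")
    ys, xs = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
    cx = float((xs * frame).sum() / total)
    cy = float((ys * frame).sum() / total)
    return np.array([cx, cy]) * pixel_size_um


def centroid_series_um(
    stack: TimelapseStack, channel: int = 0, halo_um: float = 2.0
) -> np.ndarray:
    """Per-frame group centres (um) from intensity-weighted centroids.

    Each frame is background-subtracted, the group is segmented, and the
    centroid is taken over the mask dilated by ``halo_um`` so that no
    signal is cut off at the edge while camera noise far from the group
    cannot bias the centre.
    """
    from scipy import ndimage

    from .segmentation import segment_group, subtract_background

    halo_px = max(1, int(round(halo_um / stack.pixel_size_um)))
    out = []
    for t in range(stack.n_frames):
        frame = subtract_background(stack.frames[t, channel])
        mask = ndimage.binary_dilation(segment_group(frame), iterations=halo_px)
        out.append(intensity_centroid_um(np.where(mask, frame, 0.0), stack.pixel_size_um))
    return np.array(out)


def compute_group_metrics(
    frame: np.ndarray,
    regions: RegionSet,
    centroids_um: np.ndarray | None = None,
    frame_interval_s: float | None = None,
    cfg: ClassifierConfig | None = None,
) -> GroupMetrics:
    """Assemble the scalar morphometrics and category for one frame."""
    frac, count, area = morphology_summary(regions)
    disc = cable_discontinuity(regions)
    speed = 0.0
    if centroids_um is not None and frame_interval_s is not None:
        speed = migration_speed(centroids_um, frame_interval_s)
    intensity = region_mean_intensity(frame, regions)
    return GroupMetrics(
        protrusion_area_fraction=frac,
        cable_discontinuity=disc,
        protrusion_count=count,
        total_area_um2=area,
        speed_um_per_min=speed,
        category=classify_group(frac, disc, cfg),
        per_region_intensity=intensity.relative,
    )
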