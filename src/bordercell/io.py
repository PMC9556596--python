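"""File formats, configuration and run manifests.

Movies travel as multi-page 16-bit TIFFs (one file per channel), regions
and ground truth as JSON (binary masks run-length encoded, polylines as
ordered ``[x, y]`` pixel lists, 0-based, x rightward, y downward),
metrics as CSV, dense flow fields as 4-plane 32-bit float TIFFs
(u, v, valid, corr) with a JSON sidecar, and every run ends with a
manifest listing each artefact with its SHA-256 content hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import synthetic as _synthetic
from .flow import FlowField, PIVConfig
from .metrics import ClassifierConfig, GroupMetrics
from .segmentation import CableSegment, Contact, Landmarks, RegionSet, TimelapseStack

COORD_NOTE = "0-based pixel coordinates, x rightward, y downward"

METRICS_COLUMNS = [
    "movie_id",
    "frame",
    "protrusion_area_fraction",
    "cable_discontinuity",
    "protrusion_count",
    "total_area_um2",
    "speed_um_per_min",
    "category",
    "intensity_contacts",
    "intensity_cables",
    "intensity_protrusions",
]


class IOError_(ValueError):
    pass


# ---------------------------------------------------------------------------
# run-length encoding for binary masks
# ---------------------------------------------------------------------------


def rle_encode(mask: np.ndarray) -> dict:
    """Run-length encode a binary mask (row-major, starting with a 0-run)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return {"shape": list(mask.shape), "runs": []}
    changes = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    bounds = np.concatenate([[0], changes, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0]:
        runs = [0] + runs
    return {"shape": list(mask.shape), "runs": runs}


def rle_decode(d: dict) -> np.ndarray:
    shape = tuple(d["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for run in d["runs"]:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    return flat.reshape(shape)


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------


def write_stack(stack: TimelapseStack, path, channel: int = 0) -> Path:
    """Write one channel as a multi-page 16-bit TIFF."""
    path = Path(path)
    data = np.clip(np.round(stack.frames[:, channel]), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        resolution=(1.0 / stack.pixel_size_um, 1.0 / stack.pixel_size_um),
        metadata={
            "pixel_size_um": stack.pixel_size_um,
            "frame_interval_s": stack.frame_interval_s,
        },
    )
    return path


def read_stack(
    path,
    pixel_size_um: float,
    frame_interval_s: float,
    channel_names: list[str] | None = None,
) -> TimelapseStack:
    """Read a multi-page TIFF as a calibrated stack.

    Calibration comes from the arguments (configuration is authoritative;
    TIFF resolution tags are advisory and a disagreement is logged).
    """
    import logging

    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = {p.shape for p in tif.pages}
            if len(shapes) > 1:
                raise IOError_(f"{path}: inconsistent page shapes {sorted(shapes)}")
            data = tif.asarray()
            page = tif.pages[0]
            xres = page.tags.get("XResolution")
            if xres is not None:
                num, den = xres.value
                if num:
                    tag_ps = den / num
                    if abs(tag_ps - pixel_size_um) / pixel_size_um > 1e-3:
                        logging.getLogger(__name__).warning(
                            "%s: TIFF resolution tag implies %.4g um/px, config says "
                            "%.4g um/px; using the config value",
                            path, tag_ps, pixel_size_um,
                        )
    except IOError_:
        raise
    except Exception as exc:  # unreadable / malformed file
        raise IOError_(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    return TimelapseStack(
        frames=data.astype(float),
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        channel_names=channel_names or ["actin"],
    )


# ---------------------------------------------------------------------------
# regions / landmarks / ground truth JSON
# ---------------------------------------------------------------------------


def _segment_to_json(s: CableSegment) -> dict:
    return {
        "cell_index": s.cell_index,
        "polyline": np.asarray(s.polyline).tolist(),
        "intact": bool(s.intact),
        "length_um": s.length_um,
        "mean_intensity": s.mean_intensity,
    }


def region_set_to_json(rs: RegionSet) -> dict:
    return {
        "coordinates": COORD_NOTE,
        "body_mask": rle_encode(rs.body_mask),
        "protrusions": {
            str(i): rle_encode(rs.protrusion_labels == i) for i in rs.protrusion_ids
        },
        "cable_segments": [_segment_to_json(s) for s in rs.cable_segments],
        "contacts": [
            {
                "polyline": np.asarray(c.polyline).tolist(),
                "mask": rle_encode(c.mask),
                "mean_intensity": c.mean_intensity,
                "area_um2": c.area_um2,
            }
            for c in rs.contacts
        ],
        "cell_count": rs.cell_count,
        "pixel_size_um": rs.pixel_size_um,
    }


def region_set_from_json(d: dict) -> RegionSet:
    body = rle_decode(d["body_mask"])
    labels = np.zeros_like(body, dtype=int)
    for k, rle in d["protrusions"].items():
        labels[rle_decode(rle)] = int(k)
    segments = [
        CableSegment(
            cell_index=s["cell_index"],
            polyline=np.asarray(s["polyline"], dtype=int),
            intact=s["intact"],
            length_um=s["length_um"],
            mean_intensity=s["mean_intensity"],
        )
        for s in d["cable_segments"]
    ]
    contacts = [
        Contact(
            polyline=np.asarray(c["polyline"], dtype=int),
            mask=rle_decode(c["mask"]),
            mean_intensity=c["mean_intensity"],
            area_um2=c["area_um2"],
        )
        for c in d["contacts"]
    ]
    return RegionSet(
        body_mask=body,
        protrusion_labels=labels,
        cable_segments=segments,
        contacts=contacts,
        cell_count=d["cell_count"],
        pixel_size_um=d["pixel_size_um"],
    )


def landmarks_to_json(lm: Landmarks) -> dict:
    return {
        "coordinates": COORD_NOTE,
        "boundary_points": np.asarray(lm.boundary_points).tolist(),
        "contacts": [[list(a), list(b)] for a, b in lm.contact_endpoints],
    }


def landmarks_from_json(d: dict) -> Landmarks:
    return Landmarks(
        boundary_points=np.asarray(d["boundary_points"], dtype=int),
        contact_endpoints=[
            (tuple(int(v) for v in a), tuple(int(v) for v in b))
            for a, b in d.get("contacts", [])
        ],
    )


def read_landmarks(path) -> Landmarks:
    with open(path) as fh:
        return landmarks_from_json(json.load(fh))


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# flow fields
# ---------------------------------------------------------------------------


def write_flow(field: FlowField, path, cfg: PIVConfig | None = None) -> Path:
    """4-plane float32 TIFF (u, v, valid, corr) + JSON sidecar."""
    path = Path(path)
    corr = field.corr if field.corr is not None else np.zeros_like(field.u)
    planes = np.stack(
        [field.u, field.v, field.valid.astype(float), corr]
    ).astype(np.float32)
    tifffile.imwrite(path, planes, photometric="minisblack")
    sidecar = {
        "planes": ["u_um_per_min", "v_um_per_min", "valid", "corr"],
        "frame_index": field.frame_index,
        "coordinates": COORD_NOTE,
    }
    if cfg is not None:
        sidecar["piv_config"] = dataclasses.asdict(cfg)
    write_json(sidecar, path.with_suffix(".json"))
    return path


def read_flow(path) -> FlowField:
    planes = tifffile.imread(path).astype(float)
    sidecar = json.loads(Path(path).with_suffix(".json").read_text())
    return FlowField(
        u=planes[0],
        v=planes[1],
        valid=planes[2] > 0.5,
        corr=planes[3],
        frame_index=sidecar.get("frame_index", 0),
    )


# ---------------------------------------------------------------------------
# metrics CSV
# ---------------------------------------------------------------------------


def metrics_to_frame(rows: list[tuple[str, int, GroupMetrics]]) -> pd.DataFrame:
    """Rows of (movie_id, frame, GroupMetrics) -> canonical metrics table."""
    records = []
    for movie_id, frame, m in rows:
        rel = m.per_region_intensity or {}
        records.append(
            {
                "movie_id": movie_id,
                "frame": frame,
                "protrusion_area_fraction": m.protrusion_area_fraction,
                "cable_discontinuity": m.cable_discontinuity,
                "protrusion_count": m.protrusion_count,
                "total_area_um2": m.total_area_um2,
                "speed_um_per_min": m.speed_um_per_min,
                "category": m.category,
                "intensity_contacts": rel.get("contacts"),
                "intensity_cables": rel.get("cables"),
                "intensity_protrusions": rel.get("protrusions"),
            }
        )
    return pd.DataFrame.from_records(records, columns=METRICS_COLUMNS)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SegmentationConfig:
    opening_radius_um: float = 2.0
    min_protrusion_area_um2: float = 5.0
    cable_intensity_threshold: float = 1.1
    snap_px: float = 3.0
    contact_half_width_px: int = 2


@dataclass
class RunConfig:
    """Full pipeline configuration; unknown YAML keys are rejected."""

    input_tiff: str | None = None
    landmarks_json: str | None = None
    output_dir: str = "bordercell_out"
    pixel_size_um: float = 0.2
    frame_interval_s: float = 10.0
    piv: PIVConfig = field(default_factory=PIVConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    seed: int = 0
    log_level: str = "INFO"


_SUBCONFIGS = {
    "piv": PIVConfig,
    "classifier": ClassifierConfig,
    "segmentation": SegmentationConfig,
}


def _from_mapping(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise IOError_(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        if isinstance(value, dict) and name in _SUBCONFIGS:
            kwargs[name] = _from_mapping(_SUBCONFIGS[name], value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_mapping(RunConfig, data)


def save_config(cfg: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# manifests and run outputs
# ---------------------------------------------------------------------------


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_outputs(
    metrics_rows,
    flows: list[FlowField],
    regions: RegionSet | None,
    out_dir,
    piv_cfg: PIVConfig | None = None,
) -> dict:
    """Write CSV/TIFF/JSON artefacts plus a hash manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    csv_path = out_dir / "metrics.csv"
    metrics_to_frame(metrics_rows).to_csv(csv_path, index=False)
    written.append(csv_path)
    if regions is not None:
        written.append(write_json(region_set_to_json(regions), out_dir / "regions.json"))
    for f in flows:
        written.append(write_flow(f, out_dir / f"flow_{f.frame_index:04d}.tif", piv_cfg))
        written.append((out_dir / f"flow_{f.frame_index:04d}.json"))
    manifest = {
        "coordinates": COORD_NOTE,
        "files": {p.name: sha256_file(p) for p in written},
    }
    write_json(manifest, out_dir / "manifest.json")
    return manifest


def write_fixture_suite(out_dir, specs: dict, seed: int = 0) -> dict:
    """Render and write every fixture spec with its ground truth."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError_(f"cannot create fixture directory {out_dir}: {exc}") from exc
    manifest = {"seed": seed, "coordinates": COORD_NOTE, "fixtures": {}}
    for name, spec in specs.items():
        stack, truth = _synthetic.generate(spec)
        entry = {"spec": _synthetic.spec_to_dict(spec), "files": {}}
        for c, cname in enumerate(stack.channel_names):
            p = write_stack(stack, out_dir / f"{name}_{cname}.tif", channel=c)
            entry["files"][cname] = p.name
        gt = {
            "coordinates": COORD_NOTE,
            "region_set": region_set_to_json(truth.region_set),
            "landmarks": landmarks_to_json(truth.landmarks),
            "centroid_series_um": np.asarray(truth.centroid_series).tolist(),
            "bleach_curve": np.asarray(truth.bleach_curve).tolist(),
            "centre_px": list(truth.centre_px),
            "protrusion_axes": [list(a) for a in truth.protrusion_axes],
            "true_metrics": dataclasses.asdict(truth.true_metrics),
        }
        gt_path = write_json(gt, out_dir / f"{name}_truth.json")
        entry["files"]["ground_truth"] = gt_path.name
        manifest["fixtures"][name] = entry
    write_json(manifest, out_dir / "manifest.json")
    return manifest


def read_fixture_truth(out_dir, name: str):
    """Reload a fixture's ground truth (flows regenerated from the spec)."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    entry = manifest["fixtures"][name]
    spec = _synthetic.spec_from_dict(entry["spec"])
    gt = json.loads((out_dir / entry["files"]["ground_truth"]).read_text())
    truth = _synthetic.build_geometry(spec)
    truth.flow_series = _synthetic.ground_truth_flow(spec, truth)
    return spec, truth, gt
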