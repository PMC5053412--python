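"""End-to-end orchestration and file I/O.

``process_image`` runs preprocess -> segment -> skeletonize -> split ->
prune -> area threshold -> region features for one annotated image;
``run_pipeline`` maps it over a cohort and hands the feature table to the
classifier.  Everything is deterministic given the inputs and the config,
so reruns are bit-reproducible.

On disk, an image is a PNG/TIFF/JPEG with a JSON sidecar
``{"od_endpoints": [[r, c], [r, c]], "label": "healthy"}`` (label
optional); a cohort directory additionally carries a ``manifest.csv``
with (path, label, seed) rows.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import classify as _classify
from . import features as _features
from . import segmentation as _segmentation
from . import skeleton as _skeleton
from .config import RunConfig
from .errors import RopscreenError
from .phantom import generate_cohort
from .preprocess import (FundusImage, ODGeometry, compute_eye_mask,
                         compute_od_mask, select_channel)

logger = logging.getLogger(__name__)

__all__ = [
    "RunRecord",
    "load_image",
    "load_annotation",
    "save_image",
    "write_cohort",
    "process_image",
    "run_pipeline",
    "run_directory",
]


@dataclass
class RunRecord:
    """Audit record: config snapshot, per-stage outcomes, warnings."""

    config: dict
    images: list[dict] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)
    started: float = field(default_factory=time.time)

    def as_dict(self) -> dict:
        return {"config": self.config, "images": self.images,
                "skipped": self.skipped,
                "elapsed_s": round(time.time() - self.started, 3)}


# ---------------------------------------------------------------------------
# file I/O

def load_image(path: str | Path) -> FundusImage:
    """Read a PNG/TIFF/JPEG fundus image as 8-bit RGB."""
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    return FundusImage(pixels=arr, id=path.stem, path=str(path))


def save_image(pixels: np.ndarray, path: str | Path) -> None:
    """Write an RGB raster or a boolean mask as PNG."""
    arr = np.asarray(pixels)
    if arr.dtype == bool:
        arr = (arr * 255).astype(np.uint8)
    Image.fromarray(arr).save(str(path))


def load_annotation(path: str | Path) -> tuple[ODGeometry, str | None]:
    """Read the OD-endpoint sidecar; returns (geometry, optional label)."""
    with open(path) as fh:
        data = json.load(fh)
    (a, b) = data["od_endpoints"]
    return ODGeometry(endpoint_a=tuple(a), endpoint_b=tuple(b)), data.get("label")


def write_cohort(outdir: str | Path, n_healthy: int, n_aprop: int,
                 preset_overrides: dict | None = None, seed: int = 0,
                 image_size: int = 640) -> pd.DataFrame:
    """Generate a phantom cohort and persist it (PNG + sidecar + manifest).

    Each truth sidecar stores the OD endpoints, the class label, and the
    analytic centerlines as coordinate lists.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for img, truth in generate_cohort(n_healthy, n_aprop, preset_overrides,
                                      seed=seed, image_size=image_size):
        png = outdir / f"{img.id}.png"
        save_image(img.pixels, png)
        sidecar = {
            "od_endpoints": [list(truth.od_geometry.endpoint_a),
                             list(truth.od_geometry.endpoint_b)],
            "label": truth.label,
            "centerlines": [pl.tolist() for pl in truth.centerlines],
            "true_tortuosity": truth.tortuosity,
        }
        with open(png.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh)
        rows.append({"path": str(png), "label": truth.label,
                     "seed": truth.params.seed if truth.params else None})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# per-image pipeline

def process_image(image: FundusImage, od: ODGeometry,
                  config: RunConfig | None = None,
                  label: str | None = None) -> dict:
    """Run one image through segmentation and feature extraction.

    Returns a dict with the per-region features, the intermediate rasters
    (eye/OD masks, network, skeleton) and the thresholds chosen, so any
    audit overlay can be regenerated from it.
    """
    cfg = config or RunConfig()
    eye_mask = compute_eye_mask(image, margin=cfg.eye_margin)
    od_mask = compute_od_mask(od, image.shape)
    channel = select_channel(image, eye_mask, mean_cutoff=cfg.mean_cutoff)

    kwargs: dict = {"od_halo": cfg.od_halo}
    if cfg.method == "morphology":
        kwargs["blur_length"] = cfg.blur_length
    elif cfg.method == "matched_filter":
        kwargs["bank"] = _segmentation.build_kernel_bank(cfg.sigma,
                                                         cfg.kernel_length)
    else:
        kwargs["island_min"] = cfg.island_min
    network = _segmentation.segment(channel, eye_mask, od_mask,
                                    method=cfg.method, **kwargs)

    skel = _skeleton.skeletonize(network)
    segset = _skeleton.split_segments(skel, source_method=cfg.method)
    skel, segset = _skeleton.prune(skel, segset, spur_len=cfg.spur_len,
                                   passes=cfg.prune_passes)
    if cfg.apply_area_threshold:
        segset = _skeleton.area_threshold(segset, cfg.area_min)

    feats = _features.compute_region_features(
        segset, od, eye_mask, od_mask, image_id=image.id, label=label,
        mode=cfg.tortuosity_mode, loop_cap=cfg.loop_cap,
        percentile=cfg.percentile)
    return {
        "features": feats,
        "eye_mask": eye_mask,
        "od_mask": od_mask,
        "channel": channel,
        "network": network,
        "skeleton": skel,
        "segments": segset,
        "threshold": network.threshold_used,
    }


def run_pipeline(items: list[tuple[FundusImage, ODGeometry, str | None]],
                 config: RunConfig | None = None,
                 classify: bool = True) -> tuple[pd.DataFrame, dict | None, RunRecord]:
    """Process a cohort end to end.

    Parameters
    ----------
    items : list of (image, od_geometry, label)
        ``od_geometry`` may be None, in which case the image is skipped
        with a listed reason (annotations are mandatory).
    config : RunConfig
    classify : bool
        Fit/evaluate the two-region LOOCV classifier (needs labels and
        at least one image per class).

    Returns
    -------
    (feature table, classification report or None, run record)
    """
    cfg = config or RunConfig()
    record = RunRecord(config=cfg.to_dict())
    all_feats: list[_features.FeatureVector] = []
    for image, od, label in items:
        if od is None:
            record.skipped.append({"image_id": image.id,
                                   "reason": "missing OD annotation"})
            continue
        t0 = time.time()
        try:
            result = process_image(image, od, cfg, label=label)
        except RopscreenError as exc:
            record.skipped.append({"image_id": image.id, "reason": str(exc)})
            logger.warning("skipping %s: %s", image.id, exc)
            continue
        all_feats.extend(result["features"])
        record.images.append({
            "image_id": image.id,
            "label": label,
            "threshold": _jsonable(result["threshold"]),
            "n_segments": len(result["segments"]),
            "elapsed_s": round(time.time() - t0, 3),
        })

    table = _features.features_to_frame(all_feats)
    report = None
    if classify and len(table):
        labels = table["label"].dropna().unique()
        if len(labels) >= 2:
            report = _classify.classify_cohort(table)
            report["n_skipped"] = len(record.skipped)
        else:
            logger.warning("classification skipped: need two labelled classes")
    return table, report, record


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, tuple):
        return [None if (isinstance(v, float) and np.isnan(v)) else _jsonable(v)
                for v in x]
    return x


def run_directory(indir: str | Path, config: RunConfig | None = None,
                  outdir: str | Path | None = None
                  ) -> tuple[pd.DataFrame, dict | None, RunRecord]:
    """Run the pipeline over every annotated image in a directory.

    Images without a ``<stem>.json`` sidecar are skipped with a reason.
    If the directory holds a ``manifest.csv`` its row order defines the
    cohort order (so a written cohort reproduces the in-memory run
    exactly); otherwise files are taken alphabetically.  When ``outdir``
    is given, writes ``features.csv`` (schema-versioned header),
    ``report.json`` and ``runrecord.json``.
    """
    indir = Path(indir)
    items: list[tuple[FundusImage, ODGeometry | None, str | None]] = []
    exts = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
    manifest = indir / "manifest.csv"
    if manifest.exists():
        paths = []
        for p in pd.read_csv(manifest)["path"]:
            p = Path(p)
            paths.append(p if p.exists() else indir / p.name)
    else:
        paths = sorted(indir.iterdir())
    for path in paths:
        if path.suffix.lower() not in exts:
            continue
        image = load_image(path)
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            od, label = load_annotation(sidecar)
            items.append((image, od, label))
        else:
            items.append((image, None, None))
    table, report, record = run_pipeline(items, config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "features.csv", "w", newline="") as fh:
            fh.write(f"# ropscreen-features v{_features.FEATURE_SCHEMA_VERSION}\n")
            table.to_csv(fh, index=False)
        if report is not None:
            with open(outdir / "report.json", "w") as fh:
                json.dump(report, fh, indent=2)
        with open(outdir / "runrecord.json", "w") as fh:
            json.dump(record.as_dict(), fh, indent=2)
    return table, report, record
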