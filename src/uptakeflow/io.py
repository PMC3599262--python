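"""TIFF/CSV/JSON input-output, run configuration and the pipeline driver.

Events travel as multi-page TIFF (one page per channel) with channel names
and pixel size in a JSON image description; ground truth, when present, goes
to a JSON sidecar and a cohort manifest CSV.  The pipeline driver chains
segmentation, erosion, feature extraction and population summary and writes
a machine-readable run manifest carrying the configuration hash, so outputs
are traceable and reruns with the same configuration are byte-identical.
Proprietary imaging-flow-cytometer container formats (.rif/.cif) are not
read; export events to TIFF first.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .errors import ValidationError
from .features import extract_features
from .population import summarize_population
from .segmask import MaskParams, MaskPair, compute_masks
from .simgen import CellEvent, GroundTruth

logger = logging.getLogger("uptakeflow")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run; round-trips losslessly via JSON."""

    channel_map: dict[str, int] = field(
        default_factory=lambda: {"brightfield": 0, "probe": 1}
    )
    pixel_size_um: float = 0.5
    mask_params: MaskParams = field(default_factory=MaskParams)
    epsilon: float = 1.0
    statistic: str = "mean"
    background: str = "none"
    seed: int = 0
    output_dir: str = "out"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        if "brightfield" not in self.channel_map:
            raise ValidationError("channel_map must map 'brightfield'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "mask_params" in d and isinstance(d["mask_params"], dict):
            d["mask_params"] = MaskParams(**d["mask_params"])
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))

    @property
    def config_hash(self) -> str:
        # output_dir does not affect the computation, so it is not hashed:
        # runs into different directories with the same analysis settings
        # share a hash and produce identical tables.
        d = self.to_dict()
        d.pop("output_dir")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


def write_event(event: CellEvent, path: str | Path, with_truth: bool = True) -> Path:
    """Write one event as a multi-page TIFF plus an optional truth sidecar.

    Page order: brightfield, fluorescence channels in insertion order, then
    scatter if present.  Channel names and pixel size are stored as JSON in
    the TIFF description.
    """
    path = Path(path)
    names = ["brightfield"] + list(event.fluorescence)
    pages = [event.brightfield] + [event.fluorescence[c] for c in event.fluorescence]
    if event.scatter is not None:
        names.append("scatter")
        pages.append(event.scatter)
    meta = {
        "channels": names,
        "pixel_size_um": event.pixel_size_um,
        "event_id": event.event_id,
    }
    # dtype preserved so a write/read round trip is bit-identical
    stack = np.stack([np.asarray(p) for p in pages])
    tifffile.imwrite(
        path, stack, photometric="minisblack", description=json.dumps(meta)
    )
    if with_truth and event.truth is not None:
        sidecar = path.with_suffix(".truth.json")
        sidecar.write_text(
            json.dumps(
                {
                    "internal_fraction_true": event.truth.internal_fraction_true,
                    "total_probe_true": event.truth.total_probe_true,
                },
                indent=2,
            )
        )
    return path


def write_cohort(
    events: Sequence[CellEvent], out_dir: str | Path, with_truth: bool = True
) -> Path:
    """Write a cohort of events plus a manifest CSV (event_id, file, truth)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for event in events:
        fname = f"{event.event_id}.tif"
        write_event(event, out_dir / fname, with_truth=with_truth)
        row = {"event_id": event.event_id, "file": fname}
        if event.truth is not None:
            row["internal_fraction_true"] = event.truth.internal_fraction_true
            row["total_probe_true"] = event.truth.total_probe_true
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_event(path: str | Path, config: RunConfig) -> CellEvent:
    """Read an event TIFF, mapping pages to channels per the configuration.

    Pixel size from the configuration wins over TIFF metadata (a mismatch is
    logged).  Missing pages and unreadable files raise explicit errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    if stack.ndim == 2:
        stack = stack[None]
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    n_pages = stack.shape[0]
    for name, idx in config.channel_map.items():
        if idx >= n_pages:
            raise ValidationError(
                f"channel {name!r} maps to page {idx} but file has {n_pages} pages"
            )
    pixel = config.pixel_size_um
    meta_pixel = meta.get("pixel_size_um")
    if meta_pixel is not None and meta_pixel != pixel:
        logger.warning(
            "pixel size mismatch for %s: metadata %s, config %s; using config",
            path.name,
            meta_pixel,
            pixel,
        )
    fluor = {
        name: np.asarray(stack[idx], dtype=float)
        for name, idx in config.channel_map.items()
        if name not in ("brightfield", "scatter")
    }
    scatter = None
    if "scatter" in config.channel_map:
        scatter = np.asarray(stack[config.channel_map["scatter"]], dtype=float)
    truth = None
    sidecar = path.with_suffix(".truth.json")
    if sidecar.exists():
        t = json.loads(sidecar.read_text())
        truth = GroundTruth(
            cell_mask_true=None,
            interior_mask_true=None,
            internal_fraction_true=t.get("internal_fraction_true"),
            total_probe_true=t.get("total_probe_true"),
        )
    return CellEvent(
        brightfield=np.asarray(stack[config.channel_map["brightfield"]], dtype=float),
        fluorescence=fluor,
        scatter=scatter,
        pixel_size_um=pixel,
        truth=truth,
        event_id=meta.get("event_id", path.stem),
    )


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_output_csv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the config-hash header comment."""
    return pd.read_csv(path, comment="#")


def run_pipeline(config: RunConfig, input_dir: str | Path) -> dict:
    """Run segment -> erode -> features -> summarize on a directory of events.

    Writes masks (8-bit TIFF), a QC table, the feature CSV and the population
    summary under ``config.output_dir``, plus a run manifest (versions,
    config hash, per-stage counts).  Outputs are deterministic: rerunning
    with the same configuration and inputs is byte-identical.
    """
    input_dir = Path(input_dir)
    paths = sorted(input_dir.glob("*.tif")) + sorted(input_dir.glob("*.tiff"))
    if not paths:
        raise ValidationError(f"no event TIFFs found in {input_dir}")
    out = Path(config.output_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    events: list[CellEvent] = []
    masks: list[MaskPair] = []
    qc_rows = []
    n_flagged = 0
    for path in paths:
        try:
            event = read_event(path, config)
            mask_pair = compute_masks(event.brightfield, config.mask_params)
        except Exception as err:  # abort with stage and event id
            raise RuntimeError(f"stage segment failed on event {path.stem}: {err}") from err
        events.append(event)
        masks.append(mask_pair)
        qc = mask_pair.qc.as_dict()
        if any(qc.values()):
            n_flagged += 1
        px_area = config.mask_params.pixel_size_um**2
        qc_rows.append(
            {
                "event_id": event.event_id,
                **qc,
                "area_px": int(mask_pair.whole_mask.sum()),
                "area_um2": float(mask_pair.whole_mask.sum() * px_area),
            }
        )
        mask_img = np.zeros(mask_pair.whole_mask.shape, dtype=np.uint8)
        mask_img[mask_pair.whole_mask] = 128
        if mask_pair.internal_mask is not None:
            mask_img[mask_pair.internal_mask] = 255
        tifffile.imwrite(out / "masks" / f"{event.event_id}.tif", mask_img)

    try:
        features = extract_features(
            events, masks, epsilon=config.epsilon, background=config.background
        )
    except Exception as err:
        raise RuntimeError(f"stage features failed: {err}") from err
    chash = config.config_hash
    _write_csv(features, out / "features.csv", chash)
    _write_csv(pd.DataFrame(qc_rows), out / "qc.csv", chash)

    try:
        summary = summarize_population(
            features,
            condition=[input_dir.name] * len(features),
            statistic=config.statistic,
        )
    except Exception as err:
        raise RuntimeError(f"stage summarize failed: {err}") from err
    _write_csv(summary, out / "summary.csv", chash)

    manifest = {
        "uptakeflow_version": __version__,
        "config_hash": chash,
        "config": config.to_dict(),
        "counts": {
            "events_read": len(events),
            "events_flagged": n_flagged,
            "feature_rows": int(len(features)),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info(
        "pipeline: %d events read, %d flagged, %d feature rows",
        len(events),
        n_flagged,
        len(features),
    )
    return {
        "events": events,
        "masks": masks,
        "features": features,
        "summary": summary,
        "manifest": manifest,
    }
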