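"""Manifests, images, predictions and metrics on disk.

The dataset manifest is a plain CSV with the fixed header
``image_path,bag_label,severity,subject_id,split`` (plus an optional
``mask_path`` column written by the phantom generator). Paths are stored
relative to the manifest's directory so a dataset folder can be moved
wholesale. Validation is strict and reports offending row numbers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .bagging import EnFaceImage
from .mil_core import ScoreSet

__all__ = [
    "Manifest",
    "ManifestRecord",
    "ManifestError",
    "read_manifest",
    "write_manifest",
    "read_image",
    "write_image",
    "write_predictions",
    "read_predictions",
    "write_metrics",
    "read_metrics",
    "setup_logging",
]

logger = logging.getLogger("milenface")

REQUIRED_COLUMNS = ["image_path", "bag_label", "severity", "subject_id", "split"]
SPLITS = {"train", "val", "test"}
SEVERITIES = {"healthy", "no_signs", "mild", "severe", "unknown"}


class ManifestError(ValueError):
    """Manifest validation failure; message lists the offending rows."""


@dataclass
class ManifestRecord:
    image_path: str
    bag_label: int
    severity: str
    subject_id: str
    split: str
    mask_path: str | None = None


@dataclass
class Manifest:
    records: list[ManifestRecord]
    root: Path = field(default_factory=Path)

    def __len__(self) -> int:
        return len(self.records)

    def split(self, name: str) -> list[ManifestRecord]:
        if name not in SPLITS:
            raise ValueError(f"unknown split {name!r}")
        return [r for r in self.records if r.split == name]

    def resolve(self, rel_path: str) -> Path:
        return self.root / rel_path


def read_manifest(path: str | Path) -> Manifest:
    """Read and validate a manifest CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path} is missing columns: {missing}")
    errors: list[str] = []
    records: list[ManifestRecord] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        problems = []
        label_raw = str(row.bag_label).strip()
        label = -1
        if label_raw in {"0", "1"}:
            label = int(label_raw)
        else:
            problems.append(f"bag_label={label_raw!r} is not binary")
        severity = str(row.severity).strip() or "unknown"
        if severity not in SEVERITIES:
            problems.append(f"severity={severity!r} unknown")
        elif severity == "healthy" and label == 1:
            problems.append("severity=healthy contradicts bag_label=1")
        elif severity in {"no_signs", "mild", "severe"} and label == 0:
            problems.append(f"severity={severity} contradicts bag_label=0")
        if row.split not in SPLITS:
            problems.append(f"split={row.split!r} not in {sorted(SPLITS)}")
        if row.image_path in seen:
            problems.append(f"duplicate image_path (first seen row {seen[row.image_path]})")
        else:
            seen[row.image_path] = i
        if problems:
            errors.append(f"row {i}: " + "; ".join(problems))
            continue
        records.append(
            ManifestRecord(
                image_path=row.image_path,
                bag_label=label,
                severity=severity,
                subject_id=str(row.subject_id),
                split=str(row.split),
                mask_path=(getattr(row, "mask_path", "") or None),
            )
        )
    if errors:
        raise ManifestError(f"manifest {path} invalid:\n" + "\n".join(errors))
    return Manifest(records=records, root=path.parent)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    path = Path(path)
    has_masks = any(r.mask_path for r in manifest.records)
    cols = REQUIRED_COLUMNS + (["mask_path"] if has_masks else [])
    rows = []
    for r in manifest.records:
        row = {
            "image_path": r.image_path,
            "bag_label": r.bag_label,
            "severity": r.severity,
            "subject_id": r.subject_id,
            "split": r.split,
        }
        if has_masks:
            row["mask_path"] = r.mask_path or ""
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_image(path: str | Path, bag_label: int = 0, severity: str = "unknown") -> EnFaceImage:
    """Read an 8-bit PNG or 8/16-bit TIFF as a [0, 1]-scaled grayscale image."""
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if not (arr[:, :, 0] == arr[:, :, 1]).all() or not (
            arr[:, :, 0] == arr[:, :, 2]
        ).all():
            raise ValueError(f"{path}: RGB image with non-identical channels")
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        scale = 1.0
    else:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}")
    return EnFaceImage(
        pixels=arr.astype(np.float64) / scale,
        bag_label=bag_label,
        severity=severity,
        source_path=str(path),
    )


def write_image(pixels: np.ndarray, path: str | Path, bit_depth: int = 8) -> None:
    """Write a [0, 1] grayscale array as 8-bit PNG or 16-bit PNG/TIFF."""
    pixels = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    if bit_depth == 8:
        arr = np.round(pixels * 255).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.round(pixels * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(Path(path), arr)


def write_predictions(score_sets: list[ScoreSet], path: str | Path) -> None:
    """Write per-bag scores/decisions plus flattened row-major instance scores."""
    path = Path(path)
    base_cols = ["image_path", "bag_score", "decision"]
    if not score_sets:
        pd.DataFrame(columns=base_cols).to_csv(path, index=False)
        return
    k = len(score_sets[0].instance_scores)
    width = max(3, len(str(k - 1)))
    inst_cols = [f"inst_{j:0{width}d}" for j in range(k)]
    rows = []
    for ss in score_sets:
        if len(ss.instance_scores) != k:
            raise ValueError("all ScoreSets must have the same instance count")
        values = np.asarray(ss.instance_scores, dtype=np.float64)
        if not np.all(np.isfinite(values)) or (
            ss.bag_score is not None and not np.isfinite(ss.bag_score)
        ):
            raise ValueError(f"non-finite score in predictions for {ss.source_path}")
        row = {
            "image_path": ss.source_path or "",
            "bag_score": np.float64(ss.bag_score) if ss.bag_score is not None else np.nan,
            "decision": "" if ss.decision is None else int(ss.decision),
        }
        row.update({c: v for c, v in zip(inst_cols, values)})
        rows.append(row)
    pd.DataFrame(rows, columns=base_cols + inst_cols).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_predictions(path: str | Path) -> list[ScoreSet]:
    df = pd.read_csv(path)
    inst_cols = [c for c in df.columns if c.startswith("inst_")]
    out = []
    for _, row in df.iterrows():
        decision = row.get("decision")
        out.append(
            ScoreSet(
                instance_scores=row[inst_cols].to_numpy(dtype=np.float64),
                bag_label=None,
                bag_score=float(row["bag_score"]),
                decision=None if pd.isna(decision) else int(decision),
                source_path=str(row["image_path"]),
            )
        )
    return out


def write_metrics(metrics: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(metrics), indent=2, sort_keys=True) + "\n")


def read_metrics(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def setup_logging(level: str = "INFO") -> None:
    """Route package logs to stderr at the given level."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())
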