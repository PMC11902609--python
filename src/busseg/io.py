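"""Reading and writing frames, masks, annotations, contours and reports.

File conventions
----------------
* Frames: PNG/TIFF/JPEG; color images are converted to grayscale with the
  Rec. 601 luma weights (0.299 R + 0.587 G + 0.114 B) and rescaled to 8-bit.
* Masks: 8-bit PNG, 0 = background, 255 = foreground.
* Tissue annotations: indexed 8-bit PNG where 0 = unannotated/ignore and
  value ``v`` in 1..C means class ``v - 1`` of the class list; a sidecar
  JSON (same stem, ``.classes.json``) names the classes.
* Contours: CSV with columns ``angle_deg, radius_px, x, y`` or a
  GeoJSON-style polygon JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import InvalidInputError

LUMA_WEIGHTS = (0.299, 0.587, 0.114)  # Rec. 601


def read_frame(path) -> np.ndarray:
    """Read an image as an 8-bit grayscale frame."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., :3].astype(np.float64) @ np.array(LUMA_WEIGHTS)
    img = np.asarray(img, dtype=np.float64)
    if img.max() > 255:  # 16-bit input
        img = img * (255.0 / img.max())
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def read_frame_sequence(path) -> list[np.ndarray]:
    """Read a numbered-image directory or a multi-page TIFF as frames."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".tif", ".tiff", ".jpg", ".jpeg"})
        if not files:
            raise InvalidInputError(f"no image files in {path}")
        return [read_frame(p) for p in files]
    pages = iio.imread(path, index=None)
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim == 4:  # pages x H x W x channels
        w = np.array(LUMA_WEIGHTS)
        pages = np.clip(np.rint(pages[..., :3].astype(np.float64) @ w), 0, 255)
    return [p.astype(np.uint8) for p in pages]


def write_frame(path, frame: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(frame, dtype=np.uint8))


def read_mask(path) -> np.ndarray:
    """Read a binary mask PNG (any nonzero pixel is foreground)."""
    return np.asarray(iio.imread(path)) > 0


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))


def read_annotation(path, n_classes: int | None = None) -> np.ndarray:
    """Read an indexed tissue annotation PNG into class indices.

    Palette value 0 (unannotated) becomes -1; value ``v`` becomes class
    ``v - 1``.
    """
    raw = np.asarray(iio.imread(path)).astype(np.int64)
    if raw.ndim != 2:
        raise InvalidInputError("annotation must be a single-channel indexed PNG")
    if n_classes is not None and raw.max() > n_classes:
        raise InvalidInputError(
            f"annotation value {raw.max()} exceeds {n_classes} classes")
    return raw - 1


def write_annotation(path, labels: np.ndarray, class_list=None) -> None:
    """Write class indices as indexed PNG (+ sidecar class-name JSON)."""
    labels = np.asarray(labels, dtype=np.int64)
    iio.imwrite(path, (labels + 1).astype(np.uint8))
    if class_list is not None:
        sidecar = Path(path).with_suffix(".classes.json")
        sidecar.write_text(json.dumps({"classes": list(class_list)}, indent=2))


def read_manifest(path) -> pd.DataFrame:
    """Read a CSV manifest (training or evaluation)."""
    return pd.read_csv(path)


def write_contour_csv(path, polar) -> None:
    """Write a polar contour as CSV (angle_deg, radius_px, x, y)."""
    xy = polar.to_cartesian()
    pd.DataFrame({
        "angle_deg": polar.angles_deg,
        "radius_px": polar.radii,
        "x": xy[:, 0],
        "y": xy[:, 1],
    }).to_csv(path, index=False)


def export_feature_stack(path, stack: np.ndarray) -> None:
    """Dump a per-pixel feature stack as a dense ``.npy`` array for inspection."""
    np.save(path, np.asarray(stack, dtype=np.float64))


def write_contour_json(path, contour_xy: np.ndarray) -> None:
    """Write a closed contour as a GeoJSON-style polygon."""
    ring = np.vstack([contour_xy, contour_xy[:1]]).tolist()
    payload = {"type": "Polygon", "coordinates": [ring]}
    Path(path).write_text(json.dumps(payload))
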