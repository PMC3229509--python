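"""Readers and writers for images, label maps, tables and ground truth.

Images travel as 8-bit grayscale TIFF/PNG, label images as 16-bit TIFF,
masks as 8-bit {0, 255} TIFF, tables as CSV and reports/models/configs as
JSON — every artifact written here can be re-read by the functions below.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .segment import NucleusRecord
from .synthetic import GroundTruth

__all__ = [
    "read_image",
    "write_image",
    "read_label_image",
    "write_label_image",
    "read_mask",
    "write_mask",
    "write_ground_truth",
    "read_ground_truth",
    "records_table",
    "write_records",
    "write_overlay",
    "write_json",
    "read_json",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}


def read_image(path) -> np.ndarray:
    """Load a single-channel 8-bit image (TIFF or anything Pillow reads)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("L"))
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}: {path}")
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    arr = np.asarray(image, dtype=np.uint8)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr, mode="L").save(path)


def read_label_image(path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    return arr.astype(np.int32)


def write_label_image(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label image exceeds 16-bit range")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_mask(path) -> np.ndarray:
    return (tifffile.imread(Path(path)) > 0).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def write_ground_truth(out_dir, truth: GroundTruth, stem: str = "truth") -> None:
    """Label TIFF + sidecar CSV (label, class, subtype, centroid) + mask TIFF."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_label_image(out_dir / f"{stem}_labels.tif", truth.label_image)
    write_mask(out_dir / f"{stem}_tumor_mask.tif", truth.tumor_region_mask)
    cents = truth.centroids()
    rows = [{"label": lab,
             "class": truth.classes[lab],
             "subtype": truth.subtypes[lab],
             "centroid_row": cents[lab][0],
             "centroid_col": cents[lab][1]} for lab in sorted(truth.classes)]
    pd.DataFrame(rows).to_csv(out_dir / f"{stem}_nuclei.csv", index=False)


def read_ground_truth(out_dir, stem: str = "truth") -> GroundTruth:
    out_dir = Path(out_dir)
    labels = read_label_image(out_dir / f"{stem}_labels.tif")
    mask = read_mask(out_dir / f"{stem}_tumor_mask.tif").astype(bool)
    table = pd.read_csv(out_dir / f"{stem}_nuclei.csv")
    labels_col = table["label"].astype(int)
    classes = dict(zip(labels_col, table["class"].astype(str)))
    subtypes = dict(zip(labels_col, table["subtype"].astype(str)))
    return GroundTruth(label_image=labels, classes=classes, subtypes=subtypes,
                       tumor_region_mask=mask)


def records_table(records: Sequence[NucleusRecord]) -> pd.DataFrame:
    """One row per nucleus with all per-cell statistics (no pixel sets)."""
    rows = []
    for r in records:
        rows.append({
            "label": r.label,
            "centroid_row": r.centroid[0], "centroid_col": r.centroid[1],
            "bbox_min_row": r.bbox[0], "bbox_min_col": r.bbox[1],
            "bbox_max_row": r.bbox[2], "bbox_max_col": r.bbox[3],
            "area_px": r.area_px,
            "mean_intensity": r.mean_intensity, "min_intensity": r.min_intensity,
            "max_intensity": r.max_intensity, "median_intensity": r.median_intensity,
            "std_intensity": r.std_intensity,
            "major_axis_px": r.major_axis_px, "minor_axis_px": r.minor_axis_px,
            "eccentricity": r.eccentricity,
            "equivalent_diameter_px": r.equivalent_diameter_px,
            "extent": r.extent, "perimeter_px": r.perimeter_px,
        })
    return pd.DataFrame(rows)


def write_records(path, records: Sequence[NucleusRecord]) -> None:
    records_table(records).to_csv(Path(path), index=False)


def write_overlay(path, labels: np.ndarray, nucleus_class: Dict[int, int]) -> None:
    """RGB overlay of per-nucleus classes: green = tumor, blue = stroma,
    grey = unclassified."""
    labels = np.asarray(labels)
    rgb = np.zeros(labels.shape + (3,), dtype=np.uint8)
    for lab in np.unique(labels):
        if lab <= 0:
            continue
        sel = labels == lab
        cls = nucleus_class.get(int(lab))
        if cls == 1:
            rgb[sel] = (0, 200, 0)
        elif cls == -1:
            rgb[sel] = (0, 80, 255)
        else:
            rgb[sel] = (128, 128, 128)
    Image.fromarray(rgb, mode="RGB").save(Path(path))


def write_json(path, obj) -> None:
    with open(Path(path), "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def read_json(path):
    with open(Path(path)) as fh:
        return json.load(fh)
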