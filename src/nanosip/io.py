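"""Reading and writing ion stacks, ROI label masks, and measurement tables.

Native on-disk layout for a stack is one multi-page TIFF per ion (pages =
planes, 16-bit unsigned, promoted to 32-bit when counts exceed 65535) plus
a ``stack.json`` sidecar recording the ion order and acquisition metadata.
The proprietary instrument format is deliberately not parsed.

CSV dialect everywhere: comma separator, UTF-8, '.' decimal point, no
thousands separators.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .datatypes import AccumulatedImage, CellMeasurement, CellROI, IonImageStack

SIDECAR_NAME = "stack.json"

#: Fixed column order of the measurement table.
MEASUREMENT_COLUMNS = (
    "cell_id",
    "timepoint_h",
    "sum_12C",
    "sum_13C",
    "sum_12C14N",
    "sum_12C15N",
    "sum_16O",
    "sum_32S",
    "R13",
    "R15",
    "F13",
    "F15",
    "APE13",
    "APE15",
    "length_um",
    "width_um",
)


def _ion_filename(ion: str) -> str:
    return f"ion_{ion}.tif"


def write_stack(stack: IonImageStack, path: str | Path) -> Path:
    """Write a stack as per-ion multi-page TIFFs plus a JSON sidecar.

    Counts must be integer-valued (expectation-mode float stacks are an
    in-memory construct and are rejected here).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    counts = np.asarray(stack.counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.all(counts == np.round(counts)):
            raise ValueError("stack counts must be integer-valued for serialization")
        counts = counts.astype(np.int64)
    if counts.min() < 0:
        raise ValueError("stack counts must be non-negative")
    dtype = np.uint16 if counts.max() <= np.iinfo(np.uint16).max else np.uint32
    for i, ion in enumerate(stack.ion_labels):
        tifffile.imwrite(path / _ion_filename(ion), counts[i].astype(dtype))
    sidecar = {
        "ion_labels": list(stack.ion_labels),
        "raster_um": stack.raster_um,
        "dwell_ms": stack.dwell_ms,
        "timepoint_h": stack.timepoint_h,
        "n_planes": stack.n_planes,
        "image_size": stack.image_size,
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(path: str | Path) -> IonImageStack:
    """Read a stack directory written by `write_stack`; round-trip lossless.

    Raises on a missing sidecar, missing or shape-mismatched ion files, and
    negative or non-integer pixel values.
    """
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"stack sidecar {sidecar_path} not found")
    meta = json.loads(sidecar_path.read_text())
    ions = meta["ion_labels"]
    planes = []
    for ion in ions:
        f = path / _ion_filename(ion)
        if not f.exists():
            raise FileNotFoundError(f"ion image file for {ion!r} missing from {path}")
        img = tifffile.imread(f)
        if img.ndim == 2:  # single-plane stacks come back 2-D
            img = img[None]
        if not np.issubdtype(img.dtype, np.integer):
            if not np.all(img == np.round(img)):
                raise ValueError(f"non-integer pixel values in ion {ion!r}")
            img = img.astype(np.int64)
        if np.any(np.asarray(img, dtype=np.int64) < 0):
            raise ValueError(f"negative pixel values in ion {ion!r}")
        planes.append(img.astype(np.int64))
    shapes = {p.shape for p in planes}
    if len(shapes) != 1:
        raise ValueError(f"ion images disagree in shape: {sorted(shapes)}")
    expected = (meta["n_planes"], meta["image_size"], meta["image_size"])
    if planes[0].shape != expected:
        raise ValueError(f"ion image shape {planes[0].shape} != sidecar {expected}")
    return IonImageStack(
        ion_labels=tuple(ions),
        counts=np.stack(planes),
        raster_um=meta["raster_um"],
        dwell_ms=meta["dwell_ms"],
        timepoint_h=meta["timepoint_h"],
    )


ACC_SIDECAR_NAME = "accumulated.json"


def write_accumulated(acc: AccumulatedImage, path: str | Path) -> Path:
    """Write an accumulated image as per-ion TIFFs + validity mask + sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    counts = np.asarray(acc.counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.all(counts == np.round(counts)):
            raise ValueError("accumulated counts must be integer-valued for serialization")
        counts = counts.astype(np.int64)
    dtype = np.uint16 if counts.max() <= np.iinfo(np.uint16).max else np.uint32
    for i, ion in enumerate(acc.ion_labels):
        tifffile.imwrite(path / f"acc_{ion}.tif", counts[i].astype(dtype))
    tifffile.imwrite(path / "validity.tif", acc.validity.astype(np.uint8))
    sidecar = {
        "ion_labels": list(acc.ion_labels),
        "pixel_um": acc.pixel_um,
        "timepoint_h": acc.timepoint_h,
        "trace": list(acc.trace) if acc.trace is not None else None,
        "source_id": acc.source_id,
    }
    (path / ACC_SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
    return path


def read_accumulated(path: str | Path) -> AccumulatedImage:
    """Read an accumulated image directory written by `write_accumulated`."""
    from .datatypes import DriftTrace

    path = Path(path)
    meta = json.loads((path / ACC_SIDECAR_NAME).read_text())
    counts = np.stack(
        [tifffile.imread(path / f"acc_{ion}.tif").astype(np.int64) for ion in meta["ion_labels"]]
    )
    validity = tifffile.imread(path / "validity.tif").astype(bool)
    trace = DriftTrace([tuple(s) for s in meta["trace"]]) if meta["trace"] is not None else None
    return AccumulatedImage(
        ion_labels=tuple(meta["ion_labels"]),
        counts=counts,
        validity=validity,
        pixel_um=meta["pixel_um"],
        timepoint_h=meta["timepoint_h"],
        trace=trace,
        source_id=meta.get("source_id", ""),
    )


def write_label_mask(label_mask: np.ndarray, path: str | Path) -> Path:
    """Write an integer cell-label image (0 = background) as 16-bit TIFF."""
    label_mask = np.asarray(label_mask)
    if label_mask.min() < 0 or label_mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("label values must fit in uint16")
    path = Path(path)
    tifffile.imwrite(path, label_mask.astype(np.uint16))
    return path


def read_roi_masks(path: str | Path, accumulated: AccumulatedImage) -> list[CellROI]:
    """Read a labeled mask image into one manual `CellROI` per nonzero label.

    The label image must match the accumulated image's shape; an all-zero
    image yields an empty list (no cells outlined is a valid state).
    """
    labels = np.asarray(tifffile.imread(Path(path)))
    if labels.shape != accumulated.validity.shape:
        raise ValueError(
            f"label image shape {labels.shape} != accumulated shape {accumulated.validity.shape}"
        )
    rois = []
    for k in np.unique(labels):
        if k == 0:
            continue
        rois.append(CellROI(cell_id=int(k), mask=labels == k, source="manual"))
    return rois


def write_measurements(cells: Sequence[CellMeasurement], path: str | Path) -> Path:
    """Write per-cell measurements as a CSV with a fixed column order.

    One row per cell; floats are written with 12 significant digits so the
    table re-parses to the original values at 1e-9 relative tolerance.
    Duplicate (timepoint_h, cell_id) pairs are rejected.
    """
    keys = [(c.timepoint_h, c.cell_id) for c in cells]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (timepoint_h, cell_id) pairs: {dupes}")
    rows = []
    for c in cells:
        rows.append(
            {
                "cell_id": c.cell_id,
                "timepoint_h": c.timepoint_h,
                **{f"sum_{ion}": c.ion_sums.get(ion, 0) for ion in
                   ("12C", "13C", "12C14N", "12C15N", "16O", "32S")},
                "R13": c.r13,
                "R15": c.r15,
                "F13": c.f13,
                "F15": c.f15,
                "APE13": c.ape13,
                "APE15": c.ape15,
                "length_um": c.length_um,
                "width_um": c.width_um,
            }
        )
    frame = pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.12g")
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement CSV back into a DataFrame (fixed column order)."""
    frame = pd.read_csv(Path(path))
    missing = set(MEASUREMENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    return frame[list(MEASUREMENT_COLUMNS)]


def measurements_to_objects(frame: pd.DataFrame) -> list[CellMeasurement]:
    """Rebuild `CellMeasurement` objects from a measurement table."""
    out = []
    for _, r in frame.iterrows():
        out.append(
            CellMeasurement(
                cell_id=int(r["cell_id"]),
                timepoint_h=float(r["timepoint_h"]),
                ion_sums={ion: float(r[f"sum_{ion}"]) for ion in
                          ("12C", "13C", "12C14N", "12C15N", "16O", "32S")},
                r13=float(r["R13"]),
                r15=float(r["R15"]),
                f13=float(r["F13"]),
                f15=float(r["F15"]),
                ape13=float(r["APE13"]),
                ape15=float(r["APE15"]),
                length_um=float(r["length_um"]),
                width_um=float(r["width_um"]),
            )
        )
    return out
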