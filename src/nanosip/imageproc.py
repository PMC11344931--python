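"""Inter-plane drift estimation, plane accumulation, and cell segmentation.

Drift between consecutive raster planes is modeled as a rigid integer-pixel
translation (no rotation, no subpixel interpolation — integer shifts keep
the Poisson count statistics intact).  Each plane is aligned to plane 0 of
a reference ion by maximizing normalized cross-correlation over the shift
grid, planes are summed after back-shifting, and pixels not covered by all
shifted planes are excluded through a validity mask rather than zero-padded
into downstream statistics.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

from .datatypes import AccumulatedImage, CellROI, DriftTrace, IonImageStack

logger = logging.getLogger(__name__)

DEFAULT_REF_ION = "12C14N"
DEFAULT_MAX_SHIFT = 10


def translate(img: np.ndarray, dy: int, dx: int, fill: float = 0.0) -> np.ndarray:
    """Shift image content by ``(dy, dx)`` (positive = down/right); the
    exposed border is filled with ``fill``."""
    out = np.full_like(img, fill)
    h, w = img.shape
    if abs(dy) >= h or abs(dx) >= w:
        return out
    out[max(0, dy): h + min(0, dy), max(0, dx): w + min(0, dx)] = \
        img[max(0, -dy): h + min(0, -dy), max(0, -dx): w + min(0, -dx)]
    return out


def _ncc_at(ref: np.ndarray, moving: np.ndarray, dy: int, dx: int) -> float:
    """Pearson correlation between plane 0 and a candidate-aligned plane,
    computed on the pixels where the two fields genuinely overlap.

    If ``moving`` is the reference translated by (dy, dx), the overlap of
    moving with the reference frame is ``moving[max(0,dy):, max(0,dx):]``
    against ``ref[max(0,-dy):, max(0,-dx):]`` (suitably cropped).
    """
    h, w = ref.shape
    if abs(dy) >= h or abs(dx) >= w:
        return -np.inf
    a = ref[max(0, -dy): h + min(0, -dy), max(0, -dx): w + min(0, -dx)]
    b = moving[max(0, dy): h + min(0, dy), max(0, dx): w + min(0, dx)]
    a = a.astype(float).ravel()
    b = b.astype(float).ravel()
    a -= a.mean()
    b -= b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return -np.inf
    return float((a @ b) / denom)


def estimate_drift(
    stack: IonImageStack,
    ref_ion: str = DEFAULT_REF_ION,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> DriftTrace:
    """Estimate each plane's integer (dy, dx) displacement relative to plane 0.

    For every plane the normalized cross-correlation with plane 0 of the
    reference ion is evaluated at every integer shift within ±``max_shift``
    and the maximizing shift is returned.  Ties are broken by the smallest
    shift magnitude, then row-major (dy, dx) order.

    Raises
    ------
    ValueError
        If ``max_shift`` is negative or the reference plane 0 carries no
        signal (all-zero), in which case there is nothing to align to.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    planes = stack.ion(ref_ion)
    ref = planes[0]
    if not np.any(ref):
        raise ValueError(f"plane 0 of reference ion {ref_ion!r} is all zero; no signal to align")
    # Candidates ordered by (magnitude, dy, dx): a strict improvement rule
    # then realizes the documented tie-break.
    grid = [(dy, dx) for dy in range(-max_shift, max_shift + 1)
            for dx in range(-max_shift, max_shift + 1)]
    grid.sort(key=lambda s: (s[0] * s[0] + s[1] * s[1], s[0], s[1]))
    shifts: list[tuple[int, int]] = [(0, 0)]
    for p in range(1, planes.shape[0]):
        best, best_ncc = (0, 0), -np.inf
        for dy, dx in grid:
            ncc = _ncc_at(ref, planes[p], dy, dx)
            if ncc > best_ncc:
                best, best_ncc = (dy, dx), ncc
        shifts.append(best)
    return DriftTrace(shifts)


def accumulate(stack: IonImageStack, trace: DriftTrace) -> AccumulatedImage:
    """Back-shift every plane by its drift and sum planes per ion.

    The validity mask is the intersection of all shifted plane footprints;
    outside it the accumulated counts are set to zero.  At zero drift the
    accumulation conserves total counts exactly.
    """
    if len(trace) != stack.n_planes:
        raise ValueError(f"trace has {len(trace)} shifts for {stack.n_planes} planes")
    size = stack.image_size
    for dy, dx in trace:
        if abs(dy) >= size or abs(dx) >= size:
            raise ValueError(f"shift ({dy}, {dx}) exceeds the {size}px image")
    validity = np.ones((size, size), dtype=bool)
    ones = np.ones((size, size))
    for dy, dx in trace:
        validity &= translate(ones, -dy, -dx, fill=0.0) > 0
    acc = np.zeros((len(stack.ion_labels), size, size), dtype=stack.counts.dtype)
    for i in range(len(stack.ion_labels)):
        for p, (dy, dx) in enumerate(trace):
            acc[i] += translate(stack.counts[i, p], -dy, -dx, fill=0)
        acc[i][~validity] = 0
    return AccumulatedImage(
        ion_labels=stack.ion_labels,
        counts=acc,
        validity=validity,
        pixel_um=stack.pixel_um,
        timepoint_h=stack.timepoint_h,
        trace=trace,
    )


def segment_cells(
    acc: AccumulatedImage,
    ion: str = DEFAULT_REF_ION,
    min_area_px: int = 50,
    contrast_min: float = 3.0,
) -> list[CellROI]:
    """Automatic cell segmentation standing in for manual ROI outlining.

    Otsu-thresholds the chosen ion inside the validity mask, labels
    8-connected components, fills holes, drops components smaller than
    ``min_area_px``, and returns ROIs numbered in descending area order
    with ``source="auto"``.  A constant image (nothing to threshold)
    yields an empty list with a logged warning, as does an image whose
    Otsu split separates classes by less than ``contrast_min``-fold in
    mean intensity — that split is counting noise, not cells.
    """
    img = acc.ion(ion).astype(float)
    valid_vals = img[acc.validity]
    if valid_vals.size == 0 or valid_vals.min() == valid_vals.max():
        logger.warning("segmentation: constant %s image, no threshold separates; returning no ROIs", ion)
        return []
    thr = threshold_otsu(valid_vals)
    fg_vals = valid_vals[valid_vals > thr]
    bg_vals = valid_vals[valid_vals <= thr]
    if fg_vals.size == 0 or fg_vals.mean() < contrast_min * max(bg_vals.mean(), 1e-12):
        logger.warning(
            "segmentation: %s foreground/background contrast below %gx; "
            "treating the field as background-only", ion, contrast_min)
        return []
    binary = (img > thr) & acc.validity
    binary = ndimage.binary_fill_holes(binary)
    labels = sk_label(binary, connectivity=2)
    rois = []
    for k in range(1, labels.max() + 1):
        mask = labels == k
        area = int(mask.sum())
        if area >= min_area_px:
            rois.append((area, mask))
    rois.sort(key=lambda t: -t[0])
    return [CellROI(cell_id=i + 1, mask=mask, source="auto") for i, (_, mask) in enumerate(rois)]
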