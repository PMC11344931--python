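"""Per-cell isotope quantification and cell/crystal morphometrics.

Isotope ratios are ratio-of-sums: all counts of an ion inside the cell's
ROI are pooled before dividing (the standard estimator for count-limited
secondary-ion data; per-pixel ratios would be dominated by low-count
pixels).  The 15N/14N ratio is taken as exactly the pooled 12C15N-/12C14N-
count ratio, with no further correction factor.  Atom fractions are
``F = R/(1+R)`` and atom percent enrichment is ``APE = 100*(F - F_nat)``
against the configured natural-abundance baseline.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats as sp_stats

from .datatypes import (
    AccumulatedImage,
    CellMeasurement,
    CellROI,
    CrystalMeasurement,
    NaturalAbundance,
)

logger = logging.getLogger(__name__)


def atom_fraction(ratio: float) -> float:
    """Rare-isotope atom fraction from a count ratio, F = R/(1+R)."""
    if ratio < 0:
        raise ValueError("isotope ratio must be non-negative")
    return ratio / (1.0 + ratio)


def measure_cell(
    acc: AccumulatedImage,
    roi: CellROI,
    natural: NaturalAbundance | None = None,
) -> CellMeasurement:
    """Quantify one cell: pooled ion sums, ratios, enrichments, rod size.

    ROI pixels outside the accumulated image's validity mask are dropped
    with a warning.  A zero denominator sum (no 12C- or no 12C14N- signal)
    is an error naming the offending ion.
    """
    natural = natural or NaturalAbundance()
    mask = roi.mask & acc.validity
    n_dropped = int(roi.mask.sum() - mask.sum())
    if n_dropped:
        logger.warning("cell %d: dropping %d ROI pixels outside the validity mask",
                       roi.cell_id, n_dropped)
    if not mask.any():
        raise ValueError(f"cell {roi.cell_id}: ROI has no pixels inside the validity mask")

    sums = {ion: float(acc.ion(ion)[mask].sum()) for ion in acc.ion_labels}
    for denom in ("12C", "12C14N"):
        if sums.get(denom, 0.0) <= 0:
            raise ValueError(f"cell {roi.cell_id}: zero summed {denom} counts; ratio undefined")
    r13 = sums.get("13C", 0.0) / sums["12C"]
    r15 = sums.get("12C15N", 0.0) / sums["12C14N"]
    f13, f15 = atom_fraction(r13), atom_fraction(r15)
    length_um, width_um = rod_morphometrics(mask, acc.pixel_um)
    return CellMeasurement(
        cell_id=roi.cell_id,
        timepoint_h=acc.timepoint_h,
        ion_sums=sums,
        r13=r13,
        r15=r15,
        f13=f13,
        f15=f15,
        ape13=100.0 * (f13 - natural.f13),
        ape15=100.0 * (f15 - natural.f15),
        length_um=length_um,
        width_um=width_um,
    )


def rod_morphometrics(mask: np.ndarray, pixel_um: float) -> tuple[float, float]:
    """Length and width (um) of a rod-shaped mask via principal axes.

    The major/minor axes are the eigenvectors of the second central moment
    matrix of the mask's pixel coordinates; each extent is the range of
    pixel centers projected on the axis plus one pixel (so a single-pixel
    mask measures one pixel, not zero).  The returned pair is ordered so
    that length >= width.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask).astype(float)
    if coords.shape[0] == 0:
        raise ValueError("mask is empty")
    if coords.shape[0] == 1:
        return pixel_um, pixel_um
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending; columns are axes
    minor_axis, major_axis = eigvecs[:, 0], eigvecs[:, 1]
    proj_major = centered @ major_axis
    proj_minor = centered @ minor_axis
    ext_major = proj_major.max() - proj_major.min() + 1.0
    ext_minor = proj_minor.max() - proj_minor.min() + 1.0
    length_px, width_px = max(ext_major, ext_minor), min(ext_major, ext_minor)
    return length_px * pixel_um, width_px * pixel_um


def crystal_summary(crystals: list[CrystalMeasurement], bin_nm: float = 10.0) -> dict:
    """Summarize a crystal population the way magnetosome surveys report it.

    Returns the length histogram on fixed ``[0, bin), [bin, 2*bin), ...``
    nm bins, the mean +/- SD of length, the mean shape factor, and the
    ordinary-least-squares slope/intercept/r of width versus length.  The
    regression fields are NaN when all lengths coincide (undefined slope).
    """
    if not crystals:
        raise ValueError("crystal list is empty")
    lengths = np.array([c.length_nm for c in crystals])
    widths = np.array([c.width_nm for c in crystals])
    shape_factors = widths / lengths
    upper = (np.floor(lengths.max() / bin_nm) + 1) * bin_nm
    edges = np.arange(0.0, upper + bin_nm / 2, bin_nm)
    hist, _ = np.histogram(lengths, bins=edges)
    if np.ptp(lengths) == 0:
        slope = intercept = rvalue = float("nan")
    else:
        fit = sp_stats.linregress(lengths, widths)
        slope, intercept, rvalue = fit.slope, fit.intercept, fit.rvalue
    return {
        "n": len(crystals),
        "bin_nm": bin_nm,
        "bin_edges_nm": edges.tolist(),
        "length_hist": hist.tolist(),
        "mean_length_nm": float(lengths.mean()),
        "sd_length_nm": float(lengths.std(ddof=1)) if len(crystals) > 1 else 0.0,
        "mean_shape_factor": float(shape_factors.mean()),
        "width_vs_length": {"slope": float(slope), "intercept": float(intercept), "r": float(rvalue)},
    }
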