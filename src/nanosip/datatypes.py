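"""Shared domain types for the NanoSIMS single-cell SIP pipeline.

All image arrays follow one convention: 0-based pixel coordinates, axes
ordered ``(row, col)`` with the row index increasing downward.  Ion count
stacks are indexed ``(ion, plane, row, col)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Canonical secondary-ion labels, in acquisition order.
ION_LABELS = ("12C", "13C", "12C14N", "12C15N", "16O", "32S")

#: Major/minor isotopologue pairing: rare-ion channel -> abundant-ion channel.
ISOTOPE_PAIRS = {"13C": "12C", "12C15N": "12C14N"}


@dataclass(frozen=True)
class NaturalAbundance:
    """Environmental baseline isotope count ratios.

    ``r13`` is the natural 13C-/12C- count ratio and ``r15`` the natural
    15N/14N ratio (measured via the 12C15N-/12C14N- channel pair).  The
    defaults are the freshwater-sediment baselines used throughout this
    pipeline; both can be overridden in configuration.
    """

    r13: float = 0.0112
    r15: float = 0.0037

    def __post_init__(self) -> None:
        if not (self.r13 > 0 and self.r15 > 0):
            raise ValueError("natural-abundance ratios must be positive")

    @property
    def f13(self) -> float:
        """Natural 13C atom fraction, R/(1+R)."""
        return self.r13 / (1.0 + self.r13)

    @property
    def f15(self) -> float:
        """Natural 15N atom fraction, R/(1+R)."""
        return self.r15 / (1.0 + self.r15)


@dataclass
class IonImageStack:
    """Multi-ion, multi-plane secondary-ion count images plus metadata.

    Parameters
    ----------
    ion_labels
        Ordered ion channel names, a subset (usually all) of `ION_LABELS`.
    counts
        Array of shape ``(n_ions, n_planes, size, size)``.  Integer counts
        for measured/simulated data; float only for noise-free expectation
        fields produced by the generator's expectation mode.
    raster_um
        Physical width of the imaged field in micrometres (5-41 um).
    dwell_ms
        Per-pixel dwell time in milliseconds.
    timepoint_h
        Incubation time point in hours.
    """

    ion_labels: tuple[str, ...]
    counts: np.ndarray
    raster_um: float
    dwell_ms: float = 5.0
    timepoint_h: float = 0.0

    def __post_init__(self) -> None:
        self.ion_labels = tuple(self.ion_labels)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 4:
            raise ValueError("counts must be 4-D (ion, plane, row, col)")
        if self.counts.shape[0] != len(self.ion_labels):
            raise ValueError("counts first axis must match number of ion labels")
        if len(set(self.ion_labels)) != len(self.ion_labels):
            raise ValueError("ion labels must be unique")
        unknown = set(self.ion_labels) - set(ION_LABELS)
        if unknown:
            raise ValueError(f"unknown ion labels: {sorted(unknown)}")
        if np.any(self.counts < 0):
            raise ValueError("ion counts must be non-negative")
        if not (self.raster_um > 0):
            raise ValueError("raster_um must be positive")

    @property
    def n_planes(self) -> int:
        return self.counts.shape[1]

    @property
    def image_size(self) -> int:
        return self.counts.shape[2]

    @property
    def pixel_um(self) -> float:
        """Pixel pitch in micrometres (raster width / pixels per side)."""
        return self.raster_um / self.image_size

    def ion(self, label: str) -> np.ndarray:
        """All planes of one ion channel, shape ``(n_planes, size, size)``."""
        try:
            i = self.ion_labels.index(label)
        except ValueError:
            raise KeyError(f"ion {label!r} not present in stack") from None
        return self.counts[i]


@dataclass
class DriftTrace:
    """Per-plane integer translation ``(dy, dx)`` relative to plane 0."""

    shifts: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.shifts = [(int(dy), int(dx)) for dy, dx in self.shifts]
        if self.shifts and self.shifts[0] != (0, 0):
            raise ValueError("plane 0 shift must be (0, 0)")

    def __len__(self) -> int:
        return len(self.shifts)

    def __iter__(self):
        return iter(self.shifts)

    @classmethod
    def zero(cls, n_planes: int) -> "DriftTrace":
        return cls([(0, 0)] * n_planes)


@dataclass
class AccumulatedImage:
    """Drift-corrected, plane-summed per-ion count grids.

    ``counts`` has shape ``(n_ions, size, size)``; pixels outside the
    ``validity`` mask (the intersection of all shifted plane footprints)
    are zero and must be excluded from any statistic.
    """

    ion_labels: tuple[str, ...]
    counts: np.ndarray
    validity: np.ndarray
    pixel_um: float
    timepoint_h: float = 0.0
    trace: DriftTrace | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.ion_labels = tuple(self.ion_labels)
        self.counts = np.asarray(self.counts)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.counts.ndim != 3:
            raise ValueError("accumulated counts must be 3-D (ion, row, col)")
        if self.validity.shape != self.counts.shape[1:]:
            raise ValueError("validity mask shape must match image shape")
        if np.any(self.counts[:, ~self.validity] != 0):
            raise ValueError("pixels outside the validity mask must be zero")

    @property
    def image_size(self) -> int:
        return self.counts.shape[1]

    def ion(self, label: str) -> np.ndarray:
        try:
            i = self.ion_labels.index(label)
        except ValueError:
            raise KeyError(f"ion {label!r} not present") from None
        return self.counts[i]


@dataclass
class CellROI:
    """Pixel mask of a single cell on the accumulated image."""

    cell_id: int
    mask: np.ndarray
    source: str = "manual"  # "manual" | "auto"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.cell_id <= 0:
            raise ValueError("cell_id must be a positive integer")
        if not self.mask.any():
            raise ValueError("ROI mask must be non-empty")
        if self.source not in ("manual", "auto"):
            raise ValueError("source must be 'manual' or 'auto'")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class CellMeasurement:
    """Per-cell ion sums, isotope ratios, enrichments, and morphometrics.

    ``r13 = sum(13C)/sum(12C)`` and ``r15 = sum(12C15N)/sum(12C14N)`` are
    ratio-of-sums estimates; atom fractions are ``F = R/(1+R)`` and atom
    percent enrichment ``APE = 100*(F - F_natural)``.
    """

    cell_id: int
    timepoint_h: float
    ion_sums: dict[str, float]
    r13: float
    r15: float
    f13: float
    f15: float
    ape13: float
    ape15: float
    length_um: float
    width_um: float

    def __post_init__(self) -> None:
        if self.r13 < 0 or self.r15 < 0:
            raise ValueError("isotope ratios must be non-negative")
        if not (0 <= self.f13 < 1 and 0 <= self.f15 < 1):
            raise ValueError("atom fractions must lie in [0, 1)")
        if not (self.length_um >= self.width_um > 0):
            raise ValueError("need length_um >= width_um > 0")


@dataclass
class CrystalMeasurement:
    """One magnetosome crystal: longest axis, perpendicular width, both nm."""

    length_nm: float
    width_nm: float

    def __post_init__(self) -> None:
        if not (0 < self.width_nm <= self.length_nm):
            raise ValueError("need 0 < width_nm <= length_nm")

    @property
    def shape_factor(self) -> float:
        """Width/length ratio in (0, 1]; low values mean elongated crystals."""
        return self.width_nm / self.length_nm


@dataclass
class TimeSeriesDataset:
    """One variable observed per cell, grouped by incubation time point."""

    times_h: list[float]
    groups: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.times_h) != len(self.groups):
            raise ValueError("times_h and groups must have equal length")
        if sorted(self.times_h) != list(self.times_h):
            raise ValueError("time points must be strictly increasing")
        if len(set(self.times_h)) != len(self.times_h):
            raise ValueError("time points must be unique")
        self.groups = [np.asarray(g, dtype=float) for g in self.groups]
        if any(g.ndim != 1 or g.size == 0 for g in self.groups):
            raise ValueError("every time-point group must be a non-empty 1-D array")

    @property
    def n_timepoints(self) -> int:
        return len(self.times_h)

    @classmethod
    def from_frame(cls, frame, variable: str, time_col: str = "timepoint_h") -> "TimeSeriesDataset":
        """Build from a measurement table (one row per cell)."""
        times = sorted(frame[time_col].unique())
        groups = [frame.loc[frame[time_col] == t, variable].to_numpy(dtype=float) for t in times]
        return cls([float(t) for t in times], groups)
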