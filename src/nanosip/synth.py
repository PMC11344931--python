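"""Synthetic NanoSIMS scene and magnetosome-crystal generators.

The generator emulates what the analysis pipeline assumes about real
acquisitions of rod-shaped magnetotactic cells: per-ion Poisson count
images over several consecutive raster planes, rigid translational drift
between planes, a 16O-enriched one-pixel stripe along each cell's
magnetosome chain, and per-cell isotope enrichment whose median follows a
quadratic in incubation time while the cell-to-cell spread grows with
time.  Full ground truth (label mask, true drifts, true per-cell atom
fractions and rod dimensions) is returned alongside every scene so that
recovery tests can compare pipeline output against the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .datatypes import ION_LABELS, IonImageStack, NaturalAbundance
from .imageproc import translate as _translate

Quadratic = tuple[float, float, float]  # (c2, c1, c0), value = c2*t^2 + c1*t + c0


def _child_rng(seed: int, timepoint_h: float, replicate: int) -> np.random.Generator:
    # One root seed; independent child streams per (timepoint, replicate) so
    # each scene is reproducible in isolation.
    t_key = int(round(timepoint_h * 1000))
    return np.random.default_rng(np.random.SeedSequence([int(seed), t_key, int(replicate)]))


@dataclass
class SceneConfig:
    """Parameters of one synthetic acquisition field.

    ``base_rate`` gives the expected in-cell counts per pixel per plane for
    the abundant channels; the rare-isotope channels 13C and 12C15N are
    derived per cell from its atom fractions so that the expectation fields
    satisfy ``E[rare]/E[abundant] = F/(1-F)`` exactly.  The 32S rate is tied
    to the 12C14N rate (the two signals colocalize in cells), and 16O gets a
    multiplicative boost along a one-pixel axial stripe standing in for the
    magnetosome chain.  Background pixels run at ``background_fraction`` of
    the in-cell rates, at natural isotopic abundance.
    """

    n_cells: int = 5
    image_size: int = 256
    raster_um: float = 20.0
    n_planes: int = 6
    dwell_ms: float = 5.0
    cell_length_um: tuple[float, float] = (3.5, 6.5)
    cell_width_um: tuple[float, float] = (0.8, 1.2)
    base_rate: dict[str, float] = field(
        default_factory=lambda: {"12C": 200.0, "12C14N": 150.0, "16O": 80.0}
    )
    s32_factor: float = 0.8  # 32S expectation = s32_factor * 12C14N expectation
    background_fraction: float = 0.01
    chain_o16_boost: float = 3.0
    enrich_median_coeffs: dict[str, Quadratic] | None = None  # keys "13C", "15N"
    enrich_spread: tuple[float, float] = (0.0, 0.0)  # SD(t) = base + rate * t
    drift_max_px: int = 3
    natural: NaturalAbundance = field(default_factory=NaturalAbundance)
    seed: int = 0
    max_place_tries: int = 200
    min_gap_px: int = 3  # enforced clearance between rods (cells are well separated)

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (5.0 <= self.raster_um <= 41.0):
            raise ValueError("raster_um must lie in the acquisition range 5-41 um")
        if self.n_planes < 1:
            raise ValueError("need at least one plane")
        if any(r < 0 for r in self.base_rate.values()):
            raise ValueError("base rates must be non-negative")
        if not (0 <= self.background_fraction <= 1):
            raise ValueError("background_fraction must be in [0, 1]")
        if self.drift_max_px < 0:
            raise ValueError("drift_max_px must be >= 0")
        if self.enrich_spread[0] < 0 or self.enrich_spread[1] < 0:
            raise ValueError("spread profile must be non-negative (hence non-decreasing)")
        lo, hi = self.cell_length_um
        wlo, whi = self.cell_width_um
        if not (0 < lo <= hi) or not (0 < wlo <= whi):
            raise ValueError("cell dimension ranges must be positive and ordered")
        if self.enrich_median_coeffs is None:
            # Unlabeled default: flat trajectories at natural atom fractions.
            self.enrich_median_coeffs = {
                "13C": (0.0, 0.0, self.natural.f13),
                "15N": (0.0, 0.0, self.natural.f15),
            }

    @property
    def pixel_um(self) -> float:
        return self.raster_um / self.image_size

    def spread_at(self, timepoint_h: float) -> float:
        """Per-cell atom-fraction SD at a time point (linear growth model)."""
        base, rate = self.enrich_spread
        return base + rate * timepoint_h


@dataclass
class SceneTruth:
    """Ground truth of one generated scene."""

    label_mask: np.ndarray  # int, 0 = background, k = cell k
    shifts: list[tuple[int, int]]  # true per-plane (dy, dx), plane 0 = (0, 0)
    f13: np.ndarray  # per-cell true 13C atom fraction, index k-1
    f15: np.ndarray
    lengths_um: np.ndarray
    widths_um: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.label_mask.max())

    def cell_mask(self, cell_id: int) -> np.ndarray:
        return self.label_mask == cell_id


class SceneTooDenseError(RuntimeError):
    """Raised when non-overlapping cell placement fails within the retry budget."""


def enrichment_trajectory(
    timepoint_h: float,
    coeffs: Quadratic,
    spread: float,
    n_cells: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw per-cell atom fractions around a quadratic median trajectory.

    The population median follows ``c2*t^2 + c1*t + c0``; individual cells
    scatter around it with the given SD (normal, hence median-preserving),
    clipped into [0, 1).
    """
    if spread < 0:
        raise ValueError("spread must be non-negative")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    c2, c1, c0 = coeffs
    center = c2 * timepoint_h**2 + c1 * timepoint_h + c0
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    draws = center + spread * rng.standard_normal(n_cells)
    return np.clip(draws, 0.0, np.nextafter(1.0, 0.0))


def _rod_mask(
    size: int, center: tuple[float, float], length_px: float, width_px: float, angle: float
) -> np.ndarray | None:
    """Rasterize a capsule (rectangle with semicircular caps) of total
    extent ``length_px`` along its axis; None if it pokes out of the image."""
    half_axis = max(length_px - width_px, 0.0) / 2.0  # central segment half-length
    radius = width_px / 2.0
    cy, cx = center
    uy, ux = math.sin(angle), math.cos(angle)
    # endpoints of the central segment
    eys = (cy - uy * half_axis, cy + uy * half_axis)
    exs = (cx - ux * half_axis, cx + ux * half_axis)
    if any(e - radius < 0.5 or e > size - 1.5 - radius for e in eys + exs):
        return None
    yy, xx = np.mgrid[0:size, 0:size]
    ry, rx = yy - cy, xx - cx
    ax = ry * uy + rx * ux  # axial coordinate
    pp = -ry * ux + rx * uy  # perpendicular coordinate
    ax_clamped = np.clip(ax, -half_axis, half_axis)
    d2 = (ax - ax_clamped) ** 2 + pp**2
    return d2 <= radius**2


def _chain_stripe(size: int, cell_mask: np.ndarray, center, angle, length_px, width_px) -> np.ndarray:
    """One-pixel-wide stripe along the rod axis (the magnetosome chain)."""
    cy, cx = center
    uy, ux = math.sin(angle), math.cos(angle)
    yy, xx = np.mgrid[0:size, 0:size]
    ry, rx = yy - cy, xx - cx
    ax = ry * uy + rx * ux
    pp = -ry * ux + rx * uy
    half_axis = max(length_px - width_px, 0.0) / 2.0
    return cell_mask & (np.abs(pp) <= 0.5) & (np.abs(ax) <= half_axis)


def generate_scene(
    config: SceneConfig,
    timepoint_h: float,
    replicate: int = 0,
    expectation: bool = False,
) -> tuple[IonImageStack, SceneTruth]:
    """Generate one synthetic six-ion acquisition plus its ground truth.

    Parameters
    ----------
    config
        Scene parameters; ``config.seed`` is the root seed.
    timepoint_h
        Incubation time point (hours); sets the enrichment trajectory value
        and the cell-to-cell spread.
    replicate
        Index distinguishing repeated scenes at the same time point; each
        (seed, timepoint, replicate) triple gives an independent stream.
    expectation
        If True, return the noise-free expectation fields (float counts,
        no Poisson draw) instead of sampled counts — useful for exact
        oracle tests of drift estimation and accumulation.

    Returns
    -------
    (IonImageStack, SceneTruth)
        The stack holds all six ion channels; the truth holds the label
        mask (pre-drift, i.e. plane-0 frame), true per-plane shifts, and
        true per-cell atom fractions and rod dimensions.
    """
    if timepoint_h < 0:
        raise ValueError("timepoint_h must be >= 0")
    rng = _child_rng(config.seed, timepoint_h, replicate)
    size = config.image_size
    px = config.pixel_um

    # --- place non-overlapping rods -------------------------------------
    label = np.zeros((size, size), dtype=np.int32)
    geoms = []  # (center, angle, length_px, width_px)
    occupied = np.zeros((size, size), dtype=bool)
    for k in range(1, config.n_cells + 1):
        placed = False
        for _ in range(config.max_place_tries):
            length_um = rng.uniform(*config.cell_length_um)
            width_um = rng.uniform(*config.cell_width_um)
            width_um = min(width_um, length_um)  # rods: length >= width
            length_px_, width_px_ = length_um / px, width_um / px
            margin = length_px_ / 2 + 2
            if 2 * margin >= size:
                continue
            center = tuple(rng.uniform(margin, size - margin, size=2))
            angle = rng.uniform(0.0, math.pi)
            mask = _rod_mask(size, center, length_px_, width_px_, angle)
            if mask is None or (mask & occupied).any():
                continue
            label[mask] = k
            halo = ndimage.binary_dilation(
                mask, structure=np.ones((3, 3), bool), iterations=config.min_gap_px
            )
            occupied |= halo
            geoms.append((center, angle, length_px_, width_px_, length_um, width_um))
            placed = True
            break
        if not placed:
            raise SceneTooDenseError(
                f"could not place cell {k}/{config.n_cells} without overlap after "
                f"{config.max_place_tries} tries; reduce n_cells or cell size for a "
                f"{size}px/{config.raster_um}um field"
            )

    # --- per-cell isotopic composition ----------------------------------
    spread = config.spread_at(timepoint_h)
    f13 = enrichment_trajectory(timepoint_h, config.enrich_median_coeffs["13C"], spread, config.n_cells, rng)
    f15 = enrichment_trajectory(timepoint_h, config.enrich_median_coeffs["15N"], spread, config.n_cells, rng)

    # --- expectation fields in the plane-0 frame ------------------------
    r12, r14 = config.base_rate["12C"], config.base_rate["12C14N"]
    r16 = config.base_rate["16O"]
    r32 = config.base_rate.get("32S", config.s32_factor * r14)
    nat = config.natural
    bg = config.background_fraction
    fields = {
        "12C": np.full((size, size), bg * r12),
        "13C": np.full((size, size), bg * r12 * nat.r13),
        "12C14N": np.full((size, size), bg * r14),
        "12C15N": np.full((size, size), bg * r14 * nat.r15),
        "16O": np.full((size, size), bg * r16),
        "32S": np.full((size, size), bg * r32),
    }
    for k, (center, angle, length_px_, width_px_, _, _) in enumerate(geoms, start=1):
        m = label == k
        fields["12C"][m] = r12
        fields["13C"][m] = r12 * f13[k - 1] / (1.0 - f13[k - 1])
        fields["12C14N"][m] = r14
        fields["12C15N"][m] = r14 * f15[k - 1] / (1.0 - f15[k - 1])
        fields["16O"][m] = r16
        fields["32S"][m] = r32
        stripe = _chain_stripe(size, m, center, angle, length_px_, width_px_)
        fields["16O"][stripe] = r16 * config.chain_o16_boost

    # --- per-plane drift and Poisson sampling ---------------------------
    shifts: list[tuple[int, int]] = [(0, 0)]
    for _ in range(1, config.n_planes):
        if config.drift_max_px == 0:
            shifts.append((0, 0))
        else:
            dy, dx = rng.integers(-config.drift_max_px, config.drift_max_px + 1, size=2)
            shifts.append((int(dy), int(dx)))

    counts = np.empty((len(ION_LABELS), config.n_planes, size, size), dtype=float)
    for i, ion in enumerate(ION_LABELS):
        base = fields[ion]
        bg_fill = bg * {"12C": r12, "13C": r12 * nat.r13, "12C14N": r14,
                        "12C15N": r14 * nat.r15, "16O": r16, "32S": r32}[ion]
        for p, (dy, dx) in enumerate(shifts):
            lam = base if (dy, dx) == (0, 0) else _translate(base, dy, dx, fill=bg_fill)
            counts[i, p] = lam if expectation else rng.poisson(lam)
    if not expectation:
        counts = counts.astype(np.int64)

    stack = IonImageStack(
        ion_labels=ION_LABELS,
        counts=counts,
        raster_um=config.raster_um,
        dwell_ms=config.dwell_ms,
        timepoint_h=timepoint_h,
    )
    truth = SceneTruth(
        label_mask=label,
        shifts=shifts,
        f13=f13,
        f15=f15,
        lengths_um=np.array([g[4] for g in geoms]),
        widths_um=np.array([g[5] for g in geoms]),
    )
    return stack, truth


# --------------------------------------------------------------------------
# Magnetosome crystal populations


@dataclass
class CrystalMixtureConfig:
    """Gaussian-mixture model of a crystal-length population.

    Each component has a weight, a mean and SD of crystal length (nm), and
    a mean and SD of the shape factor (width/length, truncated to (0, 1]).
    Bimodal two-component settings reproduce the bimodal length
    distributions seen in magnetotactic cells.
    """

    n: int
    weights: tuple[float, ...] = (1.0,)
    length_mean_nm: tuple[float, ...] = (100.0,)
    length_sd_nm: tuple[float, ...] = (10.0,)
    shape_mean: tuple[float, ...] = (0.43,)
    shape_sd: tuple[float, ...] = (0.05,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        k = len(self.weights)
        if not all(len(x) == k for x in (self.length_mean_nm, self.length_sd_nm, self.shape_mean, self.shape_sd)):
            raise ValueError("all per-component tuples must share one length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if any(m <= 0 for m in self.length_mean_nm) or any(s < 0 for s in self.length_sd_nm):
            raise ValueError("length means must be positive, SDs non-negative")
        if any(not (0 < m <= 1) for m in self.shape_mean) or any(s < 0 for s in self.shape_sd):
            raise ValueError("shape-factor means must lie in (0, 1], SDs be non-negative")


def generate_crystal_population(config: CrystalMixtureConfig):
    """Draw a crystal population from the configured length mixture.

    Widths are ``length * shape_factor`` with the shape factor truncated to
    (0, 1], so every crystal satisfies width <= length.
    """
    from .datatypes import CrystalMeasurement

    rng = np.random.default_rng(config.seed)
    comp = rng.choice(len(config.weights), size=config.n, p=config.weights)
    crystals = []
    for c in comp:
        length = 0.0
        while length <= 0:
            length = rng.normal(config.length_mean_nm[c], config.length_sd_nm[c])
        sf = 0.0
        while not (0 < sf <= 1):
            sf = rng.normal(config.shape_mean[c], config.shape_sd[c])
            if config.shape_sd[c] == 0:
                sf = config.shape_mean[c]
                break
        crystals.append(CrystalMeasurement(length_nm=float(length), width_nm=float(length * sf)))
    return crystals
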