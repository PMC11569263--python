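"""Sensitized-emission (3-cube) FRET quantification and NFAT scoring.

FRET: the apparent efficiency is computed pixel-wise from background-
subtracted CFP, YFP and FRET-channel rasters after bleed-through correction,

    E_app = (I_FRET − a·I_YFP − b·I_CFP) / (I_FRET − a·I_YFP + (G − b)·I_CFP)

with per-measurement-day calibration factors: `a` the YFP cross-excitation,
`b` the CFP crosstalk, and `G` the microscope-specific constant relating
sensitized emission to quenched donor signal (2.75 is a typical calibrated
value).  Analysis is gated to pixels whose CFP:YFP ratio lies between
0.1:10 and 10:0.1, i.e. within [0.01, 100] inclusive.

NFAT translocation: cells are scored by the ratio of background-subtracted
nuclear to cytosolic mean intensity and placed into three populations —
inactive (<0.85), homogeneous (0.85-1.15, closed interval), active (>1.15).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FretCalibration",
    "ImageTriple",
    "EappMap",
    "NfatCell",
    "fret_eapp",
    "fret_eapp_map",
    "gate_pixels",
    "subtract_background",
    "nfat_classify",
    "nfat_summarize",
    "measure_nfat_cells",
    "NFAT_INACTIVE_BELOW",
    "NFAT_ACTIVE_ABOVE",
    "GATE_BOUNDS",
]

NFAT_INACTIVE_BELOW = 0.85
NFAT_ACTIVE_ABOVE = 1.15
#: Inclusive CFP:YFP ratio gate, 0.1:10 .. 10:0.1.
GATE_BOUNDS = (0.01, 100.0)


@dataclass(frozen=True)
class FretCalibration:
    """Bleed-through/instrument calibration for 3-cube FRET."""

    a: float  # YFP cross-excitation factor
    b: float  # CFP crosstalk factor
    G: float  # microscope constant

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("calibration factors a, b must be >= 0")
        if self.G <= 0:
            raise ValueError("G must be > 0")


@dataclass
class ImageTriple:
    """CFP/YFP/FRET-channel rasters of one field of view (same shape)."""

    I_CFP: np.ndarray
    I_YFP: np.ndarray
    I_FRET: np.ndarray
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)  # per channel

    def __post_init__(self) -> None:
        self.I_CFP = np.asarray(self.I_CFP, dtype=np.float64)
        self.I_YFP = np.asarray(self.I_YFP, dtype=np.float64)
        self.I_FRET = np.asarray(self.I_FRET, dtype=np.float64)
        if not (self.I_CFP.shape == self.I_YFP.shape == self.I_FRET.shape):
            raise ValueError("channel rasters must share one shape")
        for r in (self.I_CFP, self.I_YFP, self.I_FRET):
            if not np.all(np.isfinite(r)):
                raise ValueError("intensities must be finite")

    def background_subtracted(self) -> "ImageTriple":
        bc, by, bf = self.background
        return ImageTriple(
            subtract_background(self.I_CFP, bc),
            subtract_background(self.I_YFP, by),
            subtract_background(self.I_FRET, bf),
        )


@dataclass
class EappMap:
    """Pixel-wise apparent FRET efficiency with its validity mask."""

    E: np.ndarray
    valid: np.ndarray  # gate passed AND finite denominator

    def summary(self, mask: np.ndarray | None = None, statistic: str = "mean") -> float:
        """Mean (default) or median E_app over valid, non-negative-numerator
        pixels, optionally restricted to a boolean region `mask`."""
        sel = self.valid & (self.E >= 0.0)
        if mask is not None:
            sel &= mask.astype(bool)
        vals = self.E[sel]
        if vals.size == 0:
            return float("nan")
        return float(np.median(vals) if statistic == "median" else np.mean(vals))


def fret_eapp(I_FRET, I_YFP, I_CFP, cal: FretCalibration):
    """Apparent FRET efficiency, scalar or element-wise.

    Assumes backgrounds already subtracted.  Pixels with a zero denominator
    yield NaN (flagged invalid), never an exception.  Negative numerators
    produce E_app < 0 and are preserved as a diagnostic; summaries exclude
    them (see :meth:`EappMap.summary`).
    """
    I_FRET = np.asarray(I_FRET, dtype=np.float64)
    I_YFP = np.asarray(I_YFP, dtype=np.float64)
    I_CFP = np.asarray(I_CFP, dtype=np.float64)
    num = I_FRET - cal.a * I_YFP - cal.b * I_CFP
    den = I_FRET - cal.a * I_YFP + (cal.G - cal.b) * I_CFP
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(den != 0.0, num / np.where(den != 0.0, den, 1.0), np.nan)
    return float(e) if e.ndim == 0 else e


def gate_pixels(I_CFP, I_YFP, bounds: tuple[float, float] = GATE_BOUNDS) -> np.ndarray:
    """Mask of pixels with positive intensities and CFP/YFP ratio in bounds.

    Bounds are inclusive; the defaults encode the 0.1:10 .. 10:0.1 gate.
    """
    I_CFP = np.asarray(I_CFP, dtype=np.float64)
    I_YFP = np.asarray(I_YFP, dtype=np.float64)
    lo, hi = bounds
    pos = (I_CFP > 0) & (I_YFP > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pos, I_CFP / np.where(pos, I_YFP, 1.0), np.nan)
    return pos & (ratio >= lo) & (ratio <= hi)


def subtract_background(raster, background=None, region_mask: np.ndarray | None = None):
    """Background-subtract a raster, clamping negatives to zero.

    `background` is a scalar level; when None it is estimated as the mean
    intensity over `region_mask` (a user-supplied cell-free region).
    """
    raster = np.asarray(raster, dtype=np.float64)
    if background is None:
        if region_mask is None:
            raise ValueError("provide a background level or a cell-free region mask")
        region_mask = np.asarray(region_mask, dtype=bool)
        if not region_mask.any():
            raise ValueError("background region is empty")
        background = float(raster[region_mask].mean())
    if background < 0:
        raise ValueError("background must be >= 0")
    return np.clip(raster - background, 0.0, None)


def fret_eapp_map(
    triple: ImageTriple,
    cal: FretCalibration,
    bounds: tuple[float, float] = GATE_BOUNDS,
    subtract: bool = True,
) -> EappMap:
    """Full pixel pipeline: background subtraction → gating → E_app."""
    t = triple.background_subtracted() if subtract else triple
    valid = gate_pixels(t.I_CFP, t.I_YFP, bounds)
    e = fret_eapp(t.I_FRET, t.I_YFP, t.I_CFP, cal)
    finite = np.isfinite(e)
    return EappMap(E=np.where(finite, e, np.nan), valid=valid & finite)


@dataclass
class NfatCell:
    """One cell's NFAT distribution: nuclear vs cytosolic mean intensity."""

    nucleus_mean: float
    cytosol_mean: float

    @property
    def ratio(self) -> float:
        return self.nucleus_mean / self.cytosol_mean

    @property
    def category(self) -> str:
        return nfat_classify(self.nucleus_mean, self.cytosol_mean)


def nfat_classify(nucleus_mean: float, cytosol_mean: float) -> str:
    """Three-population NFAT score from the nucleus/cytosol intensity ratio."""
    if cytosol_mean <= 0:
        raise ValueError("cytosol mean intensity must be > 0")
    ratio = nucleus_mean / cytosol_mean
    if ratio < NFAT_INACTIVE_BELOW:
        return "inactive"
    if ratio > NFAT_ACTIVE_ABOVE:
        return "active"
    return "homogeneous"


def nfat_summarize(cells: Sequence[NfatCell]) -> dict:
    """Category counts and fractions; fraction-active is the headline figure."""
    if not cells:
        raise ValueError("need at least one cell")
    cats = [c.category for c in cells]
    n = len(cats)
    counts = {k: cats.count(k) for k in ("inactive", "homogeneous", "active")}
    fractions = {k: v / n for k, v in counts.items()}
    return {
        "n_cells": n,
        "counts": counts,
        "fractions": fractions,
        "fraction_active": fractions["active"],
    }


def measure_nfat_cells(
    image: np.ndarray,
    nucleus_labels: np.ndarray,
    cytosol_labels: np.ndarray,
    background: float = 0.0,
) -> list[NfatCell]:
    """Build :class:`NfatCell` records from an intensity image and label masks.

    `nucleus_labels`/`cytosol_labels` are integer label images where label k
    marks cell k's nuclear / cytosolic region (0 = none); both must use the
    same labels.
    """
    img = subtract_background(image, background)
    labels = sorted(set(np.unique(nucleus_labels)) - {0})
    if labels != sorted(set(np.unique(cytosol_labels)) - {0}):
        raise ValueError("nucleus and cytosol label images disagree on cells")
    cells = []
    for k in labels:
        cells.append(
            NfatCell(
                nucleus_mean=float(img[nucleus_labels == k].mean()),
                cytosol_mean=float(img[cytosol_labels == k].mean()),
            )
        )
    return cells
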