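"""Mean telomere length from Southern-blot lane densitometry.

A terminal-restriction-fragment (TRF) smear is digitized as intensity
``NI_i`` versus migration position; a molecular-weight ladder maps each
position to a fragment size ``MW_i`` (kb) via a log-linear fit.  The
mean telomere length is the intensity-weighted harmonic-type mean

    MTL = sum(NI_i) / sum(NI_i / MW_i)

i.e. total mass divided by total molar amount, which equals the
number-weighted mean fragment length.  The formula is applied to the
discretized profile as supplied; sampling must be dense enough across
the smear for the sum to approximate the integral (a few hundred
positions is ample).  Background subtraction is the caller's
responsibility (a rolling-minimum helper is provided, off by default),
and the caller crops the profile to the smear region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import linregress

__all__ = [
    "LadderCalibration",
    "TRFLane",
    "calibrate_ladder",
    "compute_mtl",
    "rolling_min_background",
]


@dataclass
class LadderCalibration:
    """Log-linear migration model: ``log10(MW) = intercept + slope * position``."""

    slope: float
    intercept: float
    r2: float
    ladder_positions: np.ndarray = field(repr=False)
    ladder_mw_kb: np.ndarray = field(repr=False)

    def predict_mw(self, positions: Sequence[float]) -> np.ndarray:
        pos = np.asarray(positions, dtype=float)
        return 10.0 ** (self.intercept + self.slope * pos)

    def predict_position(self, mw_kb: Sequence[float]) -> np.ndarray:
        mw = np.asarray(mw_kb, dtype=float)
        return (np.log10(mw) - self.intercept) / self.slope


def calibrate_ladder(
    ladder_positions: Sequence[float], ladder_mw_kb: Sequence[float]
) -> LadderCalibration:
    """Least-squares line through ``(position, log10 MW)`` for >= 3
    distinct ladder bands."""
    pos = np.asarray(ladder_positions, dtype=float)
    mw = np.asarray(ladder_mw_kb, dtype=float)
    if pos.size < 3:
        raise ValueError("need at least 3 ladder bands")
    if np.unique(pos).size < pos.size:
        raise ValueError("ladder band positions must be distinct")
    if np.any(mw <= 0):
        raise ValueError("ladder molecular weights must be > 0")
    res = linregress(pos, np.log10(mw))
    return LadderCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        ladder_positions=pos,
        ladder_mw_kb=mw,
    )


@dataclass
class TRFLane:
    """One densitometry lane with calibrated molecular weights.

    ``positions`` must be monotone; ``mw_kb`` strictly decreasing with
    migration distance; intensities non-negative and background-
    subtracted.
    """

    positions: np.ndarray
    intensities: np.ndarray
    mw_kb: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mw_kb = np.asarray(self.mw_kb, dtype=float)
        n = self.positions.size
        if self.intensities.size != n or self.mw_kb.size != n:
            raise ValueError("positions, intensities and mw_kb must have equal length")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0 (background-subtracted)")
        if np.any(self.mw_kb <= 0):
            raise ValueError("molecular weights must be > 0")
        d = np.diff(self.positions)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("positions must be strictly monotone")
        dm = np.diff(self.mw_kb) * np.sign(d[0])
        if not np.all(dm < 0):
            raise ValueError("molecular weight must decrease with migration distance")

    @classmethod
    def from_profile(
        cls,
        positions: Sequence[float],
        intensities: Sequence[float],
        calibration: LadderCalibration,
        crop_kb: Optional[tuple[float, float]] = None,
    ) -> "TRFLane":
        """Build a lane from a raw profile and a ladder calibration,
        optionally cropping to a molecular-weight window (kb)."""
        pos = np.asarray(positions, dtype=float)
        inten = np.asarray(intensities, dtype=float)
        mw = calibration.predict_mw(pos)
        if crop_kb is not None:
            lo, hi = min(crop_kb), max(crop_kb)
            keep = (mw >= lo) & (mw <= hi)
            pos, inten, mw = pos[keep], inten[keep], mw[keep]
        return cls(pos, inten, mw)


def compute_mtl(lane: TRFLane) -> float:
    """Mean telomere length (kb): ``sum(NI) / sum(NI / MW)``."""
    total = float(lane.intensities.sum())
    if total <= 0:
        raise ValueError("zero total intensity in the lane")
    return total / float(np.sum(lane.intensities / lane.mw_kb))


def rolling_min_background(
    intensities: Sequence[float], window: int = 25
) -> np.ndarray:
    """Rolling-minimum background estimate (subtract from the raw
    profile before building a :class:`TRFLane`).  Off by default in the
    pipeline; provided as a convenience for raw densitometry exports."""
    arr = np.asarray(intensities, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    return ndimage.minimum_filter1d(arr, size=window, mode="nearest")
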