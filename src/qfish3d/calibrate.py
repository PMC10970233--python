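"""Molecular brightness calibration with DNA-origami standards.

DNA-origami nanostructures carrying a defined number of fluorophores
(by default 17, 34 or 60) are imaged and quantified with the same
settings as the biological samples.  Linear regression of the known
fluorophore counts against the measured mean integrated brightness per
standard yields a conversion factor (fluorophores per brightness
count); multiplying a telomere spot's integrated brightness by this
factor estimates the number of bound probe molecules.  With an 18-nt
telomeric PNA probe (three CCCTAA repeats) each bound probe covers
18 bp of telomeric repeat, converting probe counts to labeled sequence
length, and dividing by an independently measured mean telomere length
(e.g. from terminal-restriction-fragment analysis) gives the labeling
efficiency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

log = logging.getLogger("qfish3d")

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "ProbeModel",
    "summarize_beads",
    "fit_calibration",
    "brightness_to_probes",
    "probes_to_bp",
    "labeling_efficiency",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """Summary of one origami standard."""

    n_fluorophores: float
    mean_brightness: float
    sd_brightness: float
    n_beads: int

    def __post_init__(self) -> None:
        if self.n_fluorophores <= 0:
            raise ValueError("n_fluorophores must be > 0")
        if self.n_beads < 2:
            raise ValueError("n_beads must be >= 2")


@dataclass(frozen=True)
class CalibrationCurve:
    """Brightness -> fluorophore-count linear model.

    ``slope`` is the conversion factor in fluorophores per brightness
    count; ``intercept`` is 0 for through-origin fits.  ``r2`` refers to
    the fluorophores-vs-brightness regression.
    """

    slope: float
    intercept: float
    r2: float
    fit_mode: str = "affine"

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0 (inverted inputs?)")

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "fit_mode": self.fit_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(float(d["slope"]), float(d["intercept"]), float(d["r2"]), d["fit_mode"])


@dataclass(frozen=True)
class ProbeModel:
    """Hybridization model of the telomeric PNA probe.

    The default TelC probe is (CCCTAA)3: three 6-bp repeat units, 18 nt
    hybridized per bound probe.
    """

    probe_length_nt: int = 18
    repeat_unit: str = "TTAGGG"
    target_strand: str = "C-rich probe (CCCTAA)3"

    def __post_init__(self) -> None:
        if self.probe_length_nt <= 0:
            raise ValueError("probe_length_nt must be > 0")


def summarize_beads(brightness: Sequence[float], n_fluorophores: float) -> CalibrationPoint:
    """Summarize the brightness distribution of one origami standard.

    With >= 30 beads, a Gaussian curve is fitted to the brightness
    histogram (Scott's-rule bins, least squares) to retrieve mean and
    SD; smaller samples fall back to the sample mean/SD.  A poor
    normal fit (r^2 < 0.9, e.g. bimodal input) logs a warning.
    """
    values = np.asarray(brightness, dtype=float)
    if values.size == 0:
        raise ValueError("no bead brightness values supplied")
    if values.size < 2:
        raise ValueError("need at least 2 beads per standard")
    mean, sd = float(values.mean()), float(values.std(ddof=1))
    if values.size >= 30 and sd > 0:
        counts, edges = np.histogram(values, bins="scott")
        centers = 0.5 * (edges[:-1] + edges[1:])

        def gauss(x, amp, mu, sigma):
            return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

        try:
            popt, _ = curve_fit(
                gauss,
                centers,
                counts.astype(float),
                p0=(counts.max(), mean, sd),
                bounds=([0, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
                maxfev=5000,
            )
            resid = counts - gauss(centers, *popt)
            ss_tot = np.sum((counts - counts.mean()) ** 2)
            r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
            if r2 < 0.9:
                log.warning(
                    "poor normal fit for the %s-fluorophore standard (r2=%.3f); "
                    "check for aggregates or mixed populations",
                    n_fluorophores,
                    r2,
                )
            mean, sd = float(popt[1]), float(abs(popt[2]))
        except (RuntimeError, ValueError):
            log.warning("normal fit failed; using sample mean/SD")
    return CalibrationPoint(n_fluorophores, mean, sd, int(values.size))


def fit_calibration(
    points: Sequence[CalibrationPoint], through_origin: bool = False
) -> CalibrationCurve:
    """Weighted linear regression of fluorophore counts on brightness.

    Weights are the per-standard bead counts.  The default affine fit
    should have a near-zero intercept (a large intercept signals an
    offset problem and is warned about); ``through_origin`` forces the
    intercept to zero.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 calibration points")
    x = np.array([p.mean_brightness for p in points], dtype=float)
    y = np.array([p.n_fluorophores for p in points], dtype=float)
    w = np.array([p.n_beads for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("calibration points must have distinct brightness values")
    if through_origin:
        slope = float(np.sum(w * x * y) / np.sum(w * x * x))
        intercept = 0.0
    else:
        wm_x = np.average(x, weights=w)
        wm_y = np.average(y, weights=w)
        slope = float(np.sum(w * (x - wm_x) * (y - wm_y)) / np.sum(w * (x - wm_x) ** 2))
        intercept = float(wm_y - slope * wm_x)
    if slope <= 0:
        raise ValueError("negative calibration slope; inputs likely inverted")
    pred = slope * x + intercept
    ss_res = float(np.sum(w * (y - pred) ** 2))
    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if not through_origin and abs(intercept) > 0.1 * y.min():
        log.warning(
            "calibration intercept %.3g exceeds 10%% of the smallest standard "
            "(%.3g fluorophores); the conversion may not be proportional",
            intercept,
            y.min(),
        )
    mode = "through_origin" if through_origin else "affine"
    return CalibrationCurve(slope, intercept, r2, mode)


def brightness_to_probes(integrated_brightness: float, curve: CalibrationCurve) -> float:
    """Convert an integrated spot brightness to a (real-valued)
    fluorophore/probe count; extrapolation beyond the calibration range
    is permitted, negative predictions clip to zero with a warning."""
    value = curve.slope * float(integrated_brightness) + curve.intercept
    if value < 0:
        log.warning("negative probe count %.3g clipped to 0", value)
        return 0.0
    return value


def probes_to_bp(n_probes: float, probe_model: ProbeModel = ProbeModel()) -> int:
    """Labeled telomeric sequence length in bp for a probe count."""
    if n_probes < 0:
        raise ValueError("n_probes must be >= 0")
    return int(round(n_probes * probe_model.probe_length_nt))


def labeling_efficiency(labeled_bp: float, trf_length_bp: float) -> float:
    """Fraction of the telomere covered by bound probes, in percent.

    ``trf_length_bp`` is the mean telomere length from an orthogonal
    measurement (e.g. Southern-blot TRF).  Efficiencies above 100%
    indicate a calibration error and are warned about.
    """
    if trf_length_bp <= 0:
        raise ValueError("trf_length_bp must be > 0")
    pct = 100.0 * labeled_bp / trf_length_bp
    if pct > 100.0:
        log.warning("labeling efficiency %.1f%% exceeds 100%%; check calibration", pct)
    return pct
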