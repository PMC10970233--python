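"""Per-spot feature extraction from orthogonal lateral line profiles.

At the brightest z-plane of each detected spot, two 1D profiles of raw
photon counts are taken through the spot center along the x and y pixel
axes and each is fitted with

    y = a + (b - a) * exp(-(x - c)^2 / (2 d^2))

where ``a`` is the background offset, ``b`` the peak signal level,
``c`` the center and ``d`` the standard deviation in pixels.  Accepted
fits (r^2 above a threshold, default 0.8) yield the per-telomere
readout:

    FWHM              = 2 sqrt(2 ln 2) * d * pixel_size
    fwhm_z            = (fwhm_x + fwhm_y) / 2        (axial proxy)
    volume            = (pi/6) * fwhm_x * fwhm_y * fwhm_z
    integrated        = 2 pi * mean(b_x, b_y) * d_x * d_y
    signal density    = integrated / volume

The axial FWHM is interpolated as the mean of the lateral widths
because the axial sampling (200 nm) is far coarser than the lateral
optical resolution; no axial fit is attempted.

Note on the integral: the printed definition uses the peak *level*
``b`` (which includes the local background) rather than the amplitude
``b - a``.  The default follows that definition exactly so that
brightness calibration performed with identical settings cancels the
offset; ``background_corrected=True`` switches to the amplitude
``mean(b) - mean(a)`` when an absolute photon integral is wanted.
``d`` enters the integral in pixels, making the integral a
counts-times-pixel-area quantity; the calibration stage uses the same
convention so units cancel in molecule counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .core import CellRecord, ImageStack3D, NucleusMask, VoxelGeometry, apply_mask
from .detect import DetectionParams, SpotCandidate, _smooth_array, find_spots

__all__ = [
    "FWHM_FACTOR",
    "ProfileParams",
    "GaussianProfileFit",
    "TelomereFeatures",
    "SpotTooCloseToBorder",
    "brightest_plane",
    "extract_profiles",
    "fit_profile",
    "compute_features",
    "quantify_nucleus",
]

#: FWHM of a Gaussian = FWHM_FACTOR * sigma
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


class SpotTooCloseToBorder(ValueError):
    """The profile window does not fit inside the image."""


@dataclass(frozen=True)
class ProfileParams:
    """Line-profile settings.

    ``line_length_nm`` (default 480 nm, i.e. 16 px at 30 nm pixels) is
    converted to pixels with the stack geometry unless
    ``line_length_px`` is given explicitly.  ``r2_min`` is the
    fit-acceptance threshold.
    """

    line_length_nm: float = 480.0
    line_length_px: Optional[int] = None
    r2_min: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.r2_min < 1:
            raise ValueError("r2_min must be in (0, 1)")
        if self.line_length_px is not None and self.line_length_px < 5:
            raise ValueError("line_length_px must be >= 5")

    def resolve_px(self, geometry: VoxelGeometry) -> int:
        if self.line_length_px is not None:
            return int(self.line_length_px)
        n = int(round(self.line_length_nm / geometry.dx_nm))
        if n < 5:
            raise ValueError("line length shorter than 5 px at this pixel size")
        return n


@dataclass
class GaussianProfileFit:
    """One fitted lateral profile."""

    a: float
    b: float
    c: float
    d: float
    r2: float
    axis: str
    converged: bool = True

    @property
    def sufficient(self) -> bool:
        return self.converged and self.r2 > 0.0


@dataclass
class TelomereFeatures:
    """The per-telomere feature vector.

    Geometry/brightness fields are ``None`` unless the corresponding
    fits were accepted: ``integrated_brightness`` and ``signal_density``
    require both fits (``quality_flag == 'both_fits'``).
    """

    spot_id: int
    z_nm: float
    y_nm: float
    x_nm: float
    n_voxels: int
    peak_counts: float
    brightness_peak: Optional[float] = None
    background_a: Optional[float] = None
    fwhm_x_nm: Optional[float] = None
    fwhm_y_nm: Optional[float] = None
    fwhm_z_nm: Optional[float] = None
    volume_um3: Optional[float] = None
    integrated_brightness: Optional[float] = None
    signal_density: Optional[float] = None
    r2_x: Optional[float] = None
    r2_y: Optional[float] = None
    quality_flag: str = "rejected"


def brightest_plane(
    stack: ImageStack3D,
    spot: SpotCandidate,
    smooth_sigma_px: float = 1.0,
    axial_sigma_px: float = 0.0,
    smoothed: Optional[np.ndarray] = None,
) -> int:
    """z-plane with maximal smoothed value at the spot's rounded lateral
    center, among planes containing member voxels.  Ties go to lower z."""
    sm = (
        np.asarray(smoothed, dtype=float)
        if smoothed is not None
        else _smooth_array(stack.voxels, smooth_sigma_px, axial_sigma_px)
    )
    _, yc, xc = _rounded_center(spot, stack.shape)
    zs = np.unique(spot.member_voxels[:, 0])
    values = sm[zs, yc, xc]
    return int(zs[int(np.argmax(values))])  # argmax takes the first (lowest z) tie


def _rounded_center(spot: SpotCandidate, shape: tuple[int, int, int]) -> tuple[int, int, int]:
    idx = np.rint(np.asarray(spot.center_of_mass)).astype(int)
    return tuple(int(np.clip(idx[i], 0, shape[i] - 1)) for i in range(3))


def extract_profiles(
    stack: ImageStack3D,
    spot: SpotCandidate,
    params: ProfileParams = ProfileParams(),
    z_plane: Optional[int] = None,
    smoothed: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw-count line profiles along x and y, centered on the spot's
    rounded lateral center at its brightest plane.

    Raises :class:`SpotTooCloseToBorder` when the window would clip the
    image; such spots are flagged ``rejected`` downstream.
    """
    n = params.resolve_px(stack.geometry)
    if z_plane is None:
        z_plane = brightest_plane(stack, spot, smoothed=smoothed)
    _, yc, xc = _rounded_center(spot, stack.shape)
    half = n // 2
    offsets = np.arange(n) - half
    x_lo, x_hi = xc + offsets[0], xc + offsets[-1]
    y_lo, y_hi = yc + offsets[0], yc + offsets[-1]
    _, ny, nx = stack.shape
    if x_lo < 0 or y_lo < 0 or x_hi >= nx or y_hi >= ny:
        raise SpotTooCloseToBorder(
            f"profile window of {n} px around ({yc}, {xc}) exceeds image bounds"
        )
    raw = np.asarray(stack.voxels)
    x_profile = raw[z_plane, yc, x_lo : x_hi + 1].astype(float)
    y_profile = raw[z_plane, y_lo : y_hi + 1, xc].astype(float)
    return x_profile, y_profile


def _gauss(x: np.ndarray, a: float, h: float, c: float, d: float) -> np.ndarray:
    return a + h * np.exp(-((x - c) ** 2) / (2.0 * d**2))


def fit_profile(
    profile: np.ndarray, params: ProfileParams = ProfileParams(), axis: str = "x"
) -> GaussianProfileFit:
    """Nonlinear least-squares Gaussian fit of one profile.

    Initialization: ``a = min``, ``b = max``, ``c = argmax``, ``d = 2``
    px; bounds keep ``a >= 0``, ``b > a`` (fitted as amplitude
    ``h = b - a > 0``), ``c`` inside the profile and
    ``0.5 <= d <= len(profile)``.  Non-convergence and degenerate
    (constant) profiles return a fit with ``r2 = 0`` instead of raising.
    """
    y = np.asarray(profile, dtype=float)
    n = y.size
    if n < 5:
        raise ValueError("profile must contain at least 5 samples")
    x = np.arange(n, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    a0 = float(y.min())
    h0 = max(float(y.max() - y.min()), 1e-9)
    c0 = float(np.argmax(y))
    p0 = (a0, h0, c0, 2.0)
    bounds = ([0.0, 1e-12, 0.0, 0.5], [np.inf, np.inf, float(n - 1), float(n)])
    if ss_tot == 0.0:
        return GaussianProfileFit(a0, a0 + h0, c0, 2.0, 0.0, axis, converged=False)
    try:
        popt, _ = curve_fit(_gauss, x, y, p0=p0, bounds=bounds, maxfev=2000)
    except (RuntimeError, ValueError):
        return GaussianProfileFit(a0, a0 + h0, c0, 2.0, 0.0, axis, converged=False)
    a, h, c, d = (float(v) for v in popt)
    ss_res = float(np.sum((y - _gauss(x, a, h, c, d)) ** 2))
    r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return GaussianProfileFit(a, a + h, c, d, min(r2, 1.0), axis)


def compute_features(
    fit_x: GaussianProfileFit,
    fit_y: GaussianProfileFit,
    geometry: VoxelGeometry,
    params: ProfileParams = ProfileParams(),
    *,
    spot_id: int = 0,
    center_nm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    n_voxels: int = 0,
    peak_counts: float = 0.0,
    background_corrected: bool = False,
) -> TelomereFeatures:
    """Combine the two lateral fits into the feature vector.

    * both fits accepted: full feature set; the reported peak brightness
      and background come from the fit with higher r^2, while the volume
      and the 2D integral use both axes;
    * one fit accepted: peak brightness and that axis's FWHM only;
    * neither accepted: flag ``rejected``, only the r^2 fields kept.
    """
    feat = TelomereFeatures(
        spot_id=spot_id,
        z_nm=center_nm[0],
        y_nm=center_nm[1],
        x_nm=center_nm[2],
        n_voxels=n_voxels,
        peak_counts=peak_counts,
        r2_x=fit_x.r2,
        r2_y=fit_y.r2,
    )
    ok_x = fit_x.converged and fit_x.r2 > params.r2_min
    ok_y = fit_y.converged and fit_y.r2 > params.r2_min
    if not ok_x and not ok_y:
        return feat

    better = fit_x if (fit_x.r2 >= fit_y.r2 and ok_x) or not ok_y else fit_y
    feat.brightness_peak = better.b
    feat.background_a = better.a

    if ok_x:
        feat.fwhm_x_nm = FWHM_FACTOR * fit_x.d * geometry.dx_nm
    if ok_y:
        feat.fwhm_y_nm = FWHM_FACTOR * fit_y.d * geometry.dy_nm

    if ok_x and ok_y:
        feat.quality_flag = "both_fits"
        feat.fwhm_z_nm = 0.5 * (feat.fwhm_x_nm + feat.fwhm_y_nm)
        vol_nm3 = (math.pi / 6.0) * feat.fwhm_x_nm * feat.fwhm_y_nm * feat.fwhm_z_nm
        feat.volume_um3 = vol_nm3 * 1e-9
        if background_corrected:
            level = 0.5 * (fit_x.b + fit_y.b) - 0.5 * (fit_x.a + fit_y.a)
        else:
            level = 0.5 * (fit_x.b + fit_y.b)
        feat.integrated_brightness = 2.0 * math.pi * level * fit_x.d * fit_y.d
        feat.signal_density = feat.integrated_brightness / feat.volume_um3
    else:
        feat.quality_flag = "single_fit"
    return feat


def quantify_nucleus(
    stack: ImageStack3D,
    mask: Optional[NucleusMask] = None,
    det_params: DetectionParams = DetectionParams(),
    prof_params: ProfileParams = ProfileParams(),
    *,
    cell_id: str = "cell",
    phase: str = "unknown",
    background_corrected: bool = False,
) -> CellRecord:
    """End-to-end single-nucleus pipeline: mask, detect, fit, quantify.

    Spots whose fits fail or that sit too close to the border are kept
    in the output with ``quality_flag='rejected'``; per-cell summaries
    downstream use non-rejected spots only.
    """
    work = apply_mask(stack, mask) if mask is not None else stack
    sm = _smooth_array(work.voxels, det_params.smooth_sigma_px, det_params.axial_sigma_px)
    spots = find_spots(work, det_params, smoothed=sm)
    features: list[TelomereFeatures] = []
    for i, spot in enumerate(spots):
        center_nm = tuple(work.index_to_nm(spot.center_of_mass))
        base = dict(
            spot_id=i,
            center_nm=center_nm,
            n_voxels=spot.n_voxels,
            peak_counts=spot.peak_smoothed_value,
        )
        try:
            z_plane = brightest_plane(work, spot, smoothed=sm)
            x_prof, y_prof = extract_profiles(work, spot, prof_params, z_plane=z_plane)
        except SpotTooCloseToBorder:
            features.append(
                TelomereFeatures(
                    spot_id=i,
                    z_nm=center_nm[0],
                    y_nm=center_nm[1],
                    x_nm=center_nm[2],
                    n_voxels=spot.n_voxels,
                    peak_counts=spot.peak_smoothed_value,
                )
            )
            continue
        fit_x = fit_profile(x_prof, prof_params, axis="x")
        fit_y = fit_profile(y_prof, prof_params, axis="y")
        features.append(
            compute_features(
                fit_x,
                fit_y,
                work.geometry,
                prof_params,
                background_corrected=background_corrected,
                **base,
            )
        )
    return CellRecord(cell_id=cell_id, phase=phase, features=features)
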