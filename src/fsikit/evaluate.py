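"""Image-quality evaluation: resolution, sensitivity, and imaging depth.

Mirrors the bench procedures used to characterize a single-pixel
dual-modality imager:

* spatial resolution -- a Gaussian is fitted to an intensity profile drawn
  across a thin-wire image; resolution is reported as the fit's full width
  at half maximum, ``FWHM = 2*sqrt(2*ln 2) * sigma * pitch`` (mm);
* fluorescence sensitivity -- 5x5-pixel ROI means over a serial-dilution
  well row, an ordinary-least-squares calibration line with R², and a
  detection limit defined as the lowest concentration whose ROI mean
  exceeds the blank mean by three blank standard deviations;
* imaging depth -- tube-versus-background contrast-to-noise ratio with a
  Rose-criterion detectability threshold (CNR >= 5 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, stats

__all__ = [
    "ProfileFit",
    "CalibrationFit",
    "DetectabilityResult",
    "GaussianFitError",
    "line_profile",
    "fit_gaussian_fwhm",
    "roi_mean",
    "roi_stats",
    "fit_calibration",
    "detection_limit",
    "depth_detectability",
    "FWHM_PER_SIGMA",
]

#: FWHM of a Gaussian in units of its sigma: 2*sqrt(2*ln 2).
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class GaussianFitError(RuntimeError):
    """Raised when the profile fit cannot converge; carries the initial guess."""

    def __init__(self, message: str, p0=None, residual=None):
        super().__init__(message)
        self.p0 = p0
        self.residual = residual


@dataclass(frozen=True)
class ProfileFit:
    """Gaussian profile fit.  ``amplitude`` is signed: negative for a dip."""

    amplitude: float
    center_px: float
    sigma_px: float
    baseline: float
    pitch_mm: float
    residual_rms: float

    @property
    def fwhm_mm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_px * self.pitch_mm

    @property
    def fwhm_px(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_px


@dataclass(frozen=True)
class CalibrationFit:
    """OLS calibration of ROI intensity against concentration."""

    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    concentrations: tuple[float, ...]
    roi_means: tuple[float, ...]

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the slope (t distribution, n-2 dof)."""
        n = len(self.concentrations)
        t = stats.t.ppf(0.5 + level / 2.0, n - 2)
        return self.slope - t * self.slope_stderr, self.slope + t * self.slope_stderr


@dataclass(frozen=True)
class DetectabilityResult:
    contrast: float  # contrast-to-noise ratio (mean_tube - mean_bg) / sd_bg
    detectable: bool
    threshold: float


def line_profile(image: np.ndarray, start, end) -> np.ndarray:
    """Bilinear intensity profile from ``start`` to ``end`` at unit-pixel steps.

    Points are (row, col) and must lie inside the image; both endpoints are
    included (the last step may be shorter than one pixel).
    """
    image = np.asarray(image, dtype=np.float64)
    r0, c0 = float(start[0]), float(start[1])
    r1, c1 = float(end[0]), float(end[1])
    M, N = image.shape
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= M - 1 and 0 <= c <= N - 1):
            raise ValueError(f"endpoint ({r}, {c}) outside {M}x{N} image")
    length = math.hypot(r1 - r0, c1 - c0)
    if length == 0:
        raise ValueError("zero-length line segment")
    t = np.arange(0.0, length, 1.0)
    if length - t[-1] > 1e-9:
        t = np.append(t, length)
    rows = r0 + (r1 - r0) * t / length
    cols = c0 + (c1 - c0) * t / length
    return ndimage.map_coordinates(image, [rows, cols], order=1, mode="nearest")


def _gauss(t, amplitude, center, sigma, baseline):
    return amplitude * np.exp(-((t - center) ** 2) / (2.0 * sigma**2)) + baseline


def fit_gaussian_fwhm(profile: np.ndarray, pitch_mm: float) -> ProfileFit:
    """Least-squares Gaussian fit of a 1-D profile; FWHM reported in mm.

    Polarity (absorption dip vs emission peak) is auto-detected as the sign
    of the extremum farthest from the profile median; a dip is fitted on
    the negated profile and reported with negative amplitude.
    Initialization: baseline = median, amplitude = extremum - baseline,
    center = extremum location, sigma = half the width above half-extremum.
    """
    profile = np.asarray(profile, dtype=np.float64)
    if profile.ndim != 1 or len(profile) < 5:
        raise ValueError("profile must be 1-D with at least 5 samples")
    med = float(np.median(profile))
    idx = int(np.argmax(np.abs(profile - med)))
    sign = 1.0 if profile[idx] >= med else -1.0
    work = sign * profile
    baseline0 = float(np.median(work))
    amp0 = float(work[idx] - baseline0)
    span = float(profile.max() - profile.min())
    if span == 0 or abs(amp0) < 1e-12 * max(abs(baseline0), 1.0):
        raise GaussianFitError("profile has no peak or dip to fit", p0=None)
    above = np.flatnonzero(work > baseline0 + 0.5 * amp0)
    width = float(above[-1] - above[0] + 1) if len(above) else 1.0
    sigma0 = max(width / 2.0, 0.5)
    p0 = (amp0, float(idx), sigma0, baseline0)
    t = np.arange(len(profile), dtype=np.float64)
    try:
        popt, _ = optimize.curve_fit(_gauss, t, work, p0=p0, maxfev=10000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        res = float(np.sqrt(np.mean((work - _gauss(t, *p0)) ** 2)))
        raise GaussianFitError(f"Gaussian fit failed to converge: {exc}",
                               p0=p0, residual=res) from exc
    amp, center, sigma, baseline = popt
    sigma = abs(float(sigma))
    if sigma <= 0 or not np.isfinite(sigma):
        raise GaussianFitError("fit collapsed to non-positive width", p0=p0)
    resid = float(np.sqrt(np.mean((work - _gauss(t, *popt)) ** 2)))
    return ProfileFit(
        amplitude=sign * float(amp),
        center_px=float(center),
        sigma_px=sigma,
        baseline=sign * float(baseline),
        pitch_mm=float(pitch_mm),
        residual_rms=resid,
    )


def _roi_slices(image: np.ndarray, center, window: int) -> tuple[slice, slice]:
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    r, c = int(round(center[0])), int(round(center[1]))
    h = window // 2
    M, N = image.shape
    if not (h <= r <= M - 1 - h and h <= c <= N - 1 - h):
        raise ValueError(f"{window}x{window} window at ({r}, {c}) clipped by image border")
    return slice(r - h, r + h + 1), slice(c - h, c + h + 1)


def roi_mean(image: np.ndarray, center, window: int = 5) -> float:
    """Arithmetic mean over a ``window`` x ``window`` region centred at ``center``."""
    image = np.asarray(image, dtype=np.float64)
    sr, sc = _roi_slices(image, center, window)
    return float(image[sr, sc].mean())


def roi_stats(image: np.ndarray, center, window: int = 5) -> tuple[float, float]:
    """(mean, sample standard deviation) over the ROI window."""
    image = np.asarray(image, dtype=np.float64)
    sr, sc = _roi_slices(image, center, window)
    block = image[sr, sc]
    return float(block.mean()), float(block.std(ddof=1))


def fit_calibration(concentrations, roi_means) -> CalibrationFit:
    """Ordinary least squares of ROI mean against concentration, with R².

    The caller selects which points to fit (typically the detectable
    subset); at least three are required and the concentrations must not
    all coincide.
    """
    x = np.asarray(concentrations, dtype=np.float64)
    y = np.asarray(roi_means, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and roi_means must be matching 1-D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a calibration fit")
    if np.ptp(x) == 0:
        raise ValueError("all concentrations are equal; calibration is undefined")
    res = stats.linregress(x, y)
    # constant y: SS_tot = 0 makes the correlation undefined; by the
    # R^2 = 1 - SS_res/SS_tot convention the fit explains nothing -> 0
    r2 = float(res.rvalue**2) if np.ptp(y) > 0 else 0.0
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        slope_stderr=stderr,
        concentrations=tuple(x),
        roi_means=tuple(y),
    )


def detection_limit(concentrations, roi_means, blank_mean: float, blank_sd: float) -> float:
    """Lowest concentration whose ROI mean exceeds blank mean + 3 blank SDs.

    Returns ``inf`` when no sample clears the threshold.  Blank statistics
    come from the pure-water well's own ROI pixels.
    """
    thresh = blank_mean + 3.0 * blank_sd
    detectable = [c for c, m in zip(concentrations, roi_means) if c > 0 and m > thresh]
    return min(detectable) if detectable else float("inf")


def depth_detectability(image: np.ndarray, tube_mask: np.ndarray,
                        background_mask: np.ndarray,
                        threshold: float = 5.0) -> DetectabilityResult:
    """Tube-vs-background contrast-to-noise ratio with a Rose-type threshold.

    ``contrast = (mean_tube - mean_bg) / sd_bg``; the object counts as
    detectable when the CNR reaches ``threshold`` (default 5, the Rose
    criterion).  Invariant under affine intensity changes of the image.
    """
    image = np.asarray(image, dtype=np.float64)
    tube_mask = np.asarray(tube_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if tube_mask.shape != image.shape or background_mask.shape != image.shape:
        raise ValueError("masks must match the image shape")
    if np.any(tube_mask & background_mask):
        raise ValueError("tube and background masks overlap")
    if not tube_mask.any() or not background_mask.any():
        raise ValueError("masks must be non-empty")
    mean_t = float(image[tube_mask].mean())
    bg = image[background_mask]
    mean_b = float(bg.mean())
    sd_b = float(bg.std(ddof=1))
    if sd_b == 0.0:
        contrast = float("inf") if mean_t > mean_b else 0.0
    else:
        contrast = (mean_t - mean_b) / sd_b
    return DetectabilityResult(
        contrast=contrast,
        detectable=bool(contrast >= threshold),
        threshold=float(threshold),
    )
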