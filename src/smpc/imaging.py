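"""Single-molecule counting from fluorescence field-of-view images.

The counting chain is: average the acquisition frames, subtract the
background, detect diffraction-limited spots as thresholded local
maxima, and — beyond the density ceiling where individual spots overlap
(default 12,000 per 100 x 100 um^2 FOV) — extrapolate the count from the
integrated fluorescence intensity via a linear calibration fitted in the
countable regime.

Robust (median/MAD) statistics are used for the background throughout,
because spot pixels are outliers of the background distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.feature import peak_local_max
from skimage.restoration import rolling_ball

__all__ = [
    "FovImage",
    "SpotMap",
    "IntensityCalibration",
    "ExtrapolatedCount",
    "DEFAULT_CEILING",
    "average_frames",
    "subtract_background",
    "detect_spots",
    "integrate_intensity",
    "calibrate_intensity_to_count",
    "extrapolate_count",
    "snr",
    "interchip_cv",
]

#: Upper limit for direct identification of diffraction-limited spots
#: in a 100 x 100 um^2 FOV.
DEFAULT_CEILING = 12_000

_MAD_SCALE = 1.4826  # MAD -> sd for a Gaussian


@dataclass
class FovImage:
    """A field-of-view image (2-D) or frame stack (3-D, frames first).

    ``noise_sd`` is an optional robust estimate of the pixel-noise scale,
    filled in by :func:`subtract_background` (from the lower residual
    side, which fluorescence cannot contaminate) and consumed by
    :func:`detect_spots` for thresholding.
    """

    pixels: np.ndarray
    um_per_px: float = 0.1
    channel: int = 532  # excitation wavelength label, 488 or 532 nm
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2-D or a 3-D frame stack")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")

    @property
    def n_frames(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[0]

    @property
    def fov_um(self) -> float:
        return self.pixels.shape[-1] * self.um_per_px


@dataclass
class SpotMap:
    """Detected spots: (x, y) pixel coordinates, count and total signal."""

    coordinates: np.ndarray     # (n, 2) as (x=column, y=row), 0-based
    count: int
    total_intensity: float
    saturated: bool = False


@dataclass
class IntensityCalibration:
    """Linear count ~ intensity relation fitted in the countable regime."""

    slope: float                # counts per a.u.
    intercept: float            # counts
    valid_range: tuple[float, float]
    r_squared: float


@dataclass
class ExtrapolatedCount:
    count: int
    extrapolated: bool          # True when outside the calibrated range


def average_frames(stack: FovImage) -> FovImage:
    """Per-pixel arithmetic mean over the acquisition frames.

    Averaging the (default five) 100-ms frames reduces random pixel
    noise by ~sqrt(n_frames). Single-frame input is returned unchanged.
    """
    if stack.pixels.ndim == 2:
        return stack
    if stack.pixels.shape[0] == 0:
        raise ValueError("empty frame stack")
    return FovImage(pixels=stack.pixels.mean(axis=0),
                    um_per_px=stack.um_per_px, channel=stack.channel)


def subtract_background(
    image: FovImage, method: str = "median", window: int = 11
) -> FovImage:
    """Remove the slowly varying background, clipping residuals at zero.

    ``method='median'`` subtracts a median-filtered copy (window must
    exceed the PSF footprint so spots are rejected from the estimate);
    ``'rolling-ball'`` uses the classic rolling-ball estimator with the
    window as ball radius; ``'global'`` subtracts a single sigma-clipped
    background level, which stays unbiased even when spots cover most of
    the FOV (the regime where counts are read from integrated intensity,
    and where any local filter absorbs real signal).
    """
    if window < 3:
        raise ValueError("background window must be at least 3 px")
    if image.pixels.ndim != 2:
        raise ValueError("subtract_background expects a single 2-D image")
    if method == "median":
        bg = ndimage.median_filter(image.pixels, size=window)
    elif method == "rolling-ball":
        bg = rolling_ball(image.pixels, radius=window)
    elif method == "global":
        bg = _global_background(image.pixels)
    else:
        raise ValueError(f"unknown background method {method!r}")
    resid = image.pixels - bg
    # noise scale from the lower residual side, before clipping: spots
    # only add signal, so this stays valid at any spot density
    med_r = float(np.median(resid))
    noise_sd = med_r - float(np.quantile(resid, 0.1587))
    sub = np.clip(resid, 0.0, None)
    return FovImage(pixels=sub, um_per_px=image.um_per_px,
                    channel=image.channel, noise_sd=max(noise_sd, 0.0))


def _robust_background(pixels: np.ndarray) -> tuple[float, float]:
    """Robust (median, sd) of the background pixel distribution.

    The sd is the median-to-84.1th-percentile distance, which equals one
    Gaussian sigma and — unlike the MAD — stays valid when the negative
    half of the noise has been clipped to zero by background subtraction.
    Spot pixels are removed by iterative sigma clipping so the estimate
    holds even when spots cover a substantial fraction of the FOV.
    """
    x = np.asarray(pixels, dtype=float).ravel()
    med = sd = 0.0
    for _ in range(100):
        med = float(np.median(x))
        sd = float(np.quantile(x, 0.8413)) - med
        if sd == 0:  # fall back to the MAD for degenerate distributions
            sd = _MAD_SCALE * float(np.median(np.abs(x - med)))
        if sd == 0:
            break
        keep = x <= med + 3.5 * sd
        if keep.all():
            break
        x = x[keep]
    return med, sd


def _global_background(pixels: np.ndarray) -> float:
    """Sigma-clipped constant background level.

    The noise scale is taken from the lower quantile side of the
    distribution, which fluorescent spots (a purely additive signal)
    cannot contaminate; pixels above median + 3 sd are then clipped and
    the estimate iterated to convergence.
    """
    x = np.asarray(pixels, dtype=float).ravel()
    med = 0.0
    for _ in range(100):
        med = float(np.median(x))
        sd = med - float(np.quantile(x, 0.1587))
        if sd <= 0:
            break
        keep = x <= med + 3.0 * sd
        if keep.all():
            break
        x = x[keep]
    return med


def detect_spots(
    image: FovImage,
    threshold_k: float = 5.0,
    min_separation: int = 2,
    ceiling: int = DEFAULT_CEILING,
) -> SpotMap:
    """Count single-molecule spots as thresholded local maxima.

    Operates on a background-subtracted image. Peaks must exceed the
    robust background mean plus ``threshold_k`` robust standard
    deviations, and non-maximum suppression removes peaks closer than
    ``min_separation`` px. When more than ``ceiling`` peaks are found the
    map is flagged saturated and the count capped: at such densities
    overlap makes direct identification unreliable and the
    intensity-extrapolation route should be used instead.
    """
    px = image.pixels
    if px.ndim != 2:
        raise ValueError("detect_spots expects a single 2-D image")
    if image.noise_sd is not None:
        med, sd = float(np.median(px)), image.noise_sd
    else:
        med, sd = _robust_background(px)
    thr = med + threshold_k * sd
    if sd == 0:
        thr = med + threshold_k * 1e-12
    peaks = peak_local_max(
        px, min_distance=int(min_separation), threshold_abs=thr,
        exclude_border=False,
    )
    if len(peaks) and sd > 0:
        # PSF confirmation: a diffraction-limited spot keeps most of its
        # height under a sigma-1 Gaussian smooth, while a single-pixel
        # noise excursion collapses to ~16% of its height. This rejects
        # the rare >k-sigma pixel that a megapixel FOV produces by chance.
        smooth = ndimage.gaussian_filter(px, sigma=1.0)
        sd_sm = 0.2821 * sd  # white-noise attenuation of a sigma-1 kernel
        med_sm = float(np.median(smooth))
        keep = smooth[peaks[:, 0], peaks[:, 1]] >= med_sm + threshold_k * sd_sm
        peaks = peaks[keep]
    coords = peaks[:, ::-1].astype(float)  # (row, col) -> (x, y)
    count = len(coords)
    saturated = count > ceiling
    if saturated:
        count = ceiling
    return SpotMap(
        coordinates=coords,
        count=count,
        total_intensity=integrate_intensity(image),
        saturated=saturated,
    )


def integrate_intensity(image: FovImage) -> float:
    """Total fluorescence signal over all pixels of a subtracted image."""
    if image.pixels.ndim != 2:
        raise ValueError("integrate_intensity expects a single 2-D image")
    return float(image.pixels.sum())


def calibrate_intensity_to_count(pairs) -> IntensityCalibration:
    """Least-squares line through (count, total intensity) pairs.

    The relation is fitted only on sub-ceiling data, where counting is
    direct; it is later used to extrapolate counts above the ceiling.
    Requires at least 3 pairs with non-degenerate variation.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (count, intensity) pairs")
    counts, intensity = arr[:, 0], arr[:, 1]
    if np.ptp(intensity) == 0 or np.ptp(counts) == 0:
        raise ValueError("degenerate calibration data (zero variance)")
    fit = stats.linregress(intensity, counts)
    if fit.slope <= 0:
        raise ValueError("calibration slope must be positive")
    return IntensityCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        valid_range=(float(intensity.min()), float(intensity.max())),
        r_squared=float(fit.rvalue**2),
    )


def extrapolate_count(
    total_intensity: float, calibration: IntensityCalibration
) -> ExtrapolatedCount:
    """Convert an integrated intensity to a spot count via the calibration.

    The count is ``max(0, slope * I + intercept)`` rounded half-up to an
    integer; intensities above the calibrated range are flagged as
    extrapolated (that is the intended use beyond the counting ceiling).
    """
    if calibration is None:
        raise ValueError("calibration is required")
    if total_intensity < 0:
        raise ValueError("total_intensity must be non-negative")
    raw = calibration.slope * total_intensity + calibration.intercept
    count = int(math.floor(max(0.0, raw) + 0.5))
    return ExtrapolatedCount(
        count=count,
        extrapolated=total_intensity > calibration.valid_range[1],
    )


def snr(image: FovImage, spots: SpotMap) -> float:
    """Signal-to-noise ratio of detected spots.

    Mean peak amplitude at the spot coordinates divided by the robust
    standard deviation of spot-free pixels (pixels further than 4 px from
    any spot). Returns ``inf`` when the spot-free noise is exactly zero;
    raises on a spot-free map where the ratio is undefined.
    """
    if spots.count == 0 or len(spots.coordinates) == 0:
        raise ValueError("SNR is undefined without detected spots")
    px = image.pixels
    mask = np.zeros(px.shape, dtype=bool)
    cols = spots.coordinates[:, 0].round().astype(int).clip(0, px.shape[1] - 1)
    rows = spots.coordinates[:, 1].round().astype(int).clip(0, px.shape[0] - 1)
    mask[rows, cols] = True
    near_spot = ndimage.binary_dilation(mask, iterations=4)
    free = px[~near_spot]
    if free.size == 0:
        raise ValueError("no spot-free pixels to estimate noise")
    _, noise_sd = _robust_background(free)
    peak_mean = float(px[rows, cols].mean())
    if noise_sd == 0:
        return math.inf
    return peak_mean / noise_sd


def interchip_cv(replicate_counts) -> float:
    """Inter-chip coefficient of variation, in percent.

    ``100 * sample sd / mean`` over replicate counts of the same assay on
    independent chips. Scale-invariant; requires >= 2 replicates and a
    non-zero mean.
    """
    x = np.asarray(replicate_counts, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicates for a c.v.")
    mean = x.mean()
    if mean == 0:
        raise ValueError("c.v. undefined for zero-mean counts")
    return float(100.0 * x.std(ddof=1) / mean)
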