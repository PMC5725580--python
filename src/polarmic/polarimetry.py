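"""Core polarization math shared by both imaging modalities.

Two experimental geometries are supported:

* **EA-TIRFM** — polarized excitation with two-camera detection of emission
  parallel and perpendicular to the excitation axis.  The observable is the
  emission anisotropy ``r = (I_par - I_perp) / (I_par + 2 I_perp)``, where the
  perpendicular intensity is counted twice because emission has two planes
  perpendicular to the parallel one; ``r`` lies in [-0.5, 1].

* **FluoPolScope** — isotropic (circularly polarized) excitation with
  simultaneous four-quadrant detection at analyzer angles 0/45/90/135°.  The
  observables are the in-plane dipole orientation θ and the polarization
  factor ``p`` (fractional intensity modulation, in [0, 1]).

This module also provides the instrument calibrations both modalities need:
half-Gaussian background estimation from the image histogram, the G-factor
from an isotropic dye solution, and four-quadrant throughput/registration/
background calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage, optimize, stats
from skimage import transform as sktransform

from .angles import fold180

__all__ = [
    "BackgroundModel",
    "PolarPairStack",
    "QuadStack",
    "AnisotropyMap",
    "QuadPolarization",
    "estimate_background",
    "subtract_background",
    "g_factor_from_isotropic",
    "anisotropy",
    "region_snr",
    "quad_calibrate",
    "quad_polarization",
    "anisotropy_intensity_diagnostic",
]

#: Pixels whose total intensity is at or below this many background standard
#: deviations are excluded from anisotropy maps ("above 4 times the background
#: standard deviation").
INTENSITY_GATE_SDS = 4.0

#: Regions with signal-to-noise ratio strictly below this are excluded;
#: SNR exactly at the boundary is kept.
SNR_CUTOFF = 5.0


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

def _as_stack(a) -> np.ndarray:
    """Promote a 2-D image to a single-frame (1, H, W) stack."""
    a = np.asarray(a, dtype=float)
    if a.ndim == 2:
        a = a[None]
    if a.ndim != 3:
        raise ValueError(f"expected 2-D image or 3-D stack, got shape {a.shape}")
    return a


@dataclass
class BackgroundModel:
    """Gaussian background intensity model.

    ``mask_threshold`` is mu + 3 sigma; pixels at or below it are treated as
    background when building masks.
    """

    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def mask_threshold(self) -> float:
        return self.mu + 3.0 * self.sigma

    def background_mask(self, image) -> np.ndarray:
        """Boolean mask of background pixels (at or below the threshold)."""
        return np.asarray(image, dtype=float) <= self.mask_threshold

    def foreground_mask(self, image) -> np.ndarray:
        return ~self.background_mask(image)


@dataclass
class PolarPairStack:
    """Registered parallel/perpendicular image time series (EA-TIRFM)."""

    I_par: np.ndarray
    I_perp: np.ndarray
    g_factor: float = 1.0
    pixel_size: float = 109.0  # nm
    registration_transform: object | None = None

    def __post_init__(self):
        self.I_par = _as_stack(self.I_par)
        self.I_perp = _as_stack(self.I_perp)
        if self.I_par.shape != self.I_perp.shape:
            raise ValueError("parallel and perpendicular channels must share shape")
        if np.ndim(self.g_factor) == 0 and not self.g_factor > 0:
            raise ValueError("g_factor must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.I_par.shape[0]

    @property
    def total_intensity(self) -> np.ndarray:
        """I_par + 2 I_perp (G-corrected), the anisotropy denominator."""
        return self.I_par + 2.0 * self.g_factor * self.I_perp


@dataclass
class QuadStack:
    """Registered, throughput-normalized four-channel series (FluoPolScope).

    Channels are ordered by analyzer angle: I0, I45, I90, I135.
    """

    I0: np.ndarray
    I45: np.ndarray
    I90: np.ndarray
    I135: np.ndarray
    pixel_size: float = 70.0  # nm
    throughput_factors: Sequence[float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self):
        chans = [_as_stack(c) for c in (self.I0, self.I45, self.I90, self.I135)]
        if len({c.shape for c in chans}) != 1:
            raise ValueError("the four channels must share dimensions")
        self.I0, self.I45, self.I90, self.I135 = chans
        if np.any(np.asarray(self.throughput_factors, dtype=float) <= 0):
            raise ValueError("throughput_factors must be positive")

    @property
    def n_frames(self) -> int:
        return self.I0.shape[0]

    @property
    def channels(self) -> np.ndarray:
        return np.stack([self.I0, self.I45, self.I90, self.I135])

    @property
    def total_intensity(self) -> np.ndarray:
        return self.I0 + self.I45 + self.I90 + self.I135


@dataclass
class AnisotropyMap:
    """Per-pixel anisotropy with a validity mask (intensity/SNR gates)."""

    r: np.ndarray
    valid: np.ndarray
    total_intensity: np.ndarray | None = None

    def __post_init__(self):
        self.r = _as_stack(self.r)
        self.valid = _as_stack(self.valid).astype(bool)
        if self.r.shape != self.valid.shape:
            raise ValueError("r and validity mask must share shape")


# --------------------------------------------------------------------------
# background estimation
# --------------------------------------------------------------------------

def _gauss(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def estimate_background(image, n_bins: int = 256) -> BackgroundModel:
    """Estimate the background distribution from the image histogram.

    A Gaussian is fitted to the *left* shoulder of the intensity histogram —
    the bins at or below the histogram peak — so bright foreground in the
    right tail does not bias the estimate.

    Parameters
    ----------
    image : array_like
        Single frame or stack; at least 1000 finite pixels.
    n_bins : int
        Histogram resolution over the sub-99.5th-percentile range.

    Returns
    -------
    BackgroundModel

    Raises
    ------
    ValueError
        If the histogram is degenerate and no half-Gaussian can be fitted.
    """
    x = np.asarray(image, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 1000:
        raise ValueError("need at least 1000 finite pixels to estimate background")
    if np.ptp(x) == 0:
        # constant image: delta distribution
        return BackgroundModel(mu=float(x[0]), sigma=0.0)

    # robust bracket around the (assumed majority) background mode, so a
    # bright foreground tail does not stretch the histogram bins
    med = float(np.median(x))
    sigma0 = 1.4826 * float(np.median(np.abs(x - med)))
    if sigma0 == 0:
        below = x[x <= med]
        return BackgroundModel(mu=med, sigma=float(np.std(below)))
    lo = max(float(np.min(x)), med - 8.0 * sigma0)
    hi = med + 8.0 * sigma0
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    ipk = int(np.argmax(counts))
    mu0 = float(centers[ipk])

    below = x[x <= mu0]
    if below.size == 0 or np.ptp(below) == 0:
        # peak sits at the minimum: effectively a delta background
        return BackgroundModel(mu=mu0, sigma=0.0)
    # half-normal moment: E[(mu - X)^2 | X < mu] = sigma^2
    sig0 = float(np.sqrt(np.mean((mu0 - below) ** 2)))
    if sig0 == 0:
        return BackgroundModel(mu=mu0, sigma=0.0)

    sel = centers <= mu0 + 0.25 * sig0
    if np.count_nonzero(sel) < 4:
        sel = np.zeros_like(sel)
        sel[: ipk + 3] = True
    try:
        popt, _ = optimize.curve_fit(
            _gauss, centers[sel], counts[sel],
            p0=[float(counts[ipk]), mu0, sig0],
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - degenerate histograms
        raise ValueError(f"background half-Gaussian fit failed: {exc}") from exc
    _, mu, sigma = popt
    sigma = abs(float(sigma))
    if not np.isfinite(mu) or not np.isfinite(sigma):
        raise ValueError("background half-Gaussian fit returned non-finite values")
    return BackgroundModel(mu=float(mu), sigma=sigma)


def subtract_background(stack, bg: BackgroundModel) -> np.ndarray:
    """Subtract the mean background intensity frame by frame.

    The background mask (pixels at or below mu + 3 sigma) is evaluated on each
    frame; its mean intensity is subtracted from that frame.  Frames with an
    empty background mask fall back to subtracting ``bg.mu``.
    """
    out = _as_stack(stack).copy()
    for t in range(out.shape[0]):
        m = bg.background_mask(out[t])
        level = float(out[t][m].mean()) if m.any() else bg.mu
        out[t] -= level
    return out


# --------------------------------------------------------------------------
# EA-TIRFM: G factor and anisotropy
# --------------------------------------------------------------------------

def g_factor_from_isotropic(pair: PolarPairStack, bg: BackgroundModel | None = None) -> float:
    """G factor from an image pair of an isotropic dye solution.

    G = mean(I_par) / mean(I_perp) over background-subtracted pixels, so that
    the corrected anisotropy of the solution is zero.
    """
    par = pair.I_par.astype(float)
    perp = pair.I_perp.astype(float)
    if bg is not None:
        par = subtract_background(par, bg)
        perp = subtract_background(perp, bg)
    mean_perp = float(perp.mean())
    mean_par = float(par.mean())
    if abs(mean_perp) < 1e-12 * max(abs(mean_par), 1.0):
        raise ValueError("near-zero perpendicular signal: cannot compute G factor")
    return mean_par / mean_perp


def anisotropy(
    pair: PolarPairStack,
    bg: BackgroundModel | None = None,
    prefilter: bool = True,
) -> AnisotropyMap:
    """Per-pixel emission anisotropy map with intensity gating.

    r = (I_par - G I_perp) / (I_par + 2 G I_perp) after per-frame background
    subtraction.  With ``prefilter`` on, each pixel receives the
    intensity-weighted average anisotropy of its 3x3 neighborhood (weights =
    total intensity I_par + 2 I_perp), which equals the anisotropy of the
    weighted channel sums.  Pixels whose total intensity is not above
    ``INTENSITY_GATE_SDS`` background standard deviations (or is non-positive)
    are marked invalid and carry r = 0, never NaN.
    """
    par = pair.I_par.astype(float)
    perp = pair.g_factor * pair.I_perp.astype(float)
    if bg is not None:
        par = subtract_background(par, bg)
        perp = subtract_background(perp, bg)
        gate = INTENSITY_GATE_SDS * bg.sigma
    else:
        gate = 0.0

    total = par + 2.0 * perp
    valid = total > max(gate, 0.0)

    num = par - perp
    if prefilter:
        # 3x3 intensity-weighted mean r == r of the intensity-summed channels
        w_num = np.empty_like(num)
        w_den = np.empty_like(total)
        for t in range(num.shape[0]):
            w_num[t] = ndimage.uniform_filter(num[t], size=3, mode="nearest")
            w_den[t] = ndimage.uniform_filter(total[t], size=3, mode="nearest")
        num, total_f = w_num, w_den
    else:
        total_f = total

    r = np.zeros_like(num)
    ok = valid & (total_f > 0)
    np.divide(num, total_f, out=r, where=ok)
    r[~ok] = 0.0
    return AnisotropyMap(r=r, valid=ok, total_intensity=total)


def region_snr(region_perp_values, bg: BackgroundModel) -> float:
    """Signal-to-noise ratio of a segmented region.

    SNR = mean perpendicular-channel intensity over the region divided by the
    background standard deviation.  Regions with SNR below ``SNR_CUTOFF`` are
    excluded by callers; exactly at the cutoff is kept.  Zero background sigma
    yields +inf (trivially above any cutoff).
    """
    vals = np.asarray(region_perp_values, dtype=float)
    if vals.size == 0:
        raise ValueError("region is empty")
    if bg.sigma == 0:
        return float("inf")
    return float(vals.mean() / bg.sigma)


# --------------------------------------------------------------------------
# FluoPolScope: calibration and dipole recovery
# --------------------------------------------------------------------------

def quad_calibrate(
    raw_channels: Sequence[np.ndarray],
    throughput_factors: Sequence[float],
    transforms: Sequence[object] | None = None,
    center_roi: tuple[int, int] | None = None,
    roi_size: int = 4,
    pixel_size: float = 70.0,
) -> QuadStack:
    """Throughput-normalize, register and background-correct four quadrants.

    Parameters
    ----------
    raw_channels
        Four stacks (I0, I45, I90, I135), raw quadrant crops.
    throughput_factors
        Four positive scalars from an isotropic dye recording; each channel
        is divided by its factor.
    transforms
        Three (or four, first = identity) skimage geometric transforms mapping
        each non-reference quadrant onto the reference quadrant grid.  ``None``
        entries mean identity.
    center_roi
        (row, col) of the top-left corner of the ``roi_size`` x ``roi_size``
        background ROI at the cell center (about 0.28 um square, 4x4 px).  The
        per-channel, per-frame mean over this ROI is subtracted.  ``None``
        skips background subtraction.
    """
    if throughput_factors is None:
        raise ValueError("missing throughput calibration")
    factors = np.asarray(throughput_factors, dtype=float)
    if factors.shape != (4,):
        raise ValueError("need exactly four throughput factors")
    if np.any(factors <= 0):
        raise ValueError("throughput factors must be positive")
    chans = [_as_stack(c) / f for c, f in zip(raw_channels, factors)]
    if len(chans) != 4:
        raise ValueError("need exactly four channels")

    if transforms is not None:
        if len(transforms) == 3:
            transforms = [None, *transforms]
        if len(transforms) != 4:
            raise ValueError("need 3 or 4 registration transforms")
        for i, tf in enumerate(transforms):
            if tf is None:
                continue
            warped = np.empty_like(chans[i])
            for t in range(chans[i].shape[0]):
                warped[t] = sktransform.warp(
                    chans[i][t], tf.inverse, order=1, mode="edge",
                    preserve_range=True,
                )
            chans[i] = warped

    if center_roi is not None:
        r0, c0 = center_roi
        for i in range(4):
            roi = chans[i][:, r0:r0 + roi_size, c0:c0 + roi_size]
            if roi.size == 0:
                raise ValueError("central background ROI is outside the image")
            level = roi.mean(axis=(1, 2))
            chans[i] = chans[i] - level[:, None, None]

    return QuadStack(*chans, pixel_size=pixel_size)


class QuadPolarization(NamedTuple):
    """Dipole orientation and polarization factor from four-channel sums."""

    theta_deg: float | np.ndarray   # in-plane dipole axis, [0, 180); NaN if isotropic
    p: float | np.ndarray           # polarization factor
    isotropic: bool | np.ndarray    # p below resolution -> theta undefined
    overrange: bool | np.ndarray    # p > 1 (possible under noise), not clipped


def quad_polarization(i0, i45, i90, i135, p_tol: float = 1e-12) -> QuadPolarization:
    """Dipole orientation θ and polarization factor p from four intensities.

    p = sqrt((I0-I90)^2 + (I45-I135)^2) / (0.5 (I0+I45+I90+I135)) and
    θ = 0.5 atan2(I45-I135, I0-I90) folded to [0, 180).  Inputs must be
    background-corrected, throughput-normalized sums with positive total.
    Values p > 1 (possible under noise) are reported with the ``overrange``
    flag rather than clipped.
    """
    i0, i45, i90, i135 = (np.asarray(v, dtype=float) for v in (i0, i45, i90, i135))
    total = i0 + i45 + i90 + i135
    if np.any(total <= 0):
        raise ValueError("total intensity must be positive")
    a = i0 - i90
    b = i45 - i135
    p = np.sqrt(a * a + b * b) / (0.5 * total)
    isotropic = p <= p_tol
    theta = fold180(0.5 * np.degrees(np.arctan2(b, a)))
    theta = np.where(isotropic, np.nan, theta)
    overrange = p > 1.0
    if np.ndim(p) == 0:
        return QuadPolarization(float(theta), float(p), bool(isotropic), bool(overrange))
    return QuadPolarization(theta, p, isotropic, overrange)


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------

def anisotropy_intensity_diagnostic(amap: AnisotropyMap, mask=None):
    """Least-squares slope and correlation of r versus total intensity.

    A slope near zero indicates anisotropy independent of intensity, i.e.
    little or no homo-FRET.  Diagnostic only.
    """
    if amap.total_intensity is None:
        raise ValueError("anisotropy map carries no intensity information")
    sel = amap.valid.copy()
    if mask is not None:
        sel &= _as_stack(mask).astype(bool)
    r = amap.r[sel]
    inten = amap.total_intensity[sel]
    if r.size < 100:
        raise ValueError(f"need at least 100 valid pixels, got {r.size}")
    res = stats.linregress(inten, r)
    return float(res.slope), float(res.rvalue)
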