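"""Temporal detrending, bandpass filtering and spatial smoothing of BOLD data.

The temporal pipeline removes a per-voxel quadratic trend by ordinary least
squares and then restricts signal variation to a low-frequency band
(default 0.01-0.1 Hz) with a hard discrete-Fourier window: every rFFT bin
whose frequency lies outside the band, including DC, is zeroed. The hard
window is exactly idempotent and makes bin-level behaviour testable to
machine precision, which a recursive (e.g. Butterworth) filter would not
be.

Spatial smoothing uses an isotropic Gaussian kernel parameterised by its
full width at half maximum (FWHM) in millimetres; edge effects at mask
boundaries are removed by renormalisation (smooth the masked data, divide
by the smoothed mask) so signal near the brain edge is not diluted by the
zeros outside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import BandError, ValidationError

#: FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class FilterSpec:
    """Temporal band for resting-state fluctuation analysis.

    ``f_lo``/``f_hi`` in Hz, ``tr`` (repetition time) in seconds. The band
    must sit strictly below the Nyquist frequency 1/(2*tr).
    """

    f_lo: float = 0.01
    f_hi: float = 0.1
    tr: float = 1.7

    def __post_init__(self):
        if self.tr <= 0:
            raise BandError(f"tr must be > 0, got {self.tr}")
        nyquist = 1.0 / (2.0 * self.tr)
        if not (0.0 <= self.f_lo < self.f_hi):
            raise BandError(f"need 0 <= f_lo < f_hi, got ({self.f_lo}, {self.f_hi})")
        if self.f_hi > nyquist:
            raise BandError(
                f"f_hi={self.f_hi} Hz exceeds Nyquist {nyquist:.4f} Hz for tr={self.tr}"
            )

    @property
    def nyquist(self):
        return 1.0 / (2.0 * self.tr)


def band_keep_indices(n_volumes, spec):
    """Boolean selector over rFFT bins retained by the bandpass.

    DC (bin 0) is never retained. A bin is retained when its frequency lies
    in [f_lo, f_hi] up to a 1e-12 Hz tolerance.
    """
    freqs = np.fft.rfftfreq(n_volumes, d=spec.tr)
    keep = (freqs >= spec.f_lo - 1e-12) & (freqs <= spec.f_hi + 1e-12) & (freqs > 1e-12)
    if not keep.any():
        raise BandError(
            f"band [{spec.f_lo}, {spec.f_hi}] Hz contains no Fourier bin "
            f"at T={n_volumes}, tr={spec.tr}"
        )
    return keep


def detrend_quadratic(series, axis=-1):
    """Remove the per-series least-squares quadratic trend.

    Works on any array with time along ``axis`` (default last). The
    residuals are exactly orthogonal to {1, t, t^2}.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[axis]
    if n < 4:
        raise ValidationError(f"need at least 4 timepoints to detrend, got {n}")
    t = np.linspace(-1.0, 1.0, n)  # centred for conditioning
    basis = np.column_stack([np.ones(n), t, t * t])
    q, _ = np.linalg.qr(basis)
    x = np.moveaxis(series, axis, -1)
    fitted = (x @ q) @ q.T
    return np.moveaxis(x - fitted, -1, axis)


def bandpass(series, spec, axis=-1):
    """Hard Fourier-window bandpass along ``axis``.

    rFFT coefficients outside [f_lo, f_hi] (and DC) are set to zero; the
    output is real with the same length. Applying the filter twice zeroes
    the same bins, so the operation is idempotent.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[axis]
    keep = band_keep_indices(n, spec)
    coeffs = np.fft.rfft(series, axis=axis)
    shape = [1] * series.ndim
    shape[axis] = keep.size
    coeffs *= keep.reshape(shape)
    return np.fft.irfft(coeffs, n=n, axis=axis)


def fwhm_to_sigma_voxels(fwhm_mm, voxel_size):
    """Per-axis Gaussian sigma in voxel units for an isotropic mm FWHM."""
    voxel_size = np.asarray(voxel_size, dtype=float)
    return float(fwhm_mm) / (voxel_size * FWHM_PER_SIGMA)


def smooth_gaussian(volume, fwhm_mm, voxel_size, mask=None):
    """Isotropic Gaussian smoothing of a 3D volume or 4D series.

    ``fwhm_mm = 0`` is the identity. With a mask, data outside the mask are
    treated as absent: the masked volume is convolved with zero padding and
    divided by the smoothed mask, which preserves constants within the mask
    exactly and avoids edge dilution. Voxels outside the mask are zeroed.
    """
    volume = np.asarray(volume, dtype=float)
    if fwhm_mm < 0:
        raise ValidationError(f"fwhm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return volume.copy()
    sigma = fwhm_to_sigma_voxels(fwhm_mm, voxel_size)
    if volume.ndim == 4:
        sigma = np.append(sigma, 0.0)  # never smooth across time
    elif volume.ndim != 3:
        raise ValidationError(f"expected 3D or 4D volume, got ndim={volume.ndim}")
    if mask is None:
        return ndimage.gaussian_filter(volume, sigma=sigma, mode="constant", cval=0.0)
    mask = np.asarray(mask, dtype=bool)
    m = mask.astype(float)
    if volume.ndim == 4:
        data = volume * m[..., None]
    else:
        data = volume * m
    sm_data = ndimage.gaussian_filter(data, sigma=sigma, mode="constant", cval=0.0)
    sm_mask = ndimage.gaussian_filter(m, sigma=sigma[:3] if volume.ndim == 4 else sigma,
                                      mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        if volume.ndim == 4:
            out = sm_data / sm_mask[..., None]
            out[~mask, :] = 0.0
        else:
            out = sm_data / sm_mask
            out[~mask] = 0.0
    return out


class BOLDPreprocessor:
    """Detrend + bandpass (+ optional smoothing) transformer for 4D series.

    scikit-learn style: parameters at construction, ``fit`` validates,
    ``transform`` applies. ``transform`` accepts a 4D (x, y, z, t) array and
    returns the same shape. Smoothing is separate (:meth:`smooth`) because
    the seed-extraction step of the pipeline needs temporally filtered but
    spatially unsmoothed data.
    """

    def __init__(self, f_lo=0.01, f_hi=0.1, tr=1.7, detrend=True,
                 fwhm=6.0, voxel_size=(3.25, 3.25, 3.0)):
        self.f_lo = f_lo
        self.f_hi = f_hi
        self.tr = tr
        self.detrend = detrend
        self.fwhm = fwhm
        self.voxel_size = voxel_size

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep=True):
        return {
            "f_lo": self.f_lo, "f_hi": self.f_hi, "tr": self.tr,
            "detrend": self.detrend, "fwhm": self.fwhm,
            "voxel_size": self.voxel_size,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r} for BOLDPreprocessor")
            setattr(self, key, value)
        return self

    def fit(self, X=None, y=None):
        self.filter_spec_ = FilterSpec(self.f_lo, self.f_hi, self.tr)
        return self

    def transform(self, X):
        """Temporal preprocessing: quadratic detrend then bandpass."""
        if not hasattr(self, "filter_spec_"):
            self.fit()
        out = np.asarray(X, dtype=float)
        if self.detrend:
            out = detrend_quadratic(out, axis=-1)
        return bandpass(out, self.filter_spec_, axis=-1)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def smooth(self, X, mask=None):
        """Spatial smoothing at the configured FWHM."""
        return smooth_gaussian(X, self.fwhm, self.voxel_size, mask=mask)
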