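"""Receptive-field estimation by reverse correlation.

The spatiotemporal kernel is the response-weighted average of preceding
stimulus frames (an STA on mean-subtracted stimulus and response,
normalized by the response variance).  The RF center is the centroid of
the absolute kernel at its peak lag over pixels above half maximum — the
magnitude is used so ON and OFF cells share one code path — and the RF
width is the FWHM of a symmetric 2-D Gaussian fit to that spatial map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import DegenerateResponseError
from .preprocess import DffTrace
from .stimulus import ScreenGeometry, StimulusMovie

__all__ = ["ReceptiveField", "reverse_correlate", "rf_center_and_fwhm"]

log = logging.getLogger(__name__)

SIGMA_TO_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass
class ReceptiveField:
    """Spatiotemporal kernel with derived center coordinates and width.

    ``kernel`` has shape (n_lags, n_elevation, n_azimuth); ``lags`` are in
    seconds (0 to max_lag).  ``center``/``fwhm``/``peak_lag`` are filled in
    by :func:`rf_center_and_fwhm`.
    """

    kernel: np.ndarray
    lags: np.ndarray
    geometry: ScreenGeometry
    center: tuple[float, float] | None = None
    fwhm: float | None = None
    peak_lag: float | None = None

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if not np.all(np.isfinite(self.kernel)):
            raise ValueError("kernel contains non-finite values")

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("kernel", data=self.kernel)
            fh.create_dataset("lags", data=self.lags)
            fh.create_dataset("azimuths", data=self.geometry.azimuths)
            fh.create_dataset("elevations", data=self.geometry.elevations)
            if self.center is not None:
                ds.attrs["center_azimuth"] = self.center[0]
                ds.attrs["center_elevation"] = self.center[1]
            if self.fwhm is not None:
                ds.attrs["fwhm"] = self.fwhm
            if self.peak_lag is not None:
                ds.attrs["peak_lag"] = self.peak_lag


def reverse_correlate(
    movie: StimulusMovie, response: DffTrace, max_lag: float = 1.0
) -> ReceptiveField:
    """Spatiotemporal STA of the stimulus with respect to the response.

    kernel(lag, pixel) = <response(t) * stimulus_deviation(t - lag, pixel)>
    normalized by the response variance.  Movie frames are matched to
    response samples by nearest time; both are mean-subtracted.
    """
    rate = response.sample_rate
    resp = response.values - response.values.mean()
    # Nearest-frame alignment of the movie onto the response time base.
    t_resp = np.arange(resp.size) / rate
    idx = np.clip(
        np.round(t_resp * movie.frame_rate).astype(int), 0, movie.n_frames - 1
    )
    n_t = min(resp.size, idx.size)
    resp = resp[:n_t]
    stim = movie.frames[idx[:n_t]]
    stim = stim - stim.mean(axis=0, keepdims=True)

    n_lags = int(np.floor(max_lag * rate)) + 1
    if n_lags > n_t:
        raise ValueError(
            f"max_lag of {max_lag} s exceeds the {n_t / rate:.2f} s record"
        )
    var = resp.var()
    kernel = np.zeros((n_lags,) + stim.shape[1:])
    if var > 0:
        for lag in range(n_lags):
            seg_resp = resp[lag:]
            seg_stim = stim[: n_t - lag]
            kernel[lag] = np.tensordot(seg_resp, seg_stim, axes=(0, 0)) / (
                seg_resp.size * var
            )
    return ReceptiveField(
        kernel=kernel, lags=np.arange(n_lags) / rate, geometry=movie.geometry
    )


def _gauss2d(coords, amplitude, az0, el0, sigma, offset):
    az, el = coords
    return offset + amplitude * np.exp(
        -0.5 * ((az - az0) ** 2 + (el - el0) ** 2) / sigma**2
    )


def rf_center_and_fwhm(
    rf: ReceptiveField, smooth_px: float = 1.0
) -> tuple[tuple[float, float], float]:
    """RF center and FWHM from the kernel's peak-lag spatial map.

    Center: centroid over pixels at or above 50% of the peak magnitude of
    the peak-lag map, after smoothing the map with a one-pixel Gaussian to
    suppress single-pixel estimation noise (smoothing is symmetric, so it
    does not displace the centroid of a symmetric field).  FWHM: 2.355
    sigma of a symmetric 2-D Gaussian least-squares fit to the *unsmoothed*
    map, initialized from the centroid and the half-max mass radius; if the
    fit fails, the half-max area radius of the smoothed map is used instead
    and the fallback is logged.  Results are stored on ``rf`` and returned.
    """
    from scipy.ndimage import gaussian_filter

    absk = np.abs(rf.kernel)
    if absk.max() <= 0:
        raise DegenerateResponseError("all-zero kernel: no receptive field")
    smoothed_k = (
        gaussian_filter(absk, (0.0, smooth_px, smooth_px)) if smooth_px > 0
        else absk
    )
    lag_idx = np.unravel_index(np.argmax(smoothed_k), smoothed_k.shape)[0]
    rf.peak_lag = float(rf.lags[lag_idx])
    spatial = absk[lag_idx]
    smoothed = smoothed_k[lag_idx]

    geo = rf.geometry
    az = geo.azimuths[np.newaxis, :]
    el = geo.elevations[:, np.newaxis]
    mask = smoothed >= 0.5 * smoothed.max()
    w = np.where(mask, smoothed, 0.0)
    center = (
        float((w * az).sum() / w.sum()),
        float((w * el).sum() / w.sum()),
    )

    pixel_area = geo.pixel_size * geo.elevation_pixel_size
    halfmax_area = mask.sum() * pixel_area
    r_halfmax = np.sqrt(halfmax_area / np.pi)
    sigma0 = max(r_halfmax / np.sqrt(2.0 * np.log(2.0)), 0.5 * geo.pixel_size)

    try:
        coords = (np.broadcast_to(az, spatial.shape).ravel(),
                  np.broadcast_to(el, spatial.shape).ravel())
        with warnings.catch_warnings():
            # an exact fit has a singular covariance; we use only popt
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _gauss2d,
                coords,
                spatial.ravel(),
                p0=[spatial.max(), center[0], center[1], sigma0, 0.0],
                maxfev=5000,
            )
        amp, az0, el0, sigma, _offset = popt
        sigma = abs(sigma)
        if amp <= 0 or sigma <= 0 or not geo.contains(az0, el0):
            raise RuntimeError("implausible Gaussian fit")
        rf.fwhm = float(SIGMA_TO_FWHM * sigma)
    except (RuntimeError, ValueError):
        log.warning(
            "2-D Gaussian fit failed; falling back to half-max-area FWHM"
        )
        rf.fwhm = float(2.0 * r_halfmax)
    rf.center = center
    return rf.center, rf.fwhm
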