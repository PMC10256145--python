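"""Raw-fluorescence preprocessing: dynamic-baseline ΔF/F and SNR screening.

The baseline F0 follows the standard sliding-minimum algorithm for calcium
traces: the raw signal is smoothed with a Gaussian window (FWHM 1 s), the
minimum over a 90 s sliding window is taken, and the result is smoothed
again with a wide Gaussian window (FWHM 4 min), giving a slowly varying
baseline that tracks drift but ignores transients.  ΔF/F = (F - F0) / F0.

Recordings whose inter-trial variance rivals the mean response are screened
out with a signal-to-noise criterion: the SD over time of the trial-averaged
trace must be at least 115% of the time-averaged across-trial SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d, minimum_filter1d

from .errors import AlignmentError, DataError

__all__ = ["DffTrace", "SnrDecision", "compute_dff", "snr_filter"]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

SNR_THRESHOLD = 1.15


@dataclass
class DffTrace:
    """Relative fluorescence change with the baseline used to compute it."""

    values: np.ndarray
    sample_rate: float
    baseline: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise DataError("ΔF/F trace contains non-finite values")
        if self.baseline is not None:
            self.baseline = np.asarray(self.baseline, dtype=float)
            if np.any(self.baseline <= 0):
                raise DataError("baseline must be strictly positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sample_rate


@dataclass
class SnrDecision:
    """Outcome of the inter-trial signal-to-noise criterion."""

    signal_sd: float
    noise_sd: float
    ratio: float
    passed: bool
    threshold: float = SNR_THRESHOLD


def _smooth(x: np.ndarray, fwhm_s: float, sample_rate: float) -> np.ndarray:
    sigma = fwhm_s * FWHM_TO_SIGMA * sample_rate
    if sigma < 1e-9:
        return x.copy()
    # reflective padding, kernel truncated at 4 sigma
    return gaussian_filter1d(x, sigma, mode="reflect", truncate=4.0)


def compute_dff(
    raw: np.ndarray,
    sample_rate: float,
    smooth_fwhm: float = 1.0,
    min_window: float = 90.0,
    baseline_fwhm: float = 240.0,
) -> DffTrace:
    """Dynamic-baseline ΔF/F of a raw fluorescence trace.

    Parameters
    ----------
    raw
        Strictly positive raw fluorescence samples.
    sample_rate
        Sampling rate in Hz.
    smooth_fwhm, min_window, baseline_fwhm
        FWHM (s) of the pre-smoothing window, length (s) of the sliding
        minimum, and FWHM (s) of the baseline smoothing window.  Windows
        longer than the trace are clamped to the trace length.
    """
    raw = np.asarray(raw, dtype=float)
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if raw.size == 0:
        raise DataError("empty trace")
    if np.any(raw <= 0) or not np.all(np.isfinite(raw)):
        raise DataError("raw fluorescence must be finite and strictly positive")

    smoothed = _smooth(raw, smooth_fwhm, sample_rate)
    win = min(max(1, round(min_window * sample_rate)), raw.size)
    running_min = minimum_filter1d(smoothed, size=win, mode="reflect")
    f0 = _smooth(running_min, baseline_fwhm, sample_rate)
    # Smoothing a positive series keeps it positive; guard against underflow.
    f0 = np.maximum(f0, np.finfo(float).tiny)
    return DffTrace(values=(raw - f0) / f0, sample_rate=sample_rate, baseline=f0)


def snr_filter(trials: Sequence[DffTrace] | np.ndarray) -> SnrDecision:
    """Apply the inter-trial SNR inclusion criterion.

    ``signal_sd`` is the SD over time of the trial-averaged trace;
    ``noise_sd`` is the time-average of the per-timepoint SD across trials.
    The recording passes if ``signal_sd >= 1.15 * noise_sd``.
    """
    if isinstance(trials, np.ndarray):
        mat = np.asarray(trials, dtype=float)
        if mat.ndim != 2:
            raise ValueError("trial array must be 2-D (trials x time)")
    else:
        lengths = {t.values.size for t in trials}
        if len(trials) and len(lengths) > 1:
            raise AlignmentError(f"trials differ in length: {sorted(lengths)}")
        mat = np.array([t.values for t in trials], dtype=float)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 trials for the SNR criterion")

    mean_trace = mat.mean(axis=0)
    signal_sd = float(mean_trace.std())
    # sample SD across the (few) trials at each time point
    noise_sd = float(mat.std(axis=0, ddof=1).mean())
    if noise_sd > 0:
        ratio = signal_sd / noise_sd
    else:
        ratio = np.inf if signal_sd > 0 else 0.0
    return SnrDecision(
        signal_sd=signal_sd,
        noise_sd=noise_sd,
        ratio=ratio,
        passed=bool(ratio >= SNR_THRESHOLD),
    )
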