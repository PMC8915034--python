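"""Six classical ECG denoising filters behind a uniform config interface.

The bank comprises: median, 1-D Gaussian, moving average,
Savitzky–Golay (window 25, polynomial order 7), low-pass Butterworth,
and wavelet shrinkage (sym8, BayesShrink rule, soft thresholding).
Windowed filters handle edges by reflection; the Butterworth filter is
zero-phase (forward–backward) by default. All filters preserve signal
length and never mutate their input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pywt
from scipy import ndimage, signal as sps


@dataclass(frozen=True)
class Median:
    """Sliding-window median; removes impulse noise. Window must be odd."""

    window: int = 5
    name = "median"


@dataclass(frozen=True)
class Gaussian:
    """Convolution with a normalized discrete Gaussian kernel.

    ``sigma`` is in samples; the kernel is truncated at ``truncate``
    standard deviations and renormalized to sum 1.
    """

    sigma: float = 2.0
    truncate: float = 4.0
    name = "gaussian"


@dataclass(frozen=True)
class MovingAverage:
    """Centered mean over a sliding window (low-pass FIR)."""

    window: int = 5
    name = "moving_average"


@dataclass(frozen=True)
class SavitzkyGolay:
    """Per-window least-squares polynomial fit evaluated at the center."""

    window: int = 25
    polyorder: int = 7
    name = "savgol"


@dataclass(frozen=True)
class ButterworthLowPass:
    """Digital Butterworth low-pass; maximally flat passband.

    With ``zero_phase`` the filter runs forward and backward
    (no phase distortion, squared magnitude response).
    """

    order: int = 4
    cutoff_hz: float = 40.0
    zero_phase: bool = True
    name = "butterworth"


@dataclass(frozen=True)
class Wavelet:
    """Multilevel wavelet shrinkage with the BayesShrink threshold rule.

    Noise SD is estimated from the finest detail subband via the median
    absolute deviation (MAD / 0.6745); each detail subband gets
    threshold ``T = sigma_noise**2 / sigma_signal`` and is
    soft-thresholded before reconstruction.
    """

    wavelet: str = "sym8"
    levels: int = 4
    mode: str = "soft"
    threshold_rule: str = "bayes"
    name = "wavelet"


FilterConfig = Union[Median, Gaussian, MovingAverage, SavitzkyGolay, ButterworthLowPass, Wavelet]


def default_filter_bank() -> dict[str, FilterConfig]:
    """The six filters with their default configurations."""
    configs = (
        Median(),
        Gaussian(),
        MovingAverage(),
        SavitzkyGolay(),
        ButterworthLowPass(),
        Wavelet(),
    )
    return {c.name: c for c in configs}


def _as_1d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D signal, got shape {x.shape}")
    return x


def median_filter(x: np.ndarray, window: int = 5) -> np.ndarray:
    x = _as_1d(x)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"median window must be odd and >= 1, got {window}")
    if window > x.size:
        raise ValueError(f"window {window} exceeds signal length {x.size}")
    return ndimage.median_filter(x, size=window, mode="reflect")


def gaussian_filter(x: np.ndarray, sigma: float = 2.0, truncate: float = 4.0) -> np.ndarray:
    x = _as_1d(x)
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return ndimage.gaussian_filter1d(x, sigma=sigma, truncate=truncate, mode="reflect")


def moving_average_filter(x: np.ndarray, window: int = 5) -> np.ndarray:
    x = _as_1d(x)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window > x.size:
        raise ValueError(f"window {window} exceeds signal length {x.size}")
    return ndimage.uniform_filter1d(x, size=window, mode="reflect")


def savgol_filter(x: np.ndarray, window: int = 25, polyorder: int = 7) -> np.ndarray:
    x = _as_1d(x)
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if polyorder >= window:
        raise ValueError(f"polyorder {polyorder} must be < window {window}")
    if window > x.size:
        raise ValueError(f"window {window} exceeds signal length {x.size}")
    # 'interp' fits a polynomial to each edge window, so signals in the
    # filter's own model class (degree <= polyorder) are reproduced exactly
    return sps.savgol_filter(x, window_length=window, polyorder=polyorder, mode="interp")


def butterworth_lowpass(
    x: np.ndarray,
    order: int = 4,
    cutoff_hz: float = 40.0,
    sampling_rate: float = 360.0,
    zero_phase: bool = True,
) -> np.ndarray:
    x = _as_1d(x)
    nyquist = sampling_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie strictly between 0 and Nyquist {nyquist} Hz"
        )
    sos = sps.butter(order, cutoff_hz, btype="low", fs=sampling_rate, output="sos")
    if zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def _bayes_threshold(detail: np.ndarray, sigma_noise: float) -> float:
    # T = sigma_n^2 / sigma_x, sigma_x^2 = max(var - sigma_n^2, 0);
    # a subband indistinguishable from pure noise is zeroed entirely.
    sigma_x2 = max(float(np.var(detail)) - sigma_noise**2, 0.0)
    if sigma_x2 == 0.0:
        return float(np.max(np.abs(detail))) if detail.size else 0.0
    return sigma_noise**2 / np.sqrt(sigma_x2)


def wavelet_denoise(
    x: np.ndarray,
    wavelet: str = "sym8",
    levels: int = 4,
    mode: str = "soft",
    threshold_rule: str = "bayes",
) -> np.ndarray:
    x = _as_1d(x)
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    if threshold_rule != "bayes":
        raise ValueError(f"unsupported threshold rule {threshold_rule!r}")
    wav = pywt.Wavelet(wavelet)
    if x.size < wav.dec_len:
        raise ValueError(
            f"signal length {x.size} shorter than one {wavelet} decomposition "
            f"step (filter length {wav.dec_len})"
        )
    levels = min(levels, pywt.dwt_max_level(x.size, wav))
    coeffs = pywt.wavedec(x, wav, mode="symmetric", level=levels)
    finest = coeffs[-1]
    sigma = float(np.median(np.abs(finest))) / 0.6745
    if sigma == 0.0:
        return x.copy()
    shrunk = [coeffs[0]]
    for detail in coeffs[1:]:
        t = _bayes_threshold(detail, sigma)
        shrunk.append(pywt.threshold(detail, t, mode=mode))
    out = pywt.waverec(shrunk, wav, mode="symmetric")
    return out[: x.size]


def apply_filter(
    x: np.ndarray, config: FilterConfig, sampling_rate: float = 360.0
) -> np.ndarray:
    """Dispatch to the filter matching ``config``; output length = input length."""
    if isinstance(config, Median):
        return median_filter(x, config.window)
    if isinstance(config, Gaussian):
        return gaussian_filter(x, config.sigma, config.truncate)
    if isinstance(config, MovingAverage):
        return moving_average_filter(x, config.window)
    if isinstance(config, SavitzkyGolay):
        return savgol_filter(x, config.window, config.polyorder)
    if isinstance(config, ButterworthLowPass):
        return butterworth_lowpass(
            x, config.order, config.cutoff_hz, sampling_rate, config.zero_phase
        )
    if isinstance(config, Wavelet):
        return wavelet_denoise(
            x, config.wavelet, config.levels, config.mode, config.threshold_rule
        )
    raise TypeError(f"unknown filter config: {config!r}")
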