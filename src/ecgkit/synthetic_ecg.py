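"""Synthetic annotated ECG generation and controlled noise injection.

A heartbeat is modeled as a sum of five Gaussian bumps (P, Q, R, S, T
waves) placed relative to the R peak; a record is a quasi-periodic train
of such beats with Gaussian RR-interval variability. Abnormal
(ventricular-like) beats use a widened QRS and an inverted T wave so the
two classes are morphologically separable. Noise is additive: white
Gaussian noise scaled to an exact target SNR, plus optional sinusoidal
baseline wander and powerline interference.

This is a test harness for the pipeline, not a physiological simulator:
beat shape, spectra and noise statistics are simplified stand-ins for
real ambulatory recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ecgkit.signal_io import Annotation, EcgRecord, HeaderInfo

#: Gaussian bump parameters: (wave, amplitude mV, center offset s, width s)
_NORMAL_COMPONENTS = (
    ("P", 0.15, -0.20, 0.040),
    ("Q", -0.10, -0.035, 0.012),
    ("R", 1.20, 0.0, 0.018),
    ("S", -0.25, 0.035, 0.014),
    ("T", 0.35, 0.30, 0.070),
)

#: Ventricular-like beat: no organized P, broad QRS, inverted T.
_ABNORMAL_COMPONENTS = (
    ("P", 0.02, -0.20, 0.040),
    ("Q", -0.15, -0.065, 0.030),
    ("R", 1.05, 0.0, 0.045),
    ("S", -0.40, 0.075, 0.035),
    ("T", -0.40, 0.33, 0.090),
)


@dataclass(frozen=True)
class BeatMorphology:
    """A beat shape as Gaussian bumps ``(wave, amplitude, center, width)``.

    The R bump must dominate in absolute amplitude so the annotation
    lands on the signal's local extremum; widths are in seconds.
    """

    components: tuple[tuple[str, float, float, float], ...]

    def __post_init__(self) -> None:
        waves = {c[0] for c in self.components}
        if "R" not in waves:
            raise ValueError("morphology must include an R wave")
        if any(c[3] <= 0 for c in self.components):
            raise ValueError("bump widths must be > 0")
        r_amp = max(abs(c[1]) for c in self.components if c[0] == "R")
        others = [abs(c[1]) for c in self.components if c[0] != "R"]
        if others and r_amp <= max(others):
            raise ValueError("R amplitude must be strictly largest in absolute value")

    @property
    def support(self) -> float:
        """Half-width (s) beyond which the beat is negligible (3 SD)."""
        return max(abs(c[2]) + 3.0 * c[3] for c in self.components)

    def render(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the beat at times ``t`` (s, relative to the R peak)."""
        out = np.zeros_like(t, dtype=float)
        for _, amp, center, width in self.components:
            out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
        return out


def normal_morphology() -> BeatMorphology:
    return BeatMorphology(_NORMAL_COMPONENTS)


def abnormal_morphology() -> BeatMorphology:
    return BeatMorphology(_ABNORMAL_COMPONENTS)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise description.

    ``snr_db`` is the target SNR of the white-noise component in dB
    (``math.inf`` disables it); baseline wander and powerline
    interference are optional deterministic sinusoids on top.
    """

    snr_db: float = 10.0
    baseline_wander_hz: float | None = None
    baseline_wander_amplitude: float = 0.1
    powerline_hz: float | None = None
    powerline_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.powerline_hz is not None and self.powerline_hz not in (50.0, 60.0):
            raise ValueError("powerline_hz must be 50 or 60")


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one synthetic record.

    Defaults emulate an ambulatory single-patient recording: 360 Hz
    sampling, 72 bpm mean heart rate with 5% RR variability.
    """

    duration: float = 60.0
    sampling_rate: float = 360.0
    heart_rate_bpm: float = 72.0
    rr_cv: float = 0.05
    fraction_abnormal: float = 0.0
    normal: BeatMorphology = field(default_factory=normal_morphology)
    abnormal: BeatMorphology = field(default_factory=abnormal_morphology)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if not 0.0 <= self.fraction_abnormal <= 1.0:
            raise ValueError("fraction_abnormal must be in [0, 1]")
        if self.sampling_rate <= 0 or self.heart_rate_bpm <= 0:
            raise ValueError("sampling_rate and heart_rate_bpm must be > 0")


def generate_clean_ecg(config: SimulationConfig) -> EcgRecord:
    """Generate a noise-free annotated single-channel record.

    One annotation per beat, at the R-peak sample: symbol ``'N'`` for
    normal beats, ``'V'`` for abnormal ones, drawn i.i.d. with
    probability ``fraction_abnormal``. RR intervals are i.i.d. Gaussian
    with the configured mean and CV, truncated at ±3 SD.
    """
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    mean_rr = 60.0 / config.heart_rate_bpm
    support = max(config.normal.support, config.abnormal.support)
    # adjacent beats overlap by 2*support - RR; reject overlap beyond RR/2
    if 2.0 * support - mean_rr > mean_rr / 2:
        raise ValueError(
            f"beats overlap beyond half an RR interval: morphology support "
            f"{support:.3f}s vs mean RR {mean_rr:.3f}s at {config.heart_rate_bpm} bpm"
        )
    rng = np.random.default_rng(config.seed)
    sd = config.rr_cv * mean_rr

    t = np.arange(n) / fs
    signal = np.zeros(n)
    annotations: list[Annotation] = []
    center = mean_rr  # leave room for the first beat's P wave
    last_index = -1
    while center < config.duration - support:
        abnormal = bool(rng.random() < config.fraction_abnormal)
        morphology = config.abnormal if abnormal else config.normal
        r_index = int(round(center * fs))
        if r_index >= n:
            break
        if r_index > last_index:  # sorted-unique annotation invariant
            snapped = r_index / fs  # R peak exactly on the sample grid
            lo = max(0, int((snapped - support) * fs) - 1)
            hi = min(n, int((snapped + support) * fs) + 2)
            signal[lo:hi] += morphology.render(t[lo:hi] - snapped)
            annotations.append(Annotation(r_index, "V" if abnormal else "N"))
            last_index = r_index
        rr = mean_rr + np.clip(rng.normal(0.0, sd), -3.0 * sd, 3.0 * sd) if sd > 0 else mean_rr
        center += rr

    header = HeaderInfo(
        record_name=f"synthetic-{config.seed}",
        n_channels=1,
        sampling_rate=fs,
        n_samples=n,
    )
    return EcgRecord(header, signal[None, :], annotations)


def add_noise(
    signal: np.ndarray, spec: NoiseSpec, sampling_rate: float = 360.0
) -> np.ndarray:
    """Return ``signal`` plus additive noise per ``spec``; input unchanged.

    The white-noise component is rescaled by its realized power so the
    achieved SNR equals ``spec.snr_db`` exactly (up to float rounding).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("signal must be non-empty")
    out = signal.copy()
    if math.isfinite(spec.snr_db):
        p_signal = float(np.mean(signal**2))
        if p_signal <= 0:
            raise ValueError("cannot set a finite SNR on a zero-power signal")
        rng = np.random.default_rng(spec.seed)
        noise = rng.standard_normal(signal.shape)
        p_target = p_signal / 10.0 ** (spec.snr_db / 10.0)
        noise *= math.sqrt(p_target / float(np.mean(noise**2)))
        out += noise
    t = np.arange(signal.shape[-1]) / sampling_rate
    if spec.baseline_wander_hz is not None:
        out += spec.baseline_wander_amplitude * np.sin(
            2.0 * np.pi * spec.baseline_wander_hz * t
        )
    if spec.powerline_hz is not None:
        out += spec.powerline_amplitude * np.sin(2.0 * np.pi * spec.powerline_hz * t)
    return out
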