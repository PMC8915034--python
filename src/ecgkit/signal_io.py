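"""Reading and writing ECG records.

Supports the WFDB-style record layout used by ambulatory ECG databases —
a plain-text header (``.hea``), a format-212 packed binary signal file
(``.dat``) — plus two CSV side formats: beat annotations
(``sample_index,symbol``) and single-channel signals
(``sample_index,amplitude_mV``).

Format 212 packs two signed 12-bit samples into three bytes: the first
sample is the low byte plus the low nibble of the middle byte as its high
bits; the second sample is the third byte plus the high nibble of the
middle byte. Multi-channel signals are interleaved frame by frame.

Binary annotation files are out of scope; annotations travel as CSV.
All sample indices are 0-based.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

ADC_MIN = -2048
ADC_MAX = 2047


class FormatError(ValueError):
    """Raised when a file does not conform to the expected on-disk format."""


@dataclass(frozen=True)
class HeaderInfo:
    """Record-level metadata from the text header.

    Parameters
    ----------
    record_name : str
        Base name of the record.
    n_channels : int
        Number of signal channels (leads).
    sampling_rate : float
        Samples per second per channel (360 for MIT-BIH-style records).
    n_samples : int
        Samples per channel.
    gain_per_channel : tuple of float
        ADC units per millivolt, one entry per channel.
    baseline_per_channel : tuple of int
        ADC value corresponding to 0 mV, one entry per channel.
    """

    record_name: str
    n_channels: int
    sampling_rate: float
    n_samples: int
    gain_per_channel: tuple[float, ...] = ()
    baseline_per_channel: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.n_samples < 0:
            raise ValueError(f"n_samples must be >= 0, got {self.n_samples}")
        gains = self.gain_per_channel or (200.0,) * self.n_channels
        baselines = self.baseline_per_channel or (0,) * self.n_channels
        if len(gains) != self.n_channels or len(baselines) != self.n_channels:
            raise ValueError("per-channel gain/baseline length must equal n_channels")
        if any(g <= 0 for g in gains):
            raise ValueError("gains must be > 0")
        object.__setattr__(self, "gain_per_channel", tuple(float(g) for g in gains))
        object.__setattr__(self, "baseline_per_channel", tuple(int(b) for b in baselines))


@dataclass(frozen=True, order=True)
class Annotation:
    """A beat annotation: 0-based sample position and single-character symbol."""

    sample_index: int
    symbol: str

    def __post_init__(self) -> None:
        if self.sample_index < 0:
            raise ValueError(f"sample_index must be >= 0, got {self.sample_index}")
        if not self.symbol:
            raise ValueError("symbol must be non-empty")


@dataclass
class EcgRecord:
    """An ECG record: header, per-channel signal in mV, sorted annotations.

    ``signal`` has shape ``(n_channels, n_samples)``; annotations are kept
    strictly sorted and unique by sample index.
    """

    header: HeaderInfo
    signal: np.ndarray
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.shape != (self.header.n_channels, self.header.n_samples):
            raise ValueError(
                f"signal shape {self.signal.shape} inconsistent with header "
                f"({self.header.n_channels}, {self.header.n_samples})"
            )
        self.annotations = sorted(self.annotations)
        indices = [a.sample_index for a in self.annotations]
        if len(set(indices)) != len(indices):
            raise ValueError("annotations must be unique by sample_index")
        if indices and indices[-1] >= self.header.n_samples > 0:
            raise ValueError(
                f"annotation index {indices[-1]} out of range "
                f"[0, {self.header.n_samples})"
            )

    @property
    def sampling_rate(self) -> float:
        return self.header.sampling_rate

    def channel(self, index: int = 0) -> np.ndarray:
        """Return one channel as a 1-D array (default: channel 0)."""
        return self.signal[index]

    def with_signal(self, signal: np.ndarray) -> "EcgRecord":
        """Copy of this record with a replaced (same-shape) signal."""
        signal = np.atleast_2d(np.asarray(signal, dtype=float))
        header = replace(self.header, n_samples=signal.shape[1])
        return EcgRecord(header, signal, list(self.annotations))


def decode_format212(data: bytes, n_samples: int) -> np.ndarray:
    """Unpack ``n_samples`` signed 12-bit integers from format-212 bytes.

    Samples are packed in pairs of 3 bytes. An odd final sample occupies
    the first two bytes of a last 3-byte group.
    """
    needed = (n_samples * 3 + 1) // 2
    if len(data) < needed:
        raise FormatError(
            f"truncated format-212 stream: need {needed} bytes for "
            f"{n_samples} samples, got {len(data)} (short at byte offset {len(data)})"
        )
    n_pairs = (n_samples + 1) // 2
    raw = np.frombuffer(data[: n_pairs * 3], dtype=np.uint8)
    if len(raw) < n_pairs * 3:  # odd tail: pad the unused half-pair
        raw = np.concatenate([raw, np.zeros(n_pairs * 3 - len(raw), dtype=np.uint8)])
    raw = raw.reshape(n_pairs, 3).astype(np.int32)
    first = ((raw[:, 1] & 0x0F) << 8) | raw[:, 0]
    second = ((raw[:, 1] & 0xF0) << 4) | raw[:, 2]
    samples = np.empty(n_pairs * 2, dtype=np.int32)
    samples[0::2] = first
    samples[1::2] = second
    samples = samples[:n_samples]
    samples[samples > ADC_MAX] -= 4096  # two's complement sign extension
    return samples


def encode_format212(samples: Sequence[int]) -> bytes:
    """Pack signed 12-bit integers into format-212 bytes (inverse of decode)."""
    arr = np.asarray(samples, dtype=np.int64)
    if arr.size and (arr.min() < ADC_MIN or arr.max() > ADC_MAX):
        raise OverflowError(
            f"sample out of 12-bit range [{ADC_MIN}, {ADC_MAX}]: "
            f"min={arr.min()}, max={arr.max()}"
        )
    arr = np.where(arr < 0, arr + 4096, arr).astype(np.uint16)
    if arr.size % 2:
        arr = np.concatenate([arr, np.zeros(1, dtype=np.uint16)])
    pairs = arr.reshape(-1, 2)
    out = np.empty((len(pairs), 3), dtype=np.uint8)
    out[:, 0] = pairs[:, 0] & 0xFF
    out[:, 1] = ((pairs[:, 0] >> 8) & 0x0F) | (((pairs[:, 1] >> 8) & 0x0F) << 4)
    out[:, 2] = pairs[:, 1] & 0xFF
    return out.tobytes()


_KNOWN_FORMATS = {"212"}


def _parse_gain_token(token: str) -> tuple[float, int]:
    """Parse a WFDB gain token ``gain(baseline)/units`` → (gain, baseline)."""
    baseline = 0
    token = token.split("/")[0]
    if "(" in token:
        gain_s, rest = token.split("(", 1)
        baseline = int(rest.rstrip(")"))
    else:
        gain_s = token
    gain = float(gain_s) if gain_s else 200.0
    return (gain if gain > 0 else 200.0), baseline


def read_header(path: str | Path) -> HeaderInfo:
    """Parse a WFDB-style text header; unknown tokens are ignored with a warning."""
    path = Path(path)
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"empty header file: {path}")
    head = lines[0].split()
    if len(head) < 2:
        raise FormatError(f"header line needs at least 'name n_channels': {lines[0]!r}")
    record_name = head[0].split("/")[0]
    n_channels = int(head[1])
    sampling_rate = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    if len(head) > 4:
        logger.warning("ignoring %d unknown header tokens in %s", len(head) - 4, path)
    gains, baselines = [], []
    for line in lines[1 : 1 + n_channels]:
        tokens = line.split()
        if len(tokens) >= 2 and tokens[1].split("+")[0] not in _KNOWN_FORMATS:
            logger.warning("unknown signal format %r in %s; assuming 212", tokens[1], path)
        gain, baseline = _parse_gain_token(tokens[2]) if len(tokens) > 2 else (200.0, 0)
        # WFDB puts an explicit ADC zero in field 5; prefer it over (baseline)
        if len(tokens) > 4:
            try:
                baseline = int(tokens[4])
            except ValueError:
                logger.warning("unparseable ADC-zero token %r in %s", tokens[4], path)
        gains.append(gain)
        baselines.append(baseline)
    if len(gains) < n_channels:
        gains += [200.0] * (n_channels - len(gains))
        baselines += [0] * (n_channels - len(baselines))
    return HeaderInfo(
        record_name=record_name,
        n_channels=n_channels,
        sampling_rate=sampling_rate,
        n_samples=n_samples,
        gain_per_channel=tuple(gains),
        baseline_per_channel=tuple(baselines),
    )


def read_annotations(path: str | Path, n_samples: int | None = None) -> list[Annotation]:
    """Read a ``sample_index,symbol`` CSV into a sorted annotation list."""
    annotations = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or row[0].strip().lower() == "sample_index":
                continue
            idx, symbol = int(row[0]), row[1].strip()
            if n_samples is not None and not 0 <= idx < n_samples:
                raise ValueError(
                    f"annotation index {idx} out of range [0, {n_samples}) in {path}"
                )
            annotations.append(Annotation(idx, symbol))
    return sorted(annotations)


def write_annotations(annotations: Sequence[Annotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_index", "symbol"])
        for ann in sorted(annotations):
            writer.writerow([ann.sample_index, ann.symbol])


def read_record(
    header_path: str | Path,
    signal_path: str | Path,
    annotation_path: str | Path | None = None,
) -> EcgRecord:
    """Read a header + format-212 signal (+ optional annotation CSV) record.

    ADC values are converted to millivolts via ``(adc - baseline) / gain``.
    """
    header = read_header(header_path)
    data = Path(signal_path).read_bytes()
    total = header.n_samples * header.n_channels
    adc = decode_format212(data, total)
    frames = adc.reshape(header.n_samples, header.n_channels).T.astype(float)
    gains = np.asarray(header.gain_per_channel)[:, None]
    baselines = np.asarray(header.baseline_per_channel)[:, None]
    signal = (frames - baselines) / gains
    annotations = (
        read_annotations(annotation_path, header.n_samples or None)
        if annotation_path is not None
        else []
    )
    return EcgRecord(header, signal, annotations)


def write_record(record: EcgRecord, directory: str | Path) -> dict[str, Path]:
    """Write header, format-212 signal and annotation CSV; inverse of read_record.

    Raises
    ------
    OverflowError
        If any amplitude falls outside the 12-bit ADC range after scaling.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    h = record.header
    name = h.record_name
    paths = {
        "header": directory / f"{name}.hea",
        "signal": directory / f"{name}.dat",
        "annotations": directory / f"{name}.ann.csv",
    }
    gains = np.asarray(h.gain_per_channel)[:, None]
    baselines = np.asarray(h.baseline_per_channel)[:, None]
    adc = np.rint(record.signal * gains + baselines).astype(np.int64)
    if adc.size and (adc.min() < ADC_MIN or adc.max() > ADC_MAX):
        raise OverflowError(
            "amplitude out of 12-bit ADC range after gain/baseline scaling: "
            f"ADC min={adc.min()}, max={adc.max()}"
        )
    lines = [f"{name} {h.n_channels} {h.sampling_rate:g} {h.n_samples}"]
    for ch in range(h.n_channels):
        lines.append(
            f"{name}.dat 212 {h.gain_per_channel[ch]:g}"
            f"({h.baseline_per_channel[ch]})/mV 12 {h.baseline_per_channel[ch]}"
        )
    paths["header"].write_text("\n".join(lines) + "\n")
    paths["signal"].write_bytes(encode_format212(adc.T.reshape(-1)))
    write_annotations(record.annotations, paths["annotations"])
    return paths


def read_csv_signal(path: str | Path, sampling_rate: float = 360.0) -> EcgRecord:
    """Read a single-channel ``sample_index,amplitude_mV`` CSV as a record."""
    amplitudes = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() == "sample_index":
                continue
            amplitudes.append(float(row[1]))
    signal = np.asarray(amplitudes, dtype=float)[None, :]
    header = HeaderInfo(
        record_name=Path(path).stem,
        n_channels=1,
        sampling_rate=sampling_rate,
        n_samples=len(amplitudes),
    )
    return EcgRecord(header, signal)


def write_csv_signal(record: EcgRecord, path: str | Path, channel: int = 0) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_index", "amplitude_mV"])
        for i, v in enumerate(record.channel(channel)):
            writer.writerow([i, repr(float(v))])
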