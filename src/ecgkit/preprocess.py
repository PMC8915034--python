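"""Beat segmentation, Z-score normalization, labels, train/test split.

Each annotated beat becomes a fixed-length window (2160 samples = 6 s at
360 Hz) centered on the R-peak annotation, Z-score normalized per
segment, labeled 0 (normal, symbol ``'N'``) or 1 (any other beat
symbol). Segments are shuffled and split 80/20, stratified by label.
Windows from adjacent beats overlap by construction at normal heart
rates; that is intentional.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ecgkit.signal_io import Annotation, EcgRecord

logger = logging.getLogger(__name__)

SEGMENT_LENGTH = 2160

#: MIT-BIH-style non-beat annotation symbols (rhythm/quality markers).
NON_BEAT_SYMBOLS = frozenset('+~|s"TP=[]!x()pt*Du\'^@')

#: Beat symbols we recognize; everything not 'N' maps to abnormal (1).
BEAT_SYMBOLS = frozenset("NLRBAaJSVrFejnEfQ/")


@dataclass
class BeatSegment:
    """A fixed-length normalized beat window with its binary label."""

    samples: np.ndarray
    label: int
    source_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass
class Dataset:
    """Disjoint train/test beat segments plus the split bookkeeping."""

    train: list[BeatSegment]
    test: list[BeatSegment]
    seed: int
    label_map: dict[str, int] = field(default_factory=dict)

    def arrays(self, part: str) -> tuple[np.ndarray, np.ndarray]:
        """Stack one partition into ``(X, y)`` arrays."""
        segments = getattr(self, part)
        x = np.stack([s.samples for s in segments]) if segments else np.empty((0, 0))
        y = np.asarray([s.label for s in segments], dtype=int)
        return x, y


def segment_beats(
    record: EcgRecord, length: int = SEGMENT_LENGTH, channel: int = 0
) -> list[tuple[np.ndarray, Annotation]]:
    """Cut a centered window of ``length`` samples around each annotation.

    Annotations whose window would cross a record boundary are dropped
    (their count is logged). Returns raw (un-normalized) windows.
    """
    if length % 2:
        raise ValueError(f"segment length must be even, got {length}")
    signal = record.channel(channel)
    half = length // 2
    if signal.size < length:
        logger.warning(
            "record %s shorter than segment length (%d < %d); no segments",
            record.header.record_name, signal.size, length,
        )
        return []
    out = []
    dropped = 0
    for ann in record.annotations:
        lo = ann.sample_index - half
        hi = ann.sample_index + half
        if lo < 0 or hi > signal.size:
            dropped += 1
            continue
        out.append((signal[lo:hi].copy(), ann))
    if dropped:
        logger.info("dropped %d boundary-crossing annotations", dropped)
    return out


def zscore(segment: np.ndarray) -> np.ndarray:
    """Per-segment standardization ``(x - mean) / sd`` (population SD).

    Removes amplitude scaling and baseline offset. A constant segment
    (SD below 1e-12) maps to all zeros with a warning.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("cannot z-score an empty segment")
    sd = float(segment.std())
    if sd < 1e-12:
        logger.warning("constant segment (sd=%g); mapping to zeros", sd)
        return np.zeros_like(segment)
    return (segment - segment.mean()) / sd


def label_beats(symbols: list[str], strict: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Map beat symbols to binary labels: 'N' → 0, other beats → 1.

    Non-beat symbols (rhythm and signal-quality markers such as '+', '~')
    are excluded. Returns ``(labels, keep_mask)`` where ``keep_mask[i]``
    says whether symbol ``i`` survived. Unknown symbols are excluded by
    default; with ``strict=True`` they raise.
    """
    labels, keep = [], []
    excluded = 0
    for symbol in symbols:
        if symbol in NON_BEAT_SYMBOLS:
            keep.append(False)
            excluded += 1
        elif symbol in BEAT_SYMBOLS:
            keep.append(True)
            labels.append(0 if symbol == "N" else 1)
        elif strict:
            raise ValueError(f"unknown annotation symbol {symbol!r}")
        else:
            logger.warning("excluding unknown annotation symbol %r", symbol)
            keep.append(False)
            excluded += 1
    if excluded:
        logger.info("excluded %d non-beat annotations", excluded)
    return np.asarray(labels, dtype=int), np.asarray(keep, dtype=bool)


def make_segments(
    record: EcgRecord,
    length: int = SEGMENT_LENGTH,
    channel: int = 0,
    strict: bool = False,
) -> list[BeatSegment]:
    """Segment, label and normalize every usable beat in a record."""
    windows = segment_beats(record, length=length, channel=channel)
    symbols = [ann.symbol for _, ann in windows]
    labels, keep = label_beats(symbols, strict=strict)
    segments = []
    it = iter(labels)
    for (window, ann), kept in zip(windows, keep):
        if kept:
            segments.append(BeatSegment(zscore(window), int(next(it)), ann.sample_index))
    return segments


def split_dataset(
    segments: list[BeatSegment], ratio: float = 0.8, seed: int = 0
) -> Dataset:
    """Shuffle and split segments into train/test, stratified by label.

    Per stratum the train size is ``round(ratio * n)``, so the overall
    split is within one segment of the requested ratio. Single-class
    input falls back to a plain shuffled split with a warning.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    labels = np.asarray([s.label for s in segments])
    train: list[BeatSegment] = []
    test: list[BeatSegment] = []
    classes = np.unique(labels)
    if classes.size < 2:
        logger.warning("single-class input; falling back to a plain shuffled split")
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_train = int(round(ratio * idx.size))
        train.extend(segments[i] for i in idx[:n_train])
        test.extend(segments[i] for i in idx[n_train:])
    order_tr = rng.permutation(len(train))
    order_te = rng.permutation(len(test))
    return Dataset(
        train=[train[i] for i in order_tr],
        test=[test[i] for i in order_te],
        seed=seed,
        label_map={"N": 0, "other": 1},
    )


def save_dataset(dataset: Dataset, directory: str | Path) -> None:
    """Persist a dataset as .npy arrays plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for part in ("train", "test"):
        x, y = dataset.arrays(part)
        np.save(directory / f"{part}_x.npy", x)
        np.save(directory / f"{part}_y.npy", y)
    manifest = {
        "seed": dataset.seed,
        "label_map": dataset.label_map,
        "n_train": len(dataset.train),
        "n_test": len(dataset.test),
        "segment_length": int(dataset.train[0].samples.size) if dataset.train else 0,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def load_dataset(directory: str | Path) -> Dataset:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    parts = {}
    for part in ("train", "test"):
        x = np.load(directory / f"{part}_x.npy")
        y = np.load(directory / f"{part}_y.npy")
        parts[part] = [
            BeatSegment(x[i], int(y[i]), source_index=-1) for i in range(len(y))
        ]
    return Dataset(
        train=parts["train"],
        test=parts["test"],
        seed=manifest["seed"],
        label_map=manifest["label_map"],
    )
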