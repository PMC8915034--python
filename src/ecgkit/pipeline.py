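"""End-to-end workflows: the filter benchmark and the full
simulate → denoise → segment → train → evaluate pipeline.

The benchmark adds seeded noise to each record, applies every filter,
and scores each output with PSNR against the clean original; the
resulting table is sorted ascending by mean PSNR. The pipeline runs the
whole classification workflow from one config and writes a manifest
that suffices to reproduce the run (all seeds and settings; no
timestamps, so identical configs give byte-identical artifacts).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ecgkit import denoise as dn
from ecgkit.denoise import FilterConfig, apply_filter, default_filter_bank
from ecgkit.metrics import evaluate_predictions, psnr
from ecgkit.models import TrainConfig, build_and_train, model1_spec, model2_spec, model3_spec
from ecgkit.preprocess import make_segments, split_dataset
from ecgkit.signal_io import EcgRecord
from ecgkit.synthetic_ecg import NoiseSpec, SimulationConfig, add_noise, generate_clean_ecg

logger = logging.getLogger(__name__)

MODEL_SPECS = {"model1": model1_spec, "model2": model2_spec, "model3": model3_spec}


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for exit-code mapping."""

    STAGES = ("simulate", "denoise", "segment", "split", "train", "evaluate", "write")

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_benchmark(
    records: list[EcgRecord],
    noise: NoiseSpec,
    filters: dict[str, FilterConfig] | None = None,
    channel: int = 0,
    include_baseline: bool = True,
) -> pd.DataFrame:
    """Mean PSNR per filter over noisy copies of ``records``.

    Noise seeds derive from ``noise.seed`` plus the record index, so the
    realization is fixed per record. A filter failure on a record leaves
    a NaN cell and the run continues. Returns a DataFrame with columns
    ``filter`` and ``psnr_db``, sorted ascending by PSNR (worst first).
    """
    if not records:
        raise ValueError("need at least one record")
    filters = dict(filters) if filters is not None else default_filter_bank()
    if include_baseline:
        filters = {"none (noisy baseline)": None, **filters}
    scores: dict[str, list[float]] = {name: [] for name in filters}
    for i, record in enumerate(records):
        clean = record.channel(channel)
        spec_i = dataclasses.replace(noise, seed=noise.seed + i)
        noisy = add_noise(clean, spec_i, sampling_rate=record.sampling_rate)
        for name, config in filters.items():
            if config is None:
                scores[name].append(psnr(clean, noisy))
                continue
            try:
                denoised = apply_filter(noisy, config, sampling_rate=record.sampling_rate)
                scores[name].append(psnr(clean, denoised))
            except Exception as exc:  # per-cell failure, run continues
                logger.error("filter %s failed on record %d: %s", name, i, exc)
                scores[name].append(float("nan"))
    table = pd.DataFrame(
        {
            "filter": list(scores),
            "psnr_db": [float(np.nanmean(v)) for v in scores.values()],
        }
    )
    return table.sort_values("psnr_db", ascending=True, ignore_index=True)


@dataclass
class RunConfig:
    """One pipeline run: simulation conditions, filter, split and training."""

    seed: int = 0
    channel: int = 0
    model: str = "model3"
    filter_name: str = "median"
    segment_length: int = 2160
    split_ratio: float = 0.8
    simulation: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(duration=300.0, fraction_abnormal=0.3)
    )
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.model not in MODEL_SPECS:
            raise ValueError(f"unknown model {self.model!r}; choose from {sorted(MODEL_SPECS)}")
        if self.filter_name not in default_filter_bank():
            raise ValueError(f"unknown filter {self.filter_name!r}")

    def to_manifest(self) -> dict:
        out = dataclasses.asdict(self)
        out["simulation"]["normal"] = list(map(list, out["simulation"]["normal"]["components"]))
        out["simulation"]["abnormal"] = list(map(list, out["simulation"]["abnormal"]["components"]))
        return out


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute the full workflow and write artifacts to ``outdir``.

    Stages: simulate (clean record + additive noise) → denoise with the
    configured filter (default: median) → segment/normalize/label →
    stratified 80/20 split → train the configured CNN → evaluate on the
    test split. Any stage failure raises :class:`PipelineError` naming
    the stage; artifacts written so far are preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    sim = dataclasses.replace(config.simulation, seed=config.seed)
    record = stage("simulate", generate_clean_ecg, sim)
    noise = dataclasses.replace(config.noise, seed=config.seed + 1)
    noisy = stage(
        "simulate", add_noise, record.channel(config.channel), noise, record.sampling_rate
    )

    filter_config = default_filter_bank()[config.filter_name]
    denoised = stage("denoise", apply_filter, noisy, filter_config, record.sampling_rate)
    cleaned = record.with_signal(denoised[None, :])

    segments = stage("segment", make_segments, cleaned, length=config.segment_length)
    if not segments:
        raise PipelineError("segment", "no usable beat segments")
    dataset = stage("split", split_dataset, segments, config.split_ratio, config.seed + 2)

    train_cfg = dataclasses.replace(config.train, seed=config.seed + 3)
    model, history = stage("train", build_and_train, MODEL_SPECS[config.model](), dataset, train_cfg)

    x_test, y_test = dataset.arrays("test")
    scores = stage("evaluate", model.predict_scores, x_test)
    counts, report, roc = stage("evaluate", evaluate_predictions, y_test, scores)

    paths = {
        "manifest": outdir / "manifest.json",
        "metrics": outdir / "metrics.json",
        "history": outdir / "history.json",
        "roc": outdir / "roc.csv",
        "confusion": outdir / "confusion.csv",
    }

    def write() -> None:
        manifest = {
            "config": config.to_manifest(),
            "n_train": len(dataset.train),
            "n_test": len(dataset.test),
            "split_ratio": config.split_ratio,
            "model_parameters": model.n_parameters,
            "stage_seeds": {
                "simulate": config.seed,
                "noise": config.seed + 1,
                "split": config.seed + 2,
                "train": config.seed + 3,
            },
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        paths["metrics"].write_text(
            json.dumps(report.as_dict(), indent=2, sort_keys=True) + "\n"
        )
        paths["history"].write_text(json.dumps(history, indent=2) + "\n")
        pd.DataFrame(
            {"threshold": roc.thresholds, "tpr": roc.tpr, "fpr": roc.fpr}
        ).to_csv(paths["roc"], index=False)
        pd.DataFrame(
            [[counts.tp, counts.fp], [counts.fn, counts.tn]],
            index=["pred_1", "pred_0"],
            columns=["true_1", "true_0"],
        ).to_csv(paths["confusion"])

    stage("write", write)
    return paths


def filter_from_flags(name: str, **kwargs) -> FilterConfig:
    """Build a FilterConfig from CLI-style keyword flags (None = default)."""
    bank = {
        "median": dn.Median,
        "gaussian": dn.Gaussian,
        "moving-average": dn.MovingAverage,
        "moving_average": dn.MovingAverage,
        "savgol": dn.SavitzkyGolay,
        "butterworth": dn.ButterworthLowPass,
        "wavelet": dn.Wavelet,
    }
    if name not in bank:
        raise ValueError(f"unknown filter {name!r}")
    cls = bank[name]
    names = {f.name for f in dataclasses.fields(cls)}
    relevant = {k: v for k, v in kwargs.items() if v is not None and k in names}
    return cls(**relevant)
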