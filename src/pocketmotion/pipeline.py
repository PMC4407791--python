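"""End-to-end pipeline: raw logs -> pocket gating -> features -> evaluation.

`run_pipeline` chains the stages exactly as the recognition scheme orders
them: context sensors first decide *when* the phone is in a pocket, and only
motion data inside those intervals is windowed, featurized, and classified.
Windows therefore never leak out of in-pocket intervals — the gating
invariant asserted by the tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify_eval, features, pocket_detect, preprocess, sensor_io

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline, with the standard defaults.

    Defaults: 25 Hz sampling, 0.25 Hz gravity cutoff, 5 s edge trim, 1.6 s
    windows at 50 % overlap, 100 lux pocket threshold, 10-fold CV.
    """

    sample_rate_hz: float = 25.0
    gravity_cutoff_hz: float = 0.25
    trim_seconds: float = 5.0
    window_s: float = 1.6
    overlap: float = 0.5
    lux_threshold: float = 100.0
    folds: int = 10
    seed: int = 17
    classifier: str = "tree"

    def __post_init__(self) -> None:
        for name in ("sample_rate_hz", "gravity_cutoff_hz", "window_s",
                     "lux_threshold"):
            if not getattr(self, name) > 0:
                raise sensor_io.ValidationError(f"{name} must be > 0")
        if self.trim_seconds < 0:
            raise sensor_io.ValidationError("trim_seconds must be >= 0")
        if not 0 <= self.overlap < 1:
            raise sensor_io.ValidationError("overlap must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise sensor_io.ValidationError(
                f"unknown config keys: {sorted(unknown)}"
            )
        return cls(**data)


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run."""

    feature_table: pd.DataFrame
    pocket_intervals: list[tuple[float, float]]
    eval_report: classify_eval.EvalReport | None
    n_windows: int = 0
    warnings: list[str] = field(default_factory=list)


def _intersect_annotations(
    annotations: list[sensor_io.ActivityAnnotation],
    intervals: list[tuple[float, float]],
) -> list[sensor_io.ActivityAnnotation]:
    """Clip annotations to the in-pocket intervals (both half-open)."""
    out = []
    for a in annotations:
        for lo, hi in intervals:
            s, e = max(a.start_s, lo), min(a.end_s, hi)
            if s < e:
                out.append(sensor_io.ActivityAnnotation(s, e, a.label))
    return out


def run_pipeline(
    config: PipelineConfig,
    raw_log,
    context_log,
    annotations,
    out_dir=None,
) -> PipelineResult:
    """Run the full recognition pipeline on one recording.

    Parameters are file paths; ``annotations`` may also be a pre-parsed list.
    When ``out_dir`` is given, writes ``features.csv``, ``features.arff``,
    ``pocket_intervals.csv``, and — when evaluation ran — ``metrics.json``
    plus ``confusion.csv`` (byte-stable under fixed config and seed).
    """
    warnings: list[str] = []
    recording = sensor_io.read_raw_log(raw_log, rate_hz=config.sample_rate_hz)
    if recording.parse_report and recording.parse_report.n_malformed:
        warnings.append(
            f"{recording.parse_report.n_malformed} malformed rows in {raw_log}"
        )
    context = sensor_io.read_context_log(context_log)
    anns = (
        annotations
        if isinstance(annotations, list)
        else sensor_io.read_annotations(annotations)
    )
    logger.info(
        "loaded %d traces, %d context samples, %d annotations",
        len(recording.traces), len(context), len(anns),
    )

    rule = pocket_detect.PocketRuleConfig(lux_threshold=config.lux_threshold)
    intervals = pocket_detect.segment_in_pocket(context, rule)
    logger.info("in-pocket intervals: %s", intervals)

    gated = _intersect_annotations(anns, intervals)
    if not gated:
        msg = "no annotated data inside in-pocket intervals; zero windows"
        warnings.append(msg)
        logger.warning(msg)
        empty = pd.DataFrame(
            columns=list(features.FEATURE_NAMES) + [sensor_io.LABEL_COLUMN]
        )
        _write_artifacts(out_dir, empty, intervals, None)
        return PipelineResult(empty, intervals, None, 0, warnings)

    recording.annotations = sensor_io.validate_annotations(gated)
    recording = preprocess.trim_edges(recording, config.trim_seconds)
    signals = preprocess.derive_signals(
        recording, config.sample_rate_hz, config.gravity_cutoff_hz
    )
    windows = features.slide_windows(
        signals, config.window_s, config.overlap, recording.annotations
    )
    table = features.extract_feature_table(windows)
    logger.info("extracted %d windows x %d features", len(table),
                len(features.FEATURE_NAMES))

    report = None
    labels = table[sensor_io.LABEL_COLUMN].nunique() if len(table) else 0
    if len(table) >= config.folds and labels >= 2:
        spec = classify_eval.ClassifierSpec(kind=config.classifier)
        report = classify_eval.cross_validate(
            spec, table, k=config.folds, seed=config.seed
        )
        logger.info("%s", report.summary())
    else:
        msg = (
            f"evaluation skipped: {len(table)} windows / {labels} classes "
            f"insufficient for {config.folds}-fold CV"
        )
        warnings.append(msg)
        logger.warning(msg)

    _write_artifacts(out_dir, table, intervals, report)
    return PipelineResult(table, intervals, report, len(table), warnings)


def _write_artifacts(out_dir, table, intervals, report) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "pocket_intervals.csv", "w") as fh:
        fh.write("start_s,end_s\n")
        for lo, hi in intervals:
            fh.write(f"{lo:.6f},{hi:.6f}\n")
    if len(table):
        sensor_io.write_feature_table(table, out / "features.csv", "csv")
        sensor_io.write_feature_table(table, out / "features.arff", "arff")
    if report is not None:
        classify_eval.report(report, out)
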