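"""End-to-end orchestration: simulate -> speeds -> features -> fit -> validate.

``run_pipeline`` reproduces the whole analysis on a synthetic study from a
single seeded configuration and writes the standard artifacts: a per-type
speed summary, the cross-validated performance report, the coefficient table
with 95% CIs, calibration plots and a manifest sufficient to regenerate
every output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import throwspeed

from . import accel, kinematics, models, validation
from .errors import ConfigError, PipelineError, ThrowspeedError
from .synthdata import GeneratorConfig, Study, generate_study

__all__ = ["RunConfig", "run_pipeline", "extract_features", "speed_summary"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    ``seed`` is the single root of all randomness: the generator and the
    cross-validation fold assignment both derive from it.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cutoff_hz: float = 20.0
    filter_order: int = 2
    release_threshold_m: float = 0.01
    min_peak_g: float = accel.DEFAULT_MIN_PEAK
    refractory_s: float = accel.DEFAULT_REFRACTORY
    log_base: str = "e"
    log_units: str = "g"
    cv_k: int = 10
    seed: int = 0
    speed_source: str = "mocap"  # "mocap" (signal path) or "truth"
    write_signals: bool = False

    def __post_init__(self):
        if self.speed_source not in ("mocap", "truth"):
            raise ConfigError("speed_source", "must be 'mocap' or 'truth'")
        if self.generator.seed != self.seed:
            object.__setattr__(
                self, "generator", dataclasses.replace(self.generator, seed=self.seed)
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["type_mean_speeds"] = dict(d["generator"]["type_mean_speeds"])
        d["generator"]["type_speed_ranges"] = {
            k: list(v) for k, v in d["generator"]["type_speed_ranges"].items()
        }
        d["generator"]["accel_model_coefficients"]["type_offsets"] = dict(
            d["generator"]["accel_model_coefficients"]["type_offsets"]
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = dict(d.pop("generator", {}))
        if "accel_model_coefficients" in gen:
            coefs = dict(gen["accel_model_coefficients"])
            if "type_offsets" in coefs:
                coefs["type_offsets"] = dict(coefs["type_offsets"])
            gen["accel_model_coefficients"] = __import__(
                "throwspeed.synthdata", fromlist=["AccelModelCoefficients"]
            ).AccelModelCoefficients(**coefs)
        if "type_speed_ranges" in gen:
            gen["type_speed_ranges"] = {
                k: tuple(v) for k, v in gen["type_speed_ranges"].items()
            }
        d["generator"] = GeneratorConfig(**gen)
        return cls(**d)


def extract_features(study: Study, config: RunConfig) -> pd.DataFrame:
    """Run both measurement chains on a study and assemble feature rows.

    For every session: the accelerometer stream is segmented into per-throw
    peaks, each throw's marker trajectory is reduced to its release speed,
    and segments are paired with throws by time order (the session protocol
    separates throws by several seconds, so the pairing is unambiguous).
    """
    rows = []
    for session in study.sessions:
        pid = session.participant.participant_id
        try:
            stream = study.accel_stream(session)
            segments = accel.segment_throws(
                stream, min_peak=config.min_peak_g, refractory=config.refractory_s
            )
        except ThrowspeedError as exc:
            raise PipelineError("features", f"participant {pid}: {exc}") from exc
        if len(segments) != len(session.truths):
            raise PipelineError(
                "features",
                f"participant {pid}: segmented {len(segments)} throws but the "
                f"session contains {len(session.truths)}",
            )
        for truth, segment in zip(session.truths, segments):
            if config.speed_source == "mocap":
                try:
                    event = kinematics.release_speed_pipeline(
                        study.trajectory(truth),
                        cutoff=config.cutoff_hz,
                        order=config.filter_order,
                        threshold=config.release_threshold_m,
                    )
                except ThrowspeedError as exc:
                    raise PipelineError(
                        "speeds", f"throw {truth.throw_id}: {exc}"
                    ) from exc
                speed = event.release_speed
            else:
                speed = truth.true_release_speed
            rows.append(
                {
                    "throw_id": truth.throw_id,
                    "participant_id": pid,
                    "peak_total_accel_g": segment.peak_total_accel,
                    "log_peak_accel": accel.log_peak(
                        segment.peak_total_accel,
                        base=config.log_base,
                        units=config.log_units,
                    ),
                    "sex": truth.sex,
                    "throw_type": truth.throw_type,
                    "observed_speed_mps": speed,
                }
            )
    return pd.DataFrame(rows)


def speed_summary(features: pd.DataFrame) -> pd.DataFrame:
    """Per-type mean and range of the observed speeds (the cohort summary)."""
    grouped = features.groupby("throw_type", sort=False)["observed_speed_mps"]
    out = pd.DataFrame(
        {
            "mean_speed_mps": grouped.mean().round(1),
            "min_speed_mps": grouped.min().round(1),
            "max_speed_mps": grouped.max().round(1),
            "n_throws": grouped.size(),
        }
    )
    from .synthdata import THROW_TYPES

    return out.loc[[t for t in THROW_TYPES if t in out.index]]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the full analysis and write all artifacts under ``out_dir``.

    Returns a dict with the in-memory results: the study, feature table,
    fitted models and calibration reports.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        study = generate_study(config.generator)
    except ThrowspeedError as exc:
        raise PipelineError("simulate", str(exc)) from exc

    from .synthdata import write_truth_table

    write_truth_table(study.truth, out / "truth.csv")
    if config.write_signals:
        signals = out / "signals"
        signals.mkdir(exist_ok=True)
        for session in study.sessions:
            pid = session.participant.participant_id
            accel.write_stream(
                study.accel_stream(session), signals / f"{pid}_accel.csv"
            )
            for truth in session.truths:
                kinematics.write_trajectory(
                    study.trajectory(truth), signals / f"{truth.throw_id}_markers.csv"
                )

    features = extract_features(study, config)
    features.to_csv(out / "features.csv", index=False)
    speed_summary(features).to_csv(out / "speed_summary.csv", index_label="throw_type")

    fitted = {}
    coef_frames = []
    for name in models.MODEL_NAMES:
        try:
            fitted[name] = models.fit_model(features, name)
        except ThrowspeedError as exc:
            raise PipelineError("fit", f"model {name}: {exc}") from exc
        models.write_model(fitted[name], out / f"model_{name}.csv")
        coef_frames.append(
            pd.DataFrame(
                {
                    "model": name,
                    "term": fitted[name].params.index,
                    "estimate": fitted[name].params.round(6).to_numpy(),
                    "ci_low": fitted[name].conf_int["ci_low"].round(6).to_numpy(),
                    "ci_high": fitted[name].conf_int["ci_high"].round(6).to_numpy(),
                }
            )
        )
    pd.concat(coef_frames, ignore_index=True).to_csv(
        out / "coefficients.csv", index=False
    )

    reports = {}
    for name in models.MODEL_NAMES:
        reports[name] = validation.cross_validate(
            features, name, k=config.cv_k, seed=config.seed
        )
        validation.render_calibration_plot(
            reports[name], out / f"calibration_{name}.png"
        )
    validation.write_report_table(reports, out / "performance.csv")

    pooled = []
    for name, rep in reports.items():
        pooled.append(
            pd.DataFrame(
                {
                    "model": name,
                    "throw_id": features["throw_id"],
                    "observed_speed_mps": rep.observed,
                    "predicted_speed_mps": rep.predicted,
                    "fold": rep.fold_labels,
                }
            )
        )
    pd.concat(pooled, ignore_index=True).to_csv(
        out / "calibration_data.csv", index=False
    )

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "throwspeed": throwspeed.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "study": study,
        "features": features,
        "models": fitted,
        "reports": reports,
    }
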