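"""Orchestration: simulate -> classify -> metrics -> stats with one config.

``run_all`` produces a reproducible report bundle in the output directory:

* ``cohort.csv``           cohort table
* ``metrics.csv``          tidy per-trial and per-condition metrics
* ``stats_report.json``    model battery + paired condition contrasts
* ``coefficients.csv``     tidy coefficient table
* ``config_echo.json``     every analysis choice actually used
* ``run.log``              plain-text log

Each stage is also callable on its own (and from the CLI) through the
documented file formats, so stages can be run independently and diffed;
stage-wise and end-to-end execution produce identical artifacts for
identical seeds and configs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import metrics as gm
from . import stats as st
from . import synthetic as syn
from .errors import DyadGazeError, FormatError
from .geometry import AOISpec, default_eye_aoi, default_mouth_aoi
from .session_io import (
    GazeStream,
    Session,
    cohort_to_frame,
    read_cohort,
    read_manifest,
    read_session,
    write_cohort,
    write_gaze_stream,
    write_manifest,
    write_metrics_table,
    read_metrics_table,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"


class RunConfig(BaseModel):
    """Every analysis choice, echoed verbatim into the report bundle.

    With ``session_dir`` unset, sessions are simulated from the
    study-calibrated preset (optionally overridden); otherwise manifests
    under ``session_dir`` and the ``cohort_file`` are analysed.
    """

    output_dir: str
    seed: int = 0
    n_participants: Optional[int] = None
    session_dir: Optional[str] = None
    cohort_file: Optional[str] = None
    eye_radius_cm: float = Field(gt=0, default=6.3)
    mouth_radius_cm: float = Field(gt=0, default=6.3)
    denominator: Literal["valid", "total"] = "valid"
    mutuality: Literal["interaction", "of_eye_gaze"] = "interaction"
    max_offset_s: float = Field(gt=0, default=gm.DEFAULT_MAX_OFFSET_S)
    require_both_eyes: bool = False
    hc_type: Literal["HC0", "HC1", "HC2", "HC3"] = "HC3"
    combined_model: bool = False
    stream_overrides: Dict[str, object] = Field(default_factory=dict)
    cohort_overrides: Dict[str, object] = Field(default_factory=dict)
    effect_overrides: Dict[str, object] = Field(default_factory=dict)
    log_level: str = "INFO"


def _aois(config: RunConfig):
    return default_eye_aoi(config.eye_radius_cm), default_mouth_aoi(config.mouth_radius_cm)


def _analysis_kwargs(config: RunConfig) -> dict:
    eye_aoi, mouth_aoi = _aois(config)
    return dict(eye_aoi=eye_aoi, mouth_aoi=mouth_aoi,
                max_offset=config.max_offset_s,
                denominator=config.denominator, mutuality=config.mutuality,
                require_both_eyes=config.require_both_eyes)


def preset_from_config(config: RunConfig) -> syn.StudyPreset:
    preset = syn.study_preset()

    def merged(model, overrides):
        # revalidate so nested override dicts (e.g. one condition's effects)
        # are coerced and checked
        data = model.model_dump()
        for key, value in overrides.items():
            if isinstance(value, dict) and isinstance(data.get(key), dict):
                data[key] = {**data[key], **value}
            else:
                data[key] = value
        return type(model).model_validate(data)

    cohort = merged(preset.cohort, config.cohort_overrides)
    if config.n_participants is not None:
        cohort = cohort.model_copy(update={"n_participants": config.n_participants})
    return syn.StudyPreset(cohort=cohort,
                           effects=merged(preset.effects, config.effect_overrides),
                           stream=merged(preset.stream, config.stream_overrides))


def _iter_sessions(config: RunConfig):
    """Yield (participant_id, Session) pairs plus the cohort table."""
    if config.session_dir is not None:
        session_dir = Path(config.session_dir)
        manifests = sorted(session_dir.glob("*_session.json"))
        if not manifests:
            raise FormatError(f"no *_session.json manifests under {session_dir}")
        if config.cohort_file is None:
            raise FormatError("cohort_file is required when analysing session_dir")
        cohort_df = read_cohort(config.cohort_file)

        def sessions():
            for m in manifests:
                s = read_session(m)
                yield s.manifest.participant.id, s
        return cohort_df, sessions()

    preset = preset_from_config(config)
    participants, _targets, iterator = syn.generate_study(
        preset.cohort, preset.effects, preset.stream, master_seed=config.seed)
    cohort_df = cohort_to_frame(participants)

    def sessions():
        for synth in iterator:
            yield synth.participant.id, synth.session
    return cohort_df, sessions()


def analyze_sessions(session_pairs, config: RunConfig):
    """Run classification/pairing/aggregation over many sessions.

    Returns (trial_frame, condition_frame) in the tidy metrics layout.
    """
    kwargs = _analysis_kwargs(config)
    trial_frames, cond_frames = [], []
    for pid, session in session_pairs:
        trials, conditions, _series = gm.analyze_session(session, **kwargs)
        trial_frames.append(gm.trials_frame(pid, trials))
        cond_frames.append(gm.conditions_frame(pid, conditions))
    return (pd.concat(trial_frames, ignore_index=True),
            pd.concat(cond_frames, ignore_index=True))


def run_all(config: RunConfig) -> dict:
    """Execute the whole pipeline and write the report bundle.

    Deterministic: re-running with the same config and seed reproduces
    every artifact bit for bit. Raises on any integrity error (the CLI
    converts that into a nonzero exit status).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("dyadgaze")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        logger.info("analysis choices: denominator=%s mutuality=%s "
                    "eye_radius=%.2f cm max_offset=%.5f s hc_type=%s",
                    config.denominator, config.mutuality, config.eye_radius_cm,
                    config.max_offset_s, config.hc_type)
        cohort_df, sessions = _iter_sessions(config)
        trial_df, cond_df = analyze_sessions(sessions, config)
        write_cohort(cohort_df, outdir / "cohort.csv")
        write_metrics_table(trial_df, cond_df, outdir / "metrics.csv")
        report = st.run_models(cohort_df, cond_df, hc_type=config.hc_type,
                               combined=config.combined_model)
        report["meta"]["schema_version"] = REPORT_SCHEMA_VERSION
        report["meta"]["config"] = config.model_dump(mode="json")
        (outdir / "stats_report.json").write_text(json.dumps(report, indent=1))
        st.coefficient_table(report).to_csv(outdir / "coefficients.csv",
                                            index=False, float_format="%.17g")
        (outdir / "config_echo.json").write_text(
            json.dumps(config.model_dump(mode="json"), indent=1))
        logger.info("bundle written to %s", outdir)
        return report
    finally:
        root.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# stage functions (shared by the CLI)
# ---------------------------------------------------------------------------

def stage_simulate(output_dir, config: RunConfig) -> List[Path]:
    """Write cohort.csv plus per-participant session files (manifest + two
    gaze-stream CSVs) for later stage-wise processing."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    preset = preset_from_config(config)
    participants, _targets, iterator = syn.generate_study(
        preset.cohort, preset.effects, preset.stream, master_seed=config.seed)
    write_cohort(participants, outdir / "cohort.csv")
    paths = []
    for synth in iterator:
        manifest = synth.session.manifest
        for role, stream in (("participant", synth.session.participant_stream),
                             ("experimenter", synth.session.experimenter_stream)):
            write_gaze_stream(stream, outdir / manifest.stream_files[role])
        mpath = outdir / f"{synth.participant.id}_session.json"
        write_manifest(manifest, mpath)
        paths.append(mpath)
    return paths


_CLASSIFIED_COLUMNS = ["timestamp_s", "label", "u", "v"]


def stage_classify(manifest_path, output_dir, config: RunConfig) -> List[Path]:
    """Classify both directions of one session and write label CSVs."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    session = read_session(manifest_path)
    kwargs = _analysis_kwargs(config)
    paths = []
    for series_owner, a, b in (
            ("participant", session.participant_stream, session.experimenter_stream),
            ("experimenter", session.experimenter_stream, session.participant_stream)):
        series = gm.classify_stream(a, b, kwargs["eye_aoi"], kwargs["mouth_aoi"],
                                    kwargs["max_offset"], kwargs["require_both_eyes"])
        df = pd.DataFrame({"timestamp_s": series.timestamps,
                           "label": series.labels,
                           "u": series.uv[:, 0], "v": series.uv[:, 1]})
        path = outdir / f"{session.manifest.participant.id}_{series_owner}_classified.csv"
        df.to_csv(path, index=False, float_format="%.17g")
        paths.append(path)
    return paths


def _read_classified(path, person: str) -> gm.ClassifiedSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CLASSIFIED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: classified series missing columns {missing}")
    return gm.ClassifiedSeries(
        person=person,
        timestamps=df["timestamp_s"].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=np.int8),
        uv=df[["u", "v"]].to_numpy(dtype=float))


def stage_metrics(session_dir, classified_dir, out_csv, config: RunConfig) -> None:
    """Aggregate classified label series into the tidy metrics CSV."""
    session_dir, classified_dir = Path(session_dir), Path(classified_dir)
    manifests = sorted(session_dir.glob("*_session.json"))
    if not manifests:
        raise FormatError(f"no *_session.json manifests under {session_dir}")
    trial_frames, cond_frames = [], []
    for mpath in manifests:
        manifest = read_manifest(mpath)
        pid = manifest.participant.id
        p_series = _read_classified(
            classified_dir / f"{pid}_participant_classified.csv", "participant")
        e_series = _read_classified(
            classified_dir / f"{pid}_experimenter_classified.csv", "experimenter")
        paired = gm.pair_nearest_in_time(p_series, e_series, config.max_offset_s)
        trials = [gm.trial_percentages(p_series, paired, t,
                                       denominator=config.denominator,
                                       mutuality=config.mutuality)
                  for t in manifest.trials]
        kept = [tm for tr, tm in zip(manifest.trials, trials) if not tr.excluded]
        conditions = gm.condition_metrics(kept)
        trial_frames.append(gm.trials_frame(pid, trials))
        cond_frames.append(gm.conditions_frame(pid, conditions))
    write_metrics_table(pd.concat(trial_frames, ignore_index=True),
                        pd.concat(cond_frames, ignore_index=True), out_csv)


def stage_stats(metrics_csv, cohort_csv, out_json, config: RunConfig) -> dict:
    """Fit the model battery on a metrics table and write the JSON report."""
    cohort_df = read_cohort(cohort_csv)
    _trial_df, cond_df = read_metrics_table(metrics_csv)
    report = st.run_models(cohort_df, cond_df, hc_type=config.hc_type,
                           combined=config.combined_model)
    report["meta"]["schema_version"] = REPORT_SCHEMA_VERSION
    report["meta"]["config"] = config.model_dump(mode="json")
    Path(out_json).write_text(json.dumps(report, indent=1))
    return report
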