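"""Data model and readers/writers for gaze streams, session manifests,
cohort tables and metric outputs.

Formats (all plain text, versioned here):

* gaze stream — CSV, one row per video frame, columns
  ``timestamp_s, person, lx..lz, rx..rz, mx..mz, nx..nz,
  lox..loz, ldx..ldz, rox..roz, rdx..rdz, valid``
  (landmarks of the *recorded* person; ``l``/``r`` eye, ``m`` mouth,
  ``n`` nose optional; ``lo/ld`` and ``ro/rd`` left/right gaze-ray origins
  and directions, empty when the frame is missing). Timestamps are seconds
  from session start. Readers reject malformed input naming the row.
* session manifest — JSON validating against :class:`SessionManifest`.
* cohort table — CSV with ``id, age, sex, aq, aq_instrument, discomfort``
  (sex coded 0 = female, 1 = male).
* metrics table — tidy CSV with one row per (participant, trial) and one
  per (participant, condition), distinguished by the ``level`` column.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import FormatError, IntegrityError
from .geometry import GazeRay, LandmarkSet

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

#: seconds; nominal trial length in the word-guessing game.
NOMINAL_TRIAL_S = 90.0
#: seconds; per-word time cap in the game.
WORD_CAP_S = 20.0
#: fraction of a trial that may lack stream coverage before integrity fails.
MAX_UNCOVERED_FRACTION = 0.05
#: backward-jitter tolerance as a fraction of the nominal frame interval.
JITTER_TOLERANCE_FRACTION = 0.2

_COORD_GROUPS = {
    "left_eye": ("lx", "ly", "lz"),
    "right_eye": ("rx", "ry", "rz"),
    "mouth": ("mx", "my", "mz"),
    "nose": ("nx", "ny", "nz"),
    "left_origin": ("lox", "loy", "loz"),
    "left_dir": ("ldx", "ldy", "ldz"),
    "right_origin": ("rox", "roy", "roz"),
    "right_dir": ("rdx", "rdy", "rdz"),
}
STREAM_COLUMNS = ["timestamp_s", "person"] + [
    c for cols in _COORD_GROUPS.values() for c in cols
] + ["valid"]
_MANDATORY = [c for c in STREAM_COLUMNS if c not in _COORD_GROUPS["nose"]]


# ---------------------------------------------------------------------------
# in-memory containers
# ---------------------------------------------------------------------------

@dataclass
class GazeSampleRecord:
    """One time-stamped observation of a person: self landmarks plus
    binocular gaze rays (absent when the frame is missing)."""

    timestamp: float
    person: str
    landmarks: LandmarkSet
    left_ray: Optional[GazeRay] = None
    right_ray: Optional[GazeRay] = None
    valid: bool = True

    def __post_init__(self):
        if self.valid and self.left_ray is None and self.right_ray is None:
            raise FormatError(
                f"record at t={self.timestamp}: valid=True but both rays absent"
            )
        if not self.valid and (self.left_ray is not None or self.right_ray is not None):
            raise FormatError(
                f"record at t={self.timestamp}: valid=False but rays present"
            )


@dataclass
class GazeStream:
    """Array-backed gaze stream for one person (one row per frame).

    Ray fields hold NaN rows where the frame is missing; landmark fields are
    always present (head tracking outlives gaze estimation).
    """

    person: str
    timestamps: np.ndarray          # (n,)
    left_eye: np.ndarray            # (n, 3) landmark
    right_eye: np.ndarray           # (n, 3)
    mouth: np.ndarray               # (n, 3)
    left_origin: np.ndarray         # (n, 3) ray origins / directions
    left_dir: np.ndarray
    right_origin: np.ndarray
    right_dir: np.ndarray
    valid: np.ndarray               # (n,) bool
    nose: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return self.timestamps.shape[0]

    @property
    def landmark_centroid(self) -> np.ndarray:
        return (self.left_eye + self.right_eye + self.mouth) / 3.0

    def window(self, start: float, end: float) -> np.ndarray:
        """Boolean mask of frames with start <= t < end."""
        return (self.timestamps >= start) & (self.timestamps < end)

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self)
        data = {"timestamp_s": self.timestamps, "person": np.repeat(self.person, n)}
        arrays = {
            "left_eye": self.left_eye, "right_eye": self.right_eye,
            "mouth": self.mouth,
            "nose": self.nose if self.nose is not None else np.full((n, 3), np.nan),
            "left_origin": self.left_origin, "left_dir": self.left_dir,
            "right_origin": self.right_origin, "right_dir": self.right_dir,
        }
        for group, cols in _COORD_GROUPS.items():
            arr = arrays[group]
            for j, c in enumerate(cols):
                data[c] = arr[:, j]
        data["valid"] = self.valid.astype(int)
        return pd.DataFrame(data, columns=STREAM_COLUMNS)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, person: Optional[str] = None) -> "GazeStream":
        person = person if person is not None else str(df["person"].iloc[0])
        nose = df[list(_COORD_GROUPS["nose"])].to_numpy(dtype=float)
        return cls(
            person=person,
            timestamps=df["timestamp_s"].to_numpy(dtype=float),
            left_eye=df[list(_COORD_GROUPS["left_eye"])].to_numpy(dtype=float),
            right_eye=df[list(_COORD_GROUPS["right_eye"])].to_numpy(dtype=float),
            mouth=df[list(_COORD_GROUPS["mouth"])].to_numpy(dtype=float),
            left_origin=df[list(_COORD_GROUPS["left_origin"])].to_numpy(dtype=float),
            left_dir=df[list(_COORD_GROUPS["left_dir"])].to_numpy(dtype=float),
            right_origin=df[list(_COORD_GROUPS["right_origin"])].to_numpy(dtype=float),
            right_dir=df[list(_COORD_GROUPS["right_dir"])].to_numpy(dtype=float),
            valid=df["valid"].to_numpy(dtype=float).astype(bool),
            nose=None if np.isnan(nose).all() else nose,
        )

    def to_records(self) -> List[GazeSampleRecord]:
        records = []
        for i in range(len(self)):
            lm = LandmarkSet(
                self.left_eye[i], self.right_eye[i], self.mouth[i],
                None if self.nose is None or np.isnan(self.nose[i]).any() else self.nose[i],
            )
            if self.valid[i]:
                lray = (GazeRay(self.left_origin[i], self.left_dir[i])
                        if np.isfinite(self.left_dir[i]).all() else None)
                rray = (GazeRay(self.right_origin[i], self.right_dir[i])
                        if np.isfinite(self.right_dir[i]).all() else None)
            else:
                lray = rray = None
            records.append(GazeSampleRecord(
                float(self.timestamps[i]), self.person, lm, lray, rray,
                bool(self.valid[i])))
        return records

    @classmethod
    def from_records(cls, records: Sequence[GazeSampleRecord]) -> "GazeStream":
        if not records:
            raise FormatError("cannot build a stream from zero records")
        n = len(records)
        def stack(fn):
            return np.array([fn(r) for r in records], dtype=float)
        nan3 = np.full(3, np.nan)
        nose = stack(lambda r: r.landmarks.nose if r.landmarks.nose is not None else nan3)
        return cls(
            person=records[0].person,
            timestamps=np.array([r.timestamp for r in records], dtype=float),
            left_eye=stack(lambda r: r.landmarks.left_eye),
            right_eye=stack(lambda r: r.landmarks.right_eye),
            mouth=stack(lambda r: r.landmarks.mouth),
            left_origin=stack(lambda r: r.left_ray.origin if r.left_ray else nan3),
            left_dir=stack(lambda r: r.left_ray.direction if r.left_ray else nan3),
            right_origin=stack(lambda r: r.right_ray.origin if r.right_ray else nan3),
            right_dir=stack(lambda r: r.right_ray.direction if r.right_ray else nan3),
            valid=np.array([r.valid for r in records], dtype=bool),
            nose=None if np.isnan(nose).all() else nose,
        )


# ---------------------------------------------------------------------------
# manifest schema
# ---------------------------------------------------------------------------

class ParticipantMeta(BaseModel):
    """Cohort-level metadata for one participant.

    ``sex`` is coded 0 = female, 1 = male throughout the design matrices;
    ``aq`` is the autism-spectrum-quotient total under 4-point item scoring,
    on one common scale regardless of ``aq_instrument``.
    """

    id: str
    age: float = Field(gt=0)
    sex: Literal[0, 1]
    aq: float = Field(ge=0, le=150)
    aq_instrument: Literal["adult", "adolescent"] = "adult"
    discomfort: bool
    role_note: Optional[str] = None


class WordEvent(BaseModel):
    """One word in the describing game: display onset to guess/timeout."""

    onset: float
    end: float
    guessed: bool = True

    @model_validator(mode="after")
    def _check_duration(self):
        dur = self.end - self.onset
        if dur <= 0:
            raise ValueError(f"word event at {self.onset}: non-positive duration")
        if dur > WORD_CAP_S + 1e-9:
            raise ValueError(
                f"word event at {self.onset}: duration {dur:.2f}s exceeds the "
                f"{WORD_CAP_S:.0f}s cap")
        return self


class Trial(BaseModel):
    """One 90 s game round; ``condition`` is the participant's role."""

    index: int = Field(ge=0)
    condition: Literal["GUESS", "DESCRIBE"]
    start: float
    end: float
    word_events: List[WordEvent] = Field(default_factory=list)
    excluded: bool = False
    exclusion_reason: Optional[str] = None

    @model_validator(mode="after")
    def _check_interval(self):
        if self.end <= self.start:
            raise ValueError(f"trial {self.index}: end must exceed start")
        return self


class Fixation(BaseModel):
    landmark: Literal["left_eye", "right_eye", "nose", "mouth"]
    onset: float
    duration: float = 5.0


class CalibrationSegment(BaseModel):
    """Scheduled fixation block: left eye, right eye, nose and mouth,
    5 s each, twice."""

    start: float
    end: float
    fixation_schedule: List[Fixation]

    @model_validator(mode="after")
    def _check_schedule(self):
        counts: Dict[str, int] = {}
        for fx in self.fixation_schedule:
            counts[fx.landmark] = counts.get(fx.landmark, 0) + 1
        expected = {"left_eye": 2, "right_eye": 2, "nose": 2, "mouth": 2}
        if counts != expected:
            raise ValueError(
                f"calibration schedule must cover each landmark twice, got {counts}")
        return self


class SessionManifest(BaseModel):
    """Everything needed to locate and interpret one dyadic session."""

    schema_version: str = SCHEMA_VERSION
    participant: ParticipantMeta
    trials: List[Trial]
    calibration_segments: List[CalibrationSegment] = Field(default_factory=list)
    stream_files: Dict[Literal["participant", "experimenter"], str]
    sampling_rate_hz: float = Field(gt=0, default=60.0)

    @model_validator(mode="after")
    def _check_trials(self):
        if len(self.trials) != 4:
            raise ValueError(f"expected 4 trials, got {len(self.trials)}")
        conds = [t.condition for t in self.trials]
        if conds.count("GUESS") != 2 or conds.count("DESCRIBE") != 2:
            raise ValueError(f"expected 2 GUESS and 2 DESCRIBE trials, got {conds}")
        intervals = sorted((t.start, t.end) for t in self.trials)
        for (s0, e0), (s1, e1) in zip(intervals, intervals[1:]):
            if s1 < e0:
                raise ValueError("trial intervals overlap")
        return self


@dataclass
class Session:
    """A manifest plus the two loaded gaze streams."""

    manifest: SessionManifest
    participant_stream: GazeStream
    experimenter_stream: GazeStream


# ---------------------------------------------------------------------------
# stream I/O
# ---------------------------------------------------------------------------

def write_gaze_stream(stream, path) -> None:
    """Write a gaze stream (GazeStream or record list) to CSV.

    Floats are written with 17 significant digits so read(write(x)) is exact.
    Valid records must have finite landmark and ray coordinates.
    """
    if not isinstance(stream, GazeStream):
        if len(stream) == 0:
            pd.DataFrame(columns=STREAM_COLUMNS).to_csv(path, index=False)
            return
        stream = GazeStream.from_records(stream)
    df = stream.to_dataframe()
    core = [c for grp in ("left_eye", "right_eye", "mouth") for c in _COORD_GROUPS[grp]]
    bad = df.loc[df["valid"] == 1, core + ["timestamp_s"]].isna().any(axis=1)
    ray_cols = [c for grp in ("left_origin", "left_dir", "right_origin", "right_dir")
                for c in _COORD_GROUPS[grp]]
    all_rays_nan = df.loc[df["valid"] == 1, ray_cols].isna().all(axis=1)
    bad = bad | all_rays_nan
    if bad.any():
        row = int(bad.idxmax())
        raise FormatError(f"row {row}: NaN coordinates in a record marked valid")
    df.to_csv(path, index=False, float_format="%.17g")


def read_gaze_stream(path, person: Optional[str] = None,
                     nominal_rate_hz: float = 60.0) -> GazeStream:
    """Read a gaze-stream CSV, validating schema and timestamp order.

    Rejects (never coerces): missing mandatory columns, unparseable
    numerics, NaN coordinates on valid rows, and backward timestamp jumps
    beyond 20% of the nominal frame interval. Every rejection names the
    offending row. Invalid (missing-gaze) rows are kept and flagged.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"gaze stream file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    for c in _COORD_GROUPS["nose"]:
        if c not in df.columns:
            df[c] = ""
    numeric_cols = [c for c in STREAM_COLUMNS if c != "person"]
    out = {}
    for c in numeric_cols:
        col = df[c].replace("", np.nan)
        converted = pd.to_numeric(col, errors="coerce")
        bad = converted.isna() & col.notna()
        if bad.any():
            row = int(bad.idxmax())
            raise FormatError(f"{path}: row {row}: unparseable value in column {c!r}")
        # exact (correctly rounded) parse so write/read round-trips bitwise
        out[c] = col.astype(float)
    clean = pd.DataFrame(out)
    clean["person"] = df["person"] if "person" in df else (person or "participant")
    ts = clean["timestamp_s"].to_numpy(dtype=float)
    if np.isnan(ts).any():
        row = int(np.argmax(np.isnan(ts)))
        raise FormatError(f"{path}: row {row}: missing timestamp")
    tolerance = JITTER_TOLERANCE_FRACTION / nominal_rate_hz
    backward = np.diff(ts) < -tolerance
    if backward.any():
        row = int(np.argmax(backward)) + 1
        raise FormatError(
            f"{path}: row {row}: timestamp decreases beyond jitter tolerance "
            f"({ts[row]:.6f} after {ts[row - 1]:.6f})")
    # rows with all ray fields empty are missing frames, regardless of 'valid'
    ray_cols = [c for grp in ("left_dir", "right_dir") for c in _COORD_GROUPS[grp]]
    no_rays = clean[ray_cols].isna().all(axis=1)
    valid = clean["valid"].fillna(0).astype(float).astype(bool) & ~no_rays
    clean["valid"] = valid.astype(int)
    core = [c for grp in ("left_eye", "right_eye", "mouth") for c in _COORD_GROUPS[grp]]
    bad_core = clean.loc[valid, core].isna().any(axis=1)
    if bad_core.any():
        row = int(bad_core.idxmax())
        raise FormatError(f"{path}: row {row}: NaN landmark on a valid record")
    stream = GazeStream.from_dataframe(clean, person=person)
    n_flagged = int((~valid).sum())
    logger.info("read %s: %d records parsed, %d flagged missing",
                path, len(stream), n_flagged)
    return stream


# ---------------------------------------------------------------------------
# session / manifest I/O
# ---------------------------------------------------------------------------

def write_manifest(manifest: SessionManifest, path) -> None:
    Path(path).write_text(manifest.model_dump_json(indent=1))


def read_manifest(path) -> SessionManifest:
    try:
        return SessionManifest.model_validate_json(Path(path).read_text())
    except Exception as exc:  # pydantic ValidationError or JSON error
        raise FormatError(f"{path}: manifest does not validate: {exc}") from exc


def check_trial_coverage(manifest: SessionManifest, streams: Dict[str, GazeStream]) -> pd.DataFrame:
    """Per-trial sample counts for both streams; raises IntegrityError when
    more than 5% of a trial's expected frames are uncovered."""
    rate = manifest.sampling_rate_hz
    rows = []
    problems = []
    for trial in manifest.trials:
        expected = (trial.end - trial.start) * rate
        for role, stream in streams.items():
            n = int(stream.window(trial.start, trial.end).sum())
            rows.append({"trial": trial.index, "role": role, "n_frames": n,
                         "expected": expected})
            if expected > 0 and n < (1.0 - MAX_UNCOVERED_FRACTION) * expected:
                problems.append(
                    f"trial {trial.index} ({trial.condition}) {role} stream: "
                    f"{n} frames, expected about {expected:.0f}")
    if problems:
        raise IntegrityError("stream/trial coverage failure: " + "; ".join(problems))
    return pd.DataFrame(rows)


def read_session(manifest_path) -> Session:
    """Load a manifest and both streams, cross-checking trial coverage."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    streams = {}
    for role in ("participant", "experimenter"):
        stream_path = manifest_path.parent / manifest.stream_files[role]
        streams[role] = read_gaze_stream(stream_path, person=role,
                                         nominal_rate_hz=manifest.sampling_rate_hz)
    coverage = check_trial_coverage(manifest, streams)
    logger.info("session %s: per-trial coverage\n%s", manifest_path, coverage)
    return Session(manifest, streams["participant"], streams["experimenter"])


# ---------------------------------------------------------------------------
# cohort and metrics tables
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["id", "age", "sex", "aq", "aq_instrument", "discomfort"]


def cohort_to_frame(participants: Sequence[ParticipantMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": p.id, "age": p.age, "sex": p.sex, "aq": p.aq,
          "aq_instrument": p.aq_instrument, "discomfort": int(p.discomfort)}
         for p in participants], columns=COHORT_COLUMNS)


def write_cohort(participants, path) -> None:
    df = participants if isinstance(participants, pd.DataFrame) else cohort_to_frame(participants)
    df.to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: cohort table missing columns {missing}")
    if not df["sex"].isin([0, 1]).all():
        row = int((~df["sex"].isin([0, 1])).idxmax())
        raise FormatError(f"{path}: row {row}: sex must be coded 0 (female) / 1 (male)")
    df["discomfort"] = df["discomfort"].astype(int)
    return df


METRICS_COLUMNS = [
    "participant_id", "level", "trial_index", "condition",
    "eye_gaze_pct", "mutual_pct", "missing_pct", "n_valid", "n_paired",
]


def write_metrics_table(trial_frame: pd.DataFrame, condition_frame: pd.DataFrame,
                        path) -> None:
    """Write the tidy metrics CSV: trial-level rows then condition-level rows."""
    trial = trial_frame.copy()
    trial["level"] = "trial"
    cond = condition_frame.copy()
    cond["level"] = "condition"
    if "trial_index" not in cond:
        cond["trial_index"] = np.nan
    combined = pd.concat([trial, cond], ignore_index=True)
    for col in METRICS_COLUMNS:
        if col not in combined:
            combined[col] = np.nan
    combined[METRICS_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_metrics_table(path) -> Tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metrics table missing columns {missing}")
    trial = df[df["level"] == "trial"].reset_index(drop=True)
    cond = df[df["level"] == "condition"].reset_index(drop=True)
    return trial, cond
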