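"""Frame classification, temporal pairing, and trial/condition gaze metrics.

The measurement chain per person A gazing at person B:

1. for each A-frame take B's nearest-in-time landmarks, estimate B's
   facial plane, intersect A's two gaze rays and average them
   (:func:`classify_stream`);
2. label the intersection EYE / MOUTH / OTHER by landmark distance,
   or MISSING when gaze could not be estimated;
3. pair the two classified series nearest-in-time
   (:func:`pair_nearest_in_time`) and flag mutual eye contact on frames
   where both labels are EYE (:func:`mutual_contact`);
4. aggregate percentages per trial, then average per condition
   (:func:`trial_percentages`, :func:`condition_metrics`).

Percentages default to the valid-time denominator (non-missing frames);
missingness is accounted separately, so the two do not mix. Mutual eye
contact defaults to the fraction of valid paired interaction time; the
fraction-of-own-eye-gaze reading is available via ``mutuality="of_eye_gaze"``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import geometry
from .errors import IntegrityError
from .geometry import AOISpec, GazeLabel
from .session_io import CalibrationSegment, GazeStream, Session, Trial

__all__ = [
    "DEFAULT_MAX_OFFSET_S",
    "ClassifiedSeries",
    "PairedFrames",
    "MutualResult",
    "TrialMetrics",
    "ConditionMetrics",
    "classify_stream",
    "pair_nearest_in_time",
    "mutual_contact",
    "trial_percentages",
    "condition_metrics",
    "compute_calibration_error",
    "analyze_session",
    "trials_frame",
    "conditions_frame",
]

#: seconds; half the nominal 60 Hz frame interval.
DEFAULT_MAX_OFFSET_S = 1.0 / 120.0

_EYE = int(GazeLabel.EYE)
_MISSING = int(GazeLabel.MISSING)


@dataclass
class ClassifiedSeries:
    """Per-frame AOI labels for one person looking at the other, with the
    in-plane (u, v) coordinates of each valid gaze point (NaN otherwise)."""

    person: str
    timestamps: np.ndarray   # (n,) strictly increasing
    labels: np.ndarray       # (n,) int8 GazeLabel values
    uv: np.ndarray           # (n, 2) cm in the partner's facial plane

    def __post_init__(self):
        if len(self.timestamps) and np.any(np.diff(self.timestamps) <= 0):
            raise IntegrityError(
                f"{self.person}: classified series timestamps must be "
                "strictly increasing")

    def __len__(self) -> int:
        return self.timestamps.shape[0]

    def window(self, start: float, end: float) -> np.ndarray:
        return (self.timestamps >= start) & (self.timestamps < end)


@dataclass
class PairedFrames:
    """Nearest-in-time pairing of two classified series (one pair per
    A-frame with a B-frame within ``max_offset``; ties go to the earlier
    B-frame)."""

    t_a: np.ndarray
    t_b: np.ndarray
    label_a: np.ndarray
    label_b: np.ndarray
    offset: np.ndarray
    idx_a: np.ndarray
    idx_b: np.ndarray
    n_unmatched: int

    def __len__(self) -> int:
        return self.t_a.shape[0]


@dataclass
class MutualResult:
    """Mutual-eye-contact flags over valid (neither-missing) pairs."""

    flags: np.ndarray        # bool, one per valid pair
    mutual_pct: float        # NaN when undefined
    n_valid_pairs: int
    defined: bool
    valid_mask: np.ndarray   # bool over all pairs


@dataclass
class TrialMetrics:
    """Percentages for one trial; NaN percentages carry a defined=False flag."""

    trial_index: int
    condition: str
    eye_gaze_pct: float
    mutual_pct: float
    missing_pct: float
    n_valid: int
    n_paired: int
    n_frames: int
    eye_defined: bool = True
    mutual_defined: bool = True
    mouth_pct: float = math.nan


@dataclass
class ConditionMetrics:
    """Unweighted mean over one participant's (non-excluded) trials."""

    condition: str
    eye_gaze_pct: float
    mutual_pct: float
    missing_pct: float
    mouth_pct: float
    n_trials: int


# ---------------------------------------------------------------------------
# classification and pairing
# ---------------------------------------------------------------------------

def _nearest_indices(t_query: np.ndarray, t_ref: np.ndarray) -> np.ndarray:
    """Index of the nearest t_ref for each t_query; ties -> earlier frame."""
    pos = np.searchsorted(t_ref, t_query)
    left = np.clip(pos - 1, 0, len(t_ref) - 1)
    right = np.clip(pos, 0, len(t_ref) - 1)
    d_left = np.abs(t_query - t_ref[left])
    d_right = np.abs(t_query - t_ref[right])
    return np.where(d_left <= d_right, left, right)  # <= favours the earlier frame


def classify_stream(
    stream_a: GazeStream,
    stream_b: GazeStream,
    eye_aoi: Optional[AOISpec] = None,
    mouth_aoi: Optional[AOISpec] = None,
    max_offset: float = DEFAULT_MAX_OFFSET_S,
    require_both_eyes: bool = False,
) -> ClassifiedSeries:
    """Classify person A's gaze on person B's face, frame by frame.

    For each A-sample, B's nearest-in-time landmark set defines the facial
    plane (the AOI moves with B's head). A frame is MISSING when A's gaze
    is missing, no B landmarks lie within ``max_offset``, or no ray meets
    the plane in front of the eye. With ``require_both_eyes`` the one-eye
    fallback is disabled.
    """
    if len(stream_a) == 0 or len(stream_b) == 0:
        raise IntegrityError("cannot classify an empty stream")
    eye_aoi = eye_aoi if eye_aoi is not None else geometry.default_eye_aoi()
    mouth_aoi = mouth_aoi if mouth_aoi is not None else geometry.default_mouth_aoi()

    idx = _nearest_indices(stream_a.timestamps, stream_b.timestamps)
    offset = np.abs(stream_a.timestamps - stream_b.timestamps[idx])
    no_target = offset > max_offset

    le, re, mo = stream_b.left_eye[idx], stream_b.right_eye[idx], stream_b.mouth[idx]
    planes = geometry.planes_from_landmark_arrays(
        le, re, mo, toward=stream_a.landmark_centroid)

    pts_l, t_l, ok_l = geometry.intersect_ray_plane_arrays(
        stream_a.left_origin, stream_a.left_dir, planes["origin"], planes["normal"])
    pts_r, t_r, ok_r = geometry.intersect_ray_plane_arrays(
        stream_a.right_origin, stream_a.right_dir, planes["origin"], planes["normal"])

    if require_both_eyes:
        ok = ok_l & ok_r
        points = np.where(ok[:, None], 0.5 * (pts_l + pts_r), np.nan)
    else:
        both = ok_l & ok_r
        points = np.full_like(pts_l, np.nan)
        points[both] = 0.5 * (pts_l[both] + pts_r[both])
        only_l = ok_l & ~ok_r
        points[only_l] = pts_l[only_l]
        only_r = ok_r & ~ok_l
        points[only_r] = pts_r[only_r]
        ok = ok_l | ok_r

    invalid = ~stream_a.valid | no_target | ~ok | planes["degenerate"]
    labels = geometry.classify_point_arrays(
        points, invalid, le, re, mo,
        eye_radius=eye_aoi.radius, mouth_radius=mouth_aoi.radius)

    rel = points - planes["origin"]
    uv = np.stack([
        np.einsum("ij,ij->i", rel, planes["u_axis"]),
        np.einsum("ij,ij->i", rel, planes["v_axis"]),
    ], axis=1)
    uv[invalid] = np.nan
    return ClassifiedSeries(stream_a.person, stream_a.timestamps.copy(),
                            labels, uv)


def pair_nearest_in_time(
    series_a: ClassifiedSeries,
    series_b: ClassifiedSeries,
    max_offset: float = DEFAULT_MAX_OFFSET_S,
) -> PairedFrames:
    """Pair each A-frame with its nearest B-frame within ``max_offset``.

    Deterministic; unmatched A-frames are excluded and counted.
    """
    if len(series_b) == 0:
        empty = np.array([], dtype=float)
        return PairedFrames(empty, empty, empty.astype(np.int8),
                            empty.astype(np.int8), empty,
                            empty.astype(int), empty.astype(int),
                            n_unmatched=len(series_a))
    idx_b = _nearest_indices(series_a.timestamps, series_b.timestamps)
    offset = np.abs(series_a.timestamps - series_b.timestamps[idx_b])
    keep = offset <= max_offset
    idx_a = np.nonzero(keep)[0]
    idx_b = idx_b[keep]
    return PairedFrames(
        t_a=series_a.timestamps[idx_a],
        t_b=series_b.timestamps[idx_b],
        label_a=series_a.labels[idx_a],
        label_b=series_b.labels[idx_b],
        offset=offset[keep],
        idx_a=idx_a,
        idx_b=idx_b,
        n_unmatched=int((~keep).sum()),
    )


def mutual_contact(paired: PairedFrames, mutuality: str = "interaction") -> MutualResult:
    """Mutual eye contact over paired frames.

    A pair counts as mutual when both labels are EYE. Pairs with either
    label MISSING are excluded from numerator and denominator. With
    ``mutuality="interaction"`` (default) the percentage is over all valid
    pairs; with ``"of_eye_gaze"`` it is over valid pairs where person A's
    label is EYE (the share of A's eye gaze that was reciprocated).
    """
    valid = (paired.label_a != _MISSING) & (paired.label_b != _MISSING)
    flags = (paired.label_a[valid] == _EYE) & (paired.label_b[valid] == _EYE)
    if mutuality == "interaction":
        denom = int(valid.sum())
    elif mutuality == "of_eye_gaze":
        denom = int((paired.label_a[valid] == _EYE).sum())
    else:
        raise ValueError(f"unknown mutuality mode {mutuality!r}")
    if denom == 0:
        return MutualResult(flags, math.nan, int(valid.sum()), False, valid)
    return MutualResult(flags, 100.0 * float(flags.sum()) / denom,
                        int(valid.sum()), True, valid)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def trial_percentages(
    series: ClassifiedSeries,
    paired: Optional[PairedFrames],
    trial: Trial,
    denominator: str = "valid",
    mutuality: str = "interaction",
) -> TrialMetrics:
    """Eye-gaze, mutual and missing percentages within one trial window.

    ``denominator="valid"`` divides gaze counts by non-missing frames
    (default); ``"total"`` divides by all frames, so the two differ exactly
    by the factor valid/(valid+missing).
    """
    if denominator not in ("valid", "total"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    mask = series.window(trial.start, trial.end)
    n_frames = int(mask.sum())
    if n_frames == 0:
        raise IntegrityError(
            f"trial {trial.index}: no frames in [{trial.start}, {trial.end})")
    labels = series.labels[mask]
    n_missing = int((labels == _MISSING).sum())
    n_valid = n_frames - n_missing
    n_eye = int((labels == _EYE).sum())
    n_mouth = int((labels == int(GazeLabel.MOUTH)).sum())
    denom = n_valid if denominator == "valid" else n_frames
    if denom > 0:
        eye_pct = 100.0 * n_eye / denom
        mouth_pct = 100.0 * n_mouth / denom
        eye_defined = True
    else:
        eye_pct = mouth_pct = math.nan
        eye_defined = False
    missing_pct = 100.0 * n_missing / n_frames

    mutual_pct = math.nan
    mutual_defined = False
    n_paired = 0
    if paired is not None and len(paired):
        in_trial = (paired.t_a >= trial.start) & (paired.t_a < trial.end)
        sub = PairedFrames(
            paired.t_a[in_trial], paired.t_b[in_trial],
            paired.label_a[in_trial], paired.label_b[in_trial],
            paired.offset[in_trial], paired.idx_a[in_trial],
            paired.idx_b[in_trial], 0)
        res = mutual_contact(sub, mutuality=mutuality)
        mutual_pct, mutual_defined = res.mutual_pct, res.defined
        n_paired = res.n_valid_pairs
    return TrialMetrics(
        trial_index=trial.index, condition=trial.condition,
        eye_gaze_pct=eye_pct, mutual_pct=mutual_pct, missing_pct=missing_pct,
        n_valid=n_valid, n_paired=n_paired, n_frames=n_frames,
        eye_defined=eye_defined, mutual_defined=mutual_defined,
        mouth_pct=mouth_pct)


def condition_metrics(trials: Sequence[TrialMetrics]) -> Dict[str, ConditionMetrics]:
    """Unweighted mean of each percentage over the trials of each condition.

    Call with excluded trials already dropped; a requested condition with
    no trials simply does not appear in the result (flagged by absence).
    """
    out: Dict[str, ConditionMetrics] = {}
    for cond in ("GUESS", "DESCRIBE"):
        group = [t for t in trials if t.condition == cond]
        if not group:
            continue
        def mean_of(attr):
            vals = [getattr(t, attr) for t in group]
            return float(np.mean(vals))
        out[cond] = ConditionMetrics(
            condition=cond,
            eye_gaze_pct=mean_of("eye_gaze_pct"),
            mutual_pct=mean_of("mutual_pct"),
            missing_pct=mean_of("missing_pct"),
            mouth_pct=mean_of("mouth_pct"),
            n_trials=len(group))
    return out


def compute_calibration_error(
    stream: GazeStream,
    segment: CalibrationSegment,
    partner_stream: GazeStream,
) -> Dict[str, float]:
    """Median angular error (degrees) against the scheduled fixation targets.

    For each scheduled fixation, the binocular mean gaze direction of every
    valid frame is compared with the direction from the eye midpoint to the
    partner's fixated landmark (nearest in time). Returns per-landmark and
    overall medians.
    """
    landmark_arrays = {
        "left_eye": partner_stream.left_eye,
        "right_eye": partner_stream.right_eye,
        "mouth": partner_stream.mouth,
        "nose": partner_stream.nose,
    }
    per_landmark_errors: Dict[str, list] = {}
    all_errors = []
    for fx in segment.fixation_schedule:
        mask = stream.window(fx.onset, fx.onset + fx.duration) & stream.valid
        if not mask.any():
            continue
        targets_src = landmark_arrays[fx.landmark]
        if targets_src is None:
            raise IntegrityError(
                f"partner stream has no {fx.landmark!r} landmarks for calibration")
        idx = _nearest_indices(stream.timestamps[mask], partner_stream.timestamps)
        targets = targets_src[idx]
        # valid frames carry at least one finite ray; average what is there
        l_dir, r_dir = stream.left_dir[mask], stream.right_dir[mask]
        l_ok = np.isfinite(l_dir).all(axis=1)
        r_ok = np.isfinite(r_dir).all(axis=1)
        dir_sum = (np.where(l_ok[:, None], l_dir, 0.0)
                   + np.where(r_ok[:, None], r_dir, 0.0))
        norms = np.linalg.norm(dir_sum, axis=1)
        origin = np.where(
            (l_ok & r_ok)[:, None],
            0.5 * (np.nan_to_num(stream.left_origin[mask])
                   + np.nan_to_num(stream.right_origin[mask])),
            np.where(l_ok[:, None], stream.left_origin[mask],
                     stream.right_origin[mask]))
        usable = np.isfinite(norms) & (norms > 0)
        d = dir_sum[usable] / norms[usable, None]
        to_target = targets[usable] - origin[usable]
        tn = np.linalg.norm(to_target, axis=1)
        cos = np.einsum("ij,ij->i", d, to_target / tn[:, None])
        err = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
        per_landmark_errors.setdefault(fx.landmark, []).append(err)
        all_errors.append(err)
    if not all_errors:
        raise IntegrityError("no valid frames in the calibration segment")
    result = {name: float(np.median(np.concatenate(chunks)))
              for name, chunks in per_landmark_errors.items()}
    result["overall"] = float(np.median(np.concatenate(all_errors)))
    return result


# ---------------------------------------------------------------------------
# session-level convenience
# ---------------------------------------------------------------------------

def analyze_session(
    session: Session,
    eye_aoi: Optional[AOISpec] = None,
    mouth_aoi: Optional[AOISpec] = None,
    max_offset: float = DEFAULT_MAX_OFFSET_S,
    denominator: str = "valid",
    mutuality: str = "interaction",
    require_both_eyes: bool = False,
    include_excluded: bool = False,
):
    """Run the full classification/pairing/aggregation chain on one session.

    Returns ``(trial_metrics, condition_metrics, classified)`` where
    ``classified`` maps role to the :class:`ClassifiedSeries` (participant
    gazing at experimenter and vice versa). Excluded trials are dropped
    before condition averaging unless ``include_excluded``.
    """
    p_series = classify_stream(session.participant_stream,
                               session.experimenter_stream,
                               eye_aoi, mouth_aoi, max_offset, require_both_eyes)
    e_series = classify_stream(session.experimenter_stream,
                               session.participant_stream,
                               eye_aoi, mouth_aoi, max_offset, require_both_eyes)
    paired = pair_nearest_in_time(p_series, e_series, max_offset)
    trials = []
    for trial in session.manifest.trials:
        tm = trial_percentages(p_series, paired, trial,
                               denominator=denominator, mutuality=mutuality)
        trials.append((trial, tm))
    kept = [tm for tr, tm in trials if include_excluded or not tr.excluded]
    conditions = condition_metrics(kept)
    all_trials = [tm for _, tm in trials]
    return all_trials, conditions, {"participant": p_series, "experimenter": e_series}


def trials_frame(participant_id: str, trials: Sequence[TrialMetrics]) -> pd.DataFrame:
    return pd.DataFrame([
        {"participant_id": participant_id, "trial_index": t.trial_index,
         "condition": t.condition, "eye_gaze_pct": t.eye_gaze_pct,
         "mutual_pct": t.mutual_pct, "missing_pct": t.missing_pct,
         "n_valid": t.n_valid, "n_paired": t.n_paired}
        for t in trials])


def conditions_frame(participant_id: str,
                     conditions: Dict[str, ConditionMetrics]) -> pd.DataFrame:
    return pd.DataFrame([
        {"participant_id": participant_id, "condition": c.condition,
         "eye_gaze_pct": c.eye_gaze_pct, "mutual_pct": c.mutual_pct,
         "missing_pct": c.missing_pct, "n_valid": np.nan, "n_paired": np.nan}
        for c in conditions.values()])
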