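"""Parameter-recovery studies on the study-calibrated preset.

The study's raw gaze recordings are not publicly deposited, so the
pipeline is validated by recovery: synthetic cohorts are generated with
the calibrated preset (condition-dependent eye-gaze marginals, controlled
mutual overlap, AQ and discomfort effects, 10.3% missingness, default
emission noise), pushed through the *full* measurement chain
(emission -> frame classification through the 6.3 cm rule -> nearest-in-
time pairing -> trial and condition aggregation -> HC3 robust
regression), and the cohort-level quantities the pipeline reports are
compared with the generative values. Everything here is recomputed from
scratch at call time.
"""
from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import metrics as gm
from . import stats as st
from . import synthetic as syn
from .session_io import cohort_to_frame

__all__ = ["cohort_recovery_study", "effect_recovery_study"]

_MOD = 2 ** 31 - 1


def derive_seed(master: int, stream: int) -> int:
    """A deterministic 31-bit sub-seed for one replicate / sub-study."""
    return (master * 1_000_003 + stream * 7_919 + 17) % _MOD


def _analyze_study(cohort_cfg, effects, stream_cfg, seed):
    """Generate and analyse a whole synthetic study; returns the cohort
    table, the per-condition metrics table, and missing-frame counts."""
    cohort, _targets, sessions = syn.generate_study(cohort_cfg, effects,
                                                    stream_cfg, master_seed=seed)
    cond_rows = []
    missing_frames = 0
    total_frames = 0
    for synth in sessions:
        trials, conditions, _series = gm.analyze_session(synth.session)
        for c in conditions.values():
            cond_rows.append({
                "participant_id": synth.participant.id,
                "condition": c.condition,
                "eye_gaze_pct": c.eye_gaze_pct,
                "mutual_pct": c.mutual_pct,
                "missing_pct": c.missing_pct})
        for t in trials:
            missing_frames += t.n_frames - t.n_valid
            total_frames += t.n_frames
    return (cohort_to_frame(cohort), pd.DataFrame(cond_rows),
            missing_frames, total_frames)


def cohort_recovery_study(n_participants: int = 200,
                          seed: int = 1) -> Dict[str, float]:
    """Cohort-level recovery run with the study-calibrated preset.

    Generates ``n_participants`` synthetic participants, runs
    classify -> pair -> aggregate on every session, and returns the
    cohort means of the per-participant condition metrics, the pooled
    missing-data fraction over all participant trial frames, and the
    cohort mean AQ.
    """
    preset = syn.study_preset()
    cohort_cfg = preset.cohort.model_copy(
        update={"n_participants": n_participants})
    cohort_df, cond, missing, total = _analyze_study(
        cohort_cfg, preset.effects, preset.stream, derive_seed(seed, 1))
    by_cond = cond.groupby("condition")[["eye_gaze_pct", "mutual_pct"]].mean()
    return {
        "eye_guess_mean": float(by_cond.loc["GUESS", "eye_gaze_pct"]),
        "eye_describe_mean": float(by_cond.loc["DESCRIBE", "eye_gaze_pct"]),
        "mutual_guess_mean": float(by_cond.loc["GUESS", "mutual_pct"]),
        "mutual_describe_mean": float(by_cond.loc["DESCRIBE", "mutual_pct"]),
        "missing_pct": 100.0 * missing / total,
        "aq_mean": float(cohort_df["aq"].mean()),
        "n": n_participants,
    }


def effect_recovery_study(n_replicates: int = 50, n_participants: int = 20,
                          seed: int = 1,
                          hc_type: str = "HC3") -> Dict[str, float]:
    """Individual-difference effect recovery over replicate cohorts.

    For each replicate: a fresh cohort of ``n_participants`` through the
    full pipeline, then HC3 robust fits of
    eye% ~ aq + age + sex (describing condition) and
    eye% / mutual% ~ discomfort + age + sex (guessing condition).
    Returns the mean absolute coefficients across replicates.
    """
    preset = syn.study_preset()
    cohort_cfg = preset.cohort.model_copy(
        update={"n_participants": n_participants})
    aq_betas, disc_eye_betas, disc_mut_betas = [], [], []
    for rep in range(n_replicates):
        cohort_df, cond, _m, _t = _analyze_study(
            cohort_cfg, preset.effects, preset.stream,
            derive_seed(seed, 100 + rep))
        wide = cond.pivot(index="participant_id", columns="condition",
                          values=["eye_gaze_pct", "mutual_pct"])
        meta = cohort_df.set_index("id").loc[wide.index]
        fit = st.ols_robust(wide[("eye_gaze_pct", "DESCRIBE")],
                            meta[["aq", "age", "sex"]].astype(float),
                            hc_type=hc_type)
        aq_betas.append(abs(fit["aq"].beta))
        fit = st.ols_robust(wide[("eye_gaze_pct", "GUESS")],
                            meta[["discomfort", "age", "sex"]].astype(float),
                            hc_type=hc_type)
        disc_eye_betas.append(abs(fit["discomfort"].beta))
        fit = st.ols_robust(wide[("mutual_pct", "GUESS")],
                            meta[["discomfort", "age", "sex"]].astype(float),
                            hc_type=hc_type)
        disc_mut_betas.append(abs(fit["discomfort"].beta))
    return {
        "aq_slope_eye_describe_abs": float(np.mean(aq_betas)),
        "discomfort_eye_guess_abs": float(np.mean(disc_eye_betas)),
        "discomfort_mutual_guess_abs": float(np.mean(disc_mut_betas)),
        "n_replicates": n_replicates,
        "n_per_cohort": n_participants,
    }
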