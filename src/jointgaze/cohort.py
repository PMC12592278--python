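"""Cohort-level synthetic sessions with known generative parameters.

The generator encodes the study's assumed data-generating process: each
participant carries a random intercept on the log-odds scale, each trial
index a crossed random intercept, and the per-trial probability of a
reactive-joint-attention (RJA) response follows

    logit p = fe(group, timepoint) + u_participant + v_trial
              + slope_bps * (BPS - BPS_ref)

so arousal (baseline pupil size, BPS) can act as a mediator of group
differences: groups may shift BPS, and BPS feeds back on RJA with a
(negative, by default) log-odds slope.  The stimulus-evoked response
(SEPR) is inversely coupled to BPS.  Default sizes and trial structure
follow the 16-trial / 11 s paradigm with autistic intervention (A-FFIP),
treatment-as-usual (EIAU) and non-autistic arms.

``simulate_feature_table`` draws the per-trial outcome table directly
(fast; for statistical recovery experiments).  ``simulate_cohort``
additionally renders every trial into raw gaze/pupil sample files in the
exact dialects the I/O layer reads, with a ground-truth registry for
round-trip tests.  Output is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SampleStream, write_gaze_file, write_trial_log
from .paradigm import AOISet, ParadigmSpec, default_aois, write_aoi_file
from .synth import plan_rja_trial, simulate_trial_gaze, simulate_trial_pupil


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic longitudinal cohort."""

    # participants per group; timepoints assessed per group
    group_sizes: dict = field(default_factory=lambda: {
        "A-FFIP": 32, "EIAU": 28, "non-autistic": 52})
    group_timepoints: dict = field(default_factory=lambda: {
        "A-FFIP": ("BL", "ET", "FU"), "EIAU": ("BL", "ET", "FU"),
        "non-autistic": ("BL", "FU")})
    # fixed effects: per-(group, timepoint) RJA log-odds at reference BPS
    fixed_effects: dict = field(default_factory=lambda: {
        ("A-FFIP", "BL"): -1.8, ("A-FFIP", "ET"): -1.4, ("A-FFIP", "FU"): -0.9,
        ("EIAU", "BL"): -2.2, ("EIAU", "ET"): -1.9, ("EIAU", "FU"): -1.9,
        ("non-autistic", "BL"): -0.5, ("non-autistic", "FU"): 0.1})
    sd_participant: float = 1.0  # random-intercept SD, log-odds
    sd_trial: float = 0.3
    # mediation structure
    bps_ref_mm: float = 4.3
    bps_group_shift: dict = field(default_factory=lambda: {
        ("EIAU", "FU"): 0.3})  # mm offsets from bps_ref per (group, timepoint)
    bps_sd_participant_mm: float = 0.4
    bps_sd_trial_mm: float = 0.1
    bps_to_rja_slope: float = -0.5  # log-odds per mm
    sepr_base_mm: float = 0.1
    sepr_bps_coupling: float = -0.25  # mm SEPR per mm BPS deviation
    sepr_noise_mm: float = 0.05
    # measurement-level nuisance parameters
    pupil_noise_sd_mm: float = 0.0
    gaze_noise_deg: float = 0.0
    blink_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_participant", "sd_trial", "bps_sd_participant_mm",
                     "bps_sd_trial_mm", "sepr_noise_mm", "pupil_noise_sd_mm",
                     "gaze_noise_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.blink_prob <= 1.0):
            raise ValueError("blink_prob must be a probability")


def simulate_feature_table(cohort: CohortSpec, paradigm: ParadigmSpec,
                           rng: np.random.Generator | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the per-trial outcome table straight from the generative model.

    Returns ``(features, truth)`` where ``truth`` records the drawn
    participant intercepts and parameters used (for recovery checks).
    """
    rng = rng or np.random.default_rng(cohort.seed)
    conditions = paradigm.condition_table(seed=cohort.seed)
    trial_re = rng.normal(0.0, cohort.sd_trial, paradigm.n_trials)

    rows = []
    truth_rows = []
    for group, n in cohort.group_sizes.items():
        for i in range(n):
            pid = f"{group}-{i:03d}"
            u = rng.normal(0.0, cohort.sd_participant)
            bps_p = rng.normal(0.0, cohort.bps_sd_participant_mm)
            truth_rows.append({"participant": pid, "group": group,
                               "intercept": u, "bps_dev_mm": bps_p})
            for tp in cohort.group_timepoints[group]:
                fe = cohort.fixed_effects[(group, tp)]
                shift = cohort.bps_group_shift.get((group, tp), 0.0)
                for trial in range(paradigm.n_trials):
                    cond = conditions.iloc[trial]
                    bps = (cohort.bps_ref_mm + shift + bps_p
                           + rng.normal(0.0, cohort.bps_sd_trial_mm))
                    sepr = (cohort.sepr_base_mm
                            + cohort.sepr_bps_coupling * (bps - cohort.bps_ref_mm)
                            + rng.normal(0.0, cohort.sepr_noise_mm))
                    logit = (fe + u + trial_re[trial]
                             + cohort.bps_to_rja_slope
                             * (bps - cohort.bps_ref_mm))
                    rja = bool(rng.random() < _logistic(logit))
                    rows.append({
                        "participant": pid, "group": group, "timepoint": tp,
                        "trial": trial + 1, "cueing": cond.cueing,
                        "stimulus": cond.stimulus,
                        "target_side": cond.target_side,
                        "rja": rja, "bps_mm": bps, "sepr_mm": sepr,
                    })
    features = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return features, truth


def simulate_cohort(cohort: CohortSpec, paradigm: ParadigmSpec,
                    out_dir: str | Path,
                    aois: AOISet | None = None) -> pd.DataFrame:
    """Write a full synthetic cohort to disk.

    Produces ``participants.csv``, ``aois.csv``, a per-session gaze TSV and
    trial-log CSV under ``sessions/``, and ``ground_truth.csv`` holding the
    drawn per-trial RJA flags, BPS and SEPR.  Identical spec + seed gives
    byte-identical files.  Returns the ground-truth registry.
    """
    out = Path(out_dir)
    (out / "sessions").mkdir(parents=True, exist_ok=True)
    aois = aois or default_aois()
    rng = np.random.default_rng(cohort.seed)
    features, _truth = simulate_feature_table(cohort, paradigm, rng)
    conditions = paradigm.condition_table(seed=cohort.seed)

    write_aoi_file(aois, out / "aois.csv")
    participants = (features[["participant", "group"]]
                    .drop_duplicates().reset_index(drop=True))
    participants.to_csv(out / "participants.csv", index=False)

    gap_s = 2.0  # inter-trial gap in the session stream
    registry = []
    for (pid, tp), block in features.groupby(["participant", "timepoint"],
                                             sort=True):
        frames = []
        log_rows = []
        for _, row in block.sort_values("trial").iterrows():
            onset = (row.trial - 1) * (paradigm.trial_duration + gap_s)
            plan = plan_rja_trial(paradigm, aois, row.target_side,
                                  rja=row.rja, rng=rng,
                                  noise_deg=cohort.gaze_noise_deg,
                                  blink_prob=cohort.blink_prob)
            stream, _events = simulate_trial_gaze(paradigm, plan,
                                                  rng_seed=rng)
            simulate_trial_pupil(paradigm, row.bps_mm, row.sepr_mm,
                                 noise_sd=cohort.pupil_noise_sd_mm,
                                 rng_seed=rng, stream=stream)
            frame = stream.data.copy()
            frame["t"] = frame["t"] + onset
            frames.append(frame)
            log_rows.append({"trial": row.trial, "onset_s": onset,
                             "cueing": row.cueing, "stimulus": row.stimulus,
                             "target_side": row.target_side})
            registry.append({"participant": pid, "timepoint": tp,
                             "trial": row.trial, "rja": row.rja,
                             "bps_mm": row.bps_mm, "sepr_mm": row.sepr_mm})
        session = pd.concat(frames, ignore_index=True)
        write_gaze_file(SampleStream(session, paradigm.sampling_rate),
                        out / "sessions" / f"{pid}_{tp}_gaze.tsv")
        write_trial_log(pd.DataFrame(log_rows),
                        out / "sessions" / f"{pid}_{tp}_trials.csv")
    truth = pd.DataFrame(registry)
    truth.to_csv(out / "ground_truth.csv", index=False,
                 float_format="%.9f")
    return truth
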