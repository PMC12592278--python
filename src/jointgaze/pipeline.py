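"""End-to-end preprocessing: session files to per-trial feature rows.

Per trial the chain is: segmentation, blink correction, plausibility
filter, Savitzky-Golay smoothing, velocity, adaptive saccade threshold
(estimated once per session so it reflects that recording's noise),
saccade and fixation detection, the trial-level data-quality rule, pupil
cleaning and features, and RJA scoring.  Dropped trials contribute no
feature row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import events as ev
from .events import CleaningConfig, SaccadeThresholds
from .io import SampleStream, TrialSegment, segment_trials
from .paradigm import AOISet, ParadigmSpec, ScreenGeometry
from .pupil import PupilConfig, pupil_features
from .scoring import RJAConfig, assemble_trial_features

log = logging.getLogger(__name__)


@dataclass
class SessionResult:
    features: pd.DataFrame  # one row per retained trial
    events: pd.DataFrame  # all detected events
    thresholds: SaccadeThresholds
    dropped_trials: list[tuple[int, str]] = field(default_factory=list)


def clean_segment(segment: TrialSegment, geometry: ScreenGeometry,
                  cfg: CleaningConfig) -> TrialSegment:
    """Blink correction, plausibility filter, smoothing and velocity."""
    seg = ev.correct_blinks(segment, cfg)
    seg = ev.drop_implausible(seg, geometry, cfg)
    seg = ev.smooth_gaze(seg, cfg)
    seg = ev.compute_velocity(seg, geometry)
    return seg


def process_session(stream: SampleStream, trial_log: pd.DataFrame,
                    aois: AOISet, paradigm: ParadigmSpec,
                    geometry: ScreenGeometry | None = None,
                    cleaning: CleaningConfig = CleaningConfig(),
                    pupil_cfg: PupilConfig = PupilConfig(),
                    rja_cfg: RJAConfig = RJAConfig(),
                    **ids) -> SessionResult:
    """Run the full preprocessing chain on one session."""
    geometry = geometry or paradigm.screen
    segments = segment_trials(stream, trial_log, paradigm)
    cleaned = []
    for seg in segments:
        if seg.dropped:
            continue
        cleaned.append(clean_segment(seg, geometry, cleaning))

    # session-wide adaptive threshold: intra-individual noise is shared
    # across that session's trials
    all_vel = np.concatenate(
        [s.data["vel_deg"].to_numpy() for s in cleaned]) if cleaned else \
        np.empty(0)
    thresholds = ev.adaptive_saccade_threshold(all_vel, cleaning,
                                               rate=paradigm.sampling_rate)

    rows = []
    event_frames = []
    dropped = [(s.trial_id, s.drop_reason) for s in segments if s.dropped]
    for seg in cleaned:
        missing_fraction, drop = ev.trial_quality(seg, cleaning)
        if drop:
            dropped.append((seg.trial_id, "insufficient data"))
            log.info("trial %d dropped: %.0f%% missing",
                     seg.trial_id, 100 * missing_fraction)
            continue
        saccades = ev.detect_saccades(seg, thresholds, geometry, cleaning)
        fixations = ev.detect_fixations(seg, saccades, geometry, cleaning)
        bps, sepr, pupil_missing = pupil_features(seg, pupil_cfg)
        row = assemble_trial_features(seg, fixations, aois, missing_fraction,
                                      bps, sepr, pupil_missing, rja_cfg)
        rows.append({**ids, **row})
        event_frames.append(ev.events_to_frame(
            saccades + fixations, **ids, trial=seg.trial_id))

    features = pd.DataFrame(rows)
    events_table = (pd.concat(event_frames, ignore_index=True)
                    if event_frames else pd.DataFrame())
    return SessionResult(features=features, events=events_table,
                         thresholds=thresholds, dropped_trials=dropped)
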