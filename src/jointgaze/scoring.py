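"""Per-trial reactive joint attention (RJA) scoring from fixation sequences.

A trial counts as RJA when a fixation on the model's head ends within the
500 ms preceding the onset of a fixation on the cued target object, and
that target fixation starts in the target-cueing phase (3 s trial-local)
or later.  Fixations on the distractor-side object neither qualify nor
disqualify.  AOI membership is decided by the fixation centroid with
half-open region boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import GazeEvent
from .paradigm import AOI, AOISet


@dataclass(frozen=True)
class RJAConfig:
    max_gap_s: float = 0.5  # head-offset to target-onset window
    latency_mode: str = "offset_to_onset"  # or "onset_to_onset"
    duration_mode: str = "first"  # or "sum" over qualifying target fixations

    def __post_init__(self) -> None:
        if self.latency_mode not in ("offset_to_onset", "onset_to_onset"):
            raise ValueError("unknown latency_mode")
        if self.duration_mode not in ("first", "sum"):
            raise ValueError("unknown duration_mode")


@dataclass(frozen=True)
class RJAScore:
    rja: bool
    latency_s: float = float("nan")  # from cueing onset to target fixation
    duration_s: float = float("nan")  # dwell on the qualifying target


def aoi_hit(fixation: GazeEvent, aoi: AOI) -> bool:
    """Whether a fixation's centroid falls inside a screen region."""
    return aoi.contains(fixation.centroid_x, fixation.centroid_y)


def _gap(head: GazeEvent, target: GazeEvent, cfg: RJAConfig) -> float:
    if cfg.latency_mode == "offset_to_onset":
        return target.onset - head.offset
    return target.onset - head.onset


def score_rja(fixations: list[GazeEvent], aois: AOISet, target_side: str,
              cueing_onset: float = 3.0,
              cfg: RJAConfig = RJAConfig()) -> RJAScore:
    """Score one trial's fixation sequence against the RJA rule.

    Deterministic and invariant to input order (fixations are sorted
    internally).  Raises on an unknown target side.
    """
    target_aoi = aois.target(target_side)  # raises for unknown side
    fixations = sorted(fixations, key=lambda f: f.onset)
    heads = [f for f in fixations if aoi_hit(f, aois.head)]
    targets = [f for f in fixations
               if aoi_hit(f, target_aoi) and f.onset >= cueing_onset]

    qualifying = []
    for ft in targets:
        for fh in heads:
            gap = _gap(fh, ft, cfg)
            if fh.offset <= ft.onset and 0.0 <= gap <= cfg.max_gap_s:
                qualifying.append(ft)
                break
    if not qualifying:
        return RJAScore(rja=False)
    first = qualifying[0]
    if cfg.duration_mode == "first":
        duration = first.duration
    else:
        duration = float(sum(f.duration for f in qualifying))
    return RJAScore(rja=True, latency_s=first.onset - cueing_onset,
                    duration_s=duration)


def total_fixation_duration(fixations: list[GazeEvent],
                            window: tuple[float, float] = (0.0, 11.0)) -> float:
    """Sum of fixation durations clipped to the trial window."""
    lo, hi = window
    total = 0.0
    for f in fixations:
        total += max(0.0, min(f.offset, hi) - max(f.onset, lo))
    return total


def assemble_trial_features(segment, fixations: list[GazeEvent],
                            aois: AOISet, missing_fraction: float,
                            bps: float | None, sepr: float | None,
                            pupil_missing_fraction: float,
                            cfg: RJAConfig = RJAConfig()) -> dict:
    """Combine gaze and pupil outcomes into one per-trial feature row.

    Absent pupil features stay absent (NaN) -- no imputation.  Dropped
    trials never reach this function.
    """
    score = score_rja(fixations, aois, segment.target_side,
                      cueing_onset=segment.paradigm.cueing_onset, cfg=cfg)
    return {
        "trial": segment.trial_id,
        "cueing": segment.cueing,
        "stimulus": segment.stimulus,
        "target_side": segment.target_side,
        "rja": score.rja,
        "rja_latency_s": score.latency_s,
        "rja_duration_s": score.duration_s if score.rja else 0.0,
        "total_fixation_duration_s": total_fixation_duration(
            fixations, (0.0, segment.paradigm.trial_duration)),
        "bps_mm": np.nan if bps is None else bps,
        "sepr_mm": np.nan if sepr is None else sepr,
        "missing_fraction": missing_fraction,
        "pupil_missing_fraction": pupil_missing_fraction,
    }
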