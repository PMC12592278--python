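"""Synthetic single-trial gaze and pupil generation with known ground truth.

Gaze trials are built from an explicit behaviour plan: a sequence of
fixation targets with dwell times.  Saccades between fixations follow a
main-sequence kinematic model -- peak velocity Vp = 500 (1 - exp(-A / 15))
deg/s for amplitude A -- with a symmetric raised-cosine velocity profile,
so detection algorithms see realistic bell-shaped velocity peaks.  Blinks
are inserted as tracking-loss gaps (invalid samples in both gaze and pupil
channels, as a remote tracker reports them).  Independent Gaussian
positional noise is added per eye.

Pupil trials are piecewise-linear diameter profiles reproducing the
paradigm's canonical shape: a flat baseline, a luminance-adaptation bump
after the attention grabber, and a cueing-locked dilation that plateaus
across the evoked-response window -- constructed so that the baseline
window mean equals ``bps_true`` exactly and the normalized mean over the
evoked window equals ``sepr_true`` exactly at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import GazeEvent
from .io import STATUS_MISSING, STATUS_VALID, SampleStream, combine_gaze, deg_to_px, px_to_deg
from .paradigm import AOISet, ParadigmSpec, ScreenGeometry


@dataclass(frozen=True)
class FixationPlan:
    x: float  # px
    y: float
    dwell: float  # seconds


@dataclass(frozen=True)
class BlinkPlan:
    onset: float  # trial-local seconds
    duration: float


@dataclass
class TrialPlan:
    fixations: list[FixationPlan]
    blinks: list[BlinkPlan] = field(default_factory=list)
    noise_deg: float = 0.0  # per-eye positional noise SD


#: peak-acceleration ceiling for generated saccades (deg/s^2).  The
#: raised-cosine profile has peak acceleration pi*Vp^2 / (2A); capping it
#: keeps synthetic saccades inside the physiological plausibility envelope
#: that the cleaning chain enforces (10000 deg/s^2), with margin.
MAX_SACCADE_ACCEL = 9000.0


def main_sequence_peak_velocity(amplitude_deg: float) -> float:
    """Peak velocity (deg/s) of a generated saccade of given amplitude.

    Main-sequence law Vp = 500 (1 - exp(-A / 15)), additionally limited so
    the profile's peak acceleration stays below ``MAX_SACCADE_ACCEL``.
    """
    if amplitude_deg <= 0:
        return 0.0
    vp = 500.0 * (1.0 - np.exp(-amplitude_deg / 15.0))
    cap = np.sqrt(2.0 * amplitude_deg * MAX_SACCADE_ACCEL / np.pi)
    return float(min(vp, cap))


def saccade_duration(amplitude_deg: float) -> float:
    """Duration implied by the raised-cosine profile (mean velocity Vp/2)."""
    vp = main_sequence_peak_velocity(amplitude_deg)
    return 2.0 * amplitude_deg / vp if vp > 0 else 0.0


def _raised_cosine_displacement(frac_t: np.ndarray) -> np.ndarray:
    """Normalized displacement 0..1 along a raised-cosine velocity profile
    evaluated at normalized time 0..1."""
    return frac_t - np.sin(2.0 * np.pi * frac_t) / (2.0 * np.pi)


def simulate_trial_gaze(paradigm: ParadigmSpec, plan: TrialPlan,
                        geometry: ScreenGeometry | None = None,
                        rng_seed: int | np.random.Generator = 0
                        ) -> tuple[SampleStream, list[GazeEvent]]:
    """Render a behaviour plan into a 300 Hz sample stream.

    Returns the stream and the exact ground-truth event list (fixations,
    saccades, blinks).  The last planned fixation is extended to the end
    of the trial; a plan whose dwells plus saccade flight times exceed the
    trial duration is rejected.
    """
    geometry = geometry or paradigm.screen
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    n = paradigm.samples_per_trial
    t = np.arange(n) / paradigm.sampling_rate
    x = np.empty(n)
    y = np.empty(n)
    events: list[GazeEvent] = []

    if not plan.fixations:
        raise ValueError("behaviour plan needs at least one fixation")

    cursor = 0.0
    for i, fix in enumerate(plan.fixations):
        is_last = i == len(plan.fixations) - 1
        if cursor + fix.dwell > paradigm.trial_duration + 1e-9:
            raise ValueError(
                f"behaviour plan exceeds the {paradigm.trial_duration} s "
                f"trial at fixation {i} (t = {cursor + fix.dwell:.3f} s)")
        # the last fixation holds through the remainder of the trial
        fix_end = paradigm.trial_duration if is_last else cursor + fix.dwell
        mask = (t >= cursor) & (t < fix_end)
        x[mask] = fix.x
        y[mask] = fix.y
        if fix_end > cursor:
            events.append(GazeEvent("fixation", cursor, fix_end,
                                    centroid_x=fix.x, centroid_y=fix.y))
        if is_last:
            cursor = fix_end
            break
        nxt = plan.fixations[i + 1]
        amp = float(px_to_deg(nxt.x - fix.x, nxt.y - fix.y, geometry))
        dur = saccade_duration(amp)
        s0, s1 = fix_end, fix_end + dur
        if s1 > paradigm.trial_duration + 1e-9:
            raise ValueError(
                f"behaviour plan exceeds the {paradigm.trial_duration} s "
                f"trial during the saccade after fixation {i}")
        mask = (t >= s0) & (t < s1)
        frac = _raised_cosine_displacement((t[mask] - s0) / dur) if dur else 0
        x[mask] = fix.x + (nxt.x - fix.x) * frac
        y[mask] = fix.y + (nxt.y - fix.y) * frac
        if dur > 0:
            events.append(GazeEvent(
                "saccade", s0, s1, amplitude_deg=amp,
                peak_velocity=main_sequence_peak_velocity(amp)))
        cursor = s1

    valid = np.ones(n, dtype=bool)
    for blink in plan.blinks:
        mask = (t >= blink.onset) & (t < blink.onset + blink.duration)
        if mask.any():
            valid[mask] = False
            events.append(GazeEvent("blink", blink.onset,
                                    blink.onset + blink.duration))

    noise_px = float(deg_to_px(plan.noise_deg, geometry)) if plan.noise_deg else 0.0
    data = pd.DataFrame({"t": t})
    for eye in ("left", "right"):
        ex = x + rng.normal(0.0, noise_px, n) if noise_px else x.copy()
        ey = y + rng.normal(0.0, noise_px, n) if noise_px else y.copy()
        ex[~valid] = np.nan
        ey[~valid] = np.nan
        data[f"x_{eye}"] = ex
        data[f"y_{eye}"] = ey
        data[f"pupil_{eye}"] = np.nan  # filled by simulate_trial_pupil
        data[f"valid_{eye}"] = valid
    data = combine_gaze(data)
    data["status"] = np.where(valid, STATUS_VALID, STATUS_MISSING)

    events.sort(key=lambda e: (e.onset, e.kind))
    return SampleStream(data, paradigm.sampling_rate), events


def pupil_profile(paradigm: ParadigmSpec, bps_true: float, sepr_true: float,
                  bump_mm: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free pupil diameter profile (t, mm) for one trial.

    Piecewise linear: flat at ``bps_true`` through the baseline window,
    luminance-adaptation bump (rise/fall) during the video intro, then a
    cueing-locked ramp that plateaus at ``bps_true + sepr_true`` across
    4.4-5.6 s so the mean over the evoked window [4.5, 5.5) is exact, and
    a slow return to baseline.
    """
    t = np.arange(paradigm.samples_per_trial) / paradigm.sampling_rate
    knots_t = [0.0, 0.6, 1.1, 1.9, paradigm.cueing_onset, 4.4, 5.6, 8.0,
               paradigm.trial_duration]
    knots_v = [bps_true, bps_true, bps_true + bump_mm, bps_true - 0.2 * bump_mm,
               bps_true, bps_true + sepr_true, bps_true + sepr_true,
               bps_true, bps_true]
    return t, np.interp(t, knots_t, knots_v)


def simulate_trial_pupil(paradigm: ParadigmSpec, bps_true: float,
                         sepr_true: float, noise_sd: float = 0.0,
                         rng_seed: int | np.random.Generator = 0,
                         stream: SampleStream | None = None) -> SampleStream:
    """Generate binocular pupil channels for one trial.

    ``bps_true`` must lie strictly inside the plausible 2-8 mm band
    (values outside would be deleted by the range filter).  Both eyes
    carry the same underlying profile plus independent Gaussian noise.
    When ``stream`` is given, its pupil columns are filled in place
    (respecting blink gaps); otherwise a pupil-only stream is returned.
    """
    if not (2.0 < bps_true < 8.0):
        raise ValueError("bps_true must lie strictly within (2, 8) mm")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    t, profile = pupil_profile(paradigm, bps_true, sepr_true)

    if stream is None:
        data = pd.DataFrame({"t": t})
        for eye in ("left", "right"):
            data[f"x_{eye}"] = np.nan
            data[f"y_{eye}"] = np.nan
            data[f"valid_{eye}"] = True
        data["x"] = np.nan
        data["y"] = np.nan
        data["status"] = STATUS_VALID
        stream = SampleStream(data, paradigm.sampling_rate)
    for eye in ("left", "right"):
        noise = rng.normal(0.0, noise_sd, len(t)) if noise_sd else 0.0
        p = profile + noise
        p[~stream.data[f"valid_{eye}"].to_numpy(dtype=bool)] = np.nan
        stream.data[f"pupil_{eye}"] = p
    return stream


def plan_rja_trial(paradigm: ParadigmSpec, aois: AOISet, target_side: str,
                   rja: bool, rng: np.random.Generator,
                   noise_deg: float = 0.0,
                   blink_prob: float = 0.0) -> TrialPlan:
    """Draw a realistic behaviour plan that realizes a wanted RJA outcome.

    RJA-true trials fixate the attention grabber / head location, hold it
    into the cueing phase, then saccade to the cued target (head-offset to
    target-onset gap well inside the 500 ms rule).  RJA-false trials shift
    to the distractor-side object instead, which never satisfies the rule.
    """
    head = aois.head.center
    target = aois.target(target_side).center
    other_side = "left" if target_side == "right" else "right"
    distractor = aois.target(other_side).center

    head_hold = float(rng.uniform(0.6, 1.8))  # dwell after cueing onset
    fixations = [
        FixationPlan(head[0], head[1],
                     paradigm.cueing_onset + head_hold),
    ]
    dest = target if rja else distractor
    dwell = float(rng.uniform(1.5, 3.0))
    fixations.append(FixationPlan(dest[0], dest[1], dwell))
    # return to the head for the outro
    fixations.append(FixationPlan(head[0], head[1], 1.0))

    blinks = []
    if blink_prob > 0 and rng.random() < blink_prob:
        onset = float(rng.uniform(1.2, 2.2))
        blinks.append(BlinkPlan(onset, float(rng.uniform(0.08, 0.24))))
    return TrialPlan(fixations=fixations, blinks=blinks, noise_deg=noise_deg)
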