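"""Gaze cleaning and saccade / fixation / blink classification.

The cleaning chain runs per trial in a fixed order: blink correction,
plausibility filtering on raw coordinates, Savitzky-Golay smoothing within
contiguous valid runs, velocity/acceleration computation, adaptive
saccade-threshold estimation, saccade detection, fixation detection, and
the trial-level data-quality rule.  Cleaning is monotone: no step ever
turns a non-valid sample back into a valid one.

Blinks are tracking-loss gaps of 75-250 ms; valid samples within 25 ms of
such a gap are excluded as eyelid-motion artefacts.  Samples implying
velocities above 1000 deg/s or accelerations above 10000 deg/s^2 are
physiologically implausible and dropped.  Saccades are detected with an
iterative data-driven velocity threshold (mean + 6 SD of sub-threshold
samples, seeded at 100 deg/s) so the criterion adapts to each recording's
noise level; event onset/offset extend to a mean + 3 SD boundary.
Fixations are stable valid runs of at least 100 ms outside saccades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .io import (
    STATUS_BLINK,
    STATUS_EXCLUDED,
    STATUS_IMPLAUSIBLE,
    STATUS_MISSING,
    STATUS_VALID,
    TrialSegment,
    px_to_deg,
)
from .paradigm import ScreenGeometry

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GazeEvent:
    """A labelled saccade, fixation or blink interval (trial-local s)."""

    kind: str  # "saccade" | "fixation" | "blink"
    onset: float
    offset: float
    centroid_x: float = float("nan")  # fixations, px
    centroid_y: float = float("nan")
    amplitude_deg: float = float("nan")  # saccades
    peak_velocity: float = float("nan")  # deg/s

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("event offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class CleaningConfig:
    blink_min_ms: float = 75.0
    blink_max_ms: float = 250.0
    blink_pad_ms: float = 25.0
    max_velocity: float = 1000.0  # deg/s
    max_acceleration: float = 10000.0  # deg/s^2
    sg_window_ms: float = 70.0
    sg_polyorder: int = 3
    fixation_max_velocity: float = 1.0  # deg/s ("velocity" criterion)
    fixation_dispersion_deg: float = 1.0  # ("dispersion" criterion)
    fixation_criterion: str = "velocity"  # or "dispersion"
    fixation_min_duration_ms: float = 100.0
    trial_min_valid_fraction: float = 0.5
    # adaptive saccade threshold (iterative mean + k*SD scheme)
    pt_initial: float = 100.0  # deg/s
    pt_peak_sd_mult: float = 6.0
    pt_onset_sd_mult: float = 3.0
    pt_tol: float = 1.0  # deg/s convergence
    pt_max_iter: int = 50
    pt_floor: float = 10.0  # deg/s, degenerate-data fallback
    pt_min_samples_s: float = 1.0  # seconds of defined velocity required
    min_saccade_duration_ms: float = 10.0
    min_saccade_amplitude_deg: float = 1.0  # reject sub-microsaccade noise
    saccade_merge_gap_ms: float = 30.0  # bridge dropout-split candidates

    def __post_init__(self) -> None:
        if self.blink_min_ms >= self.blink_max_ms:
            raise ValueError("blink_min_ms must be below blink_max_ms")
        for name in ("blink_min_ms", "blink_pad_ms", "max_velocity",
                     "max_acceleration", "sg_window_ms",
                     "fixation_min_duration_ms", "pt_initial", "pt_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fixation_criterion not in ("velocity", "dispersion"):
            raise ValueError("fixation_criterion must be velocity|dispersion")

    def sg_window_samples(self, rate: float) -> int:
        w = int(round(self.sg_window_ms * 1e-3 * rate))
        return w + 1 if w % 2 == 0 else w


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) index runs where mask is True."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def correct_blinks(segment: TrialSegment, cfg: CleaningConfig) -> TrialSegment:
    """Relabel tracking-loss gaps of blink-typical duration.

    Contiguous ``missing`` runs lasting 75-250 ms (inclusive band) become
    ``blink``; valid samples within 25 ms before/after are ``excluded``.
    Gaps outside the band are left untouched.
    """
    seg = segment.copy()
    status = seg.data["status"].to_numpy(dtype=object)
    n_pad = int(round(cfg.blink_pad_ms * 1e-3 * seg.rate))
    dt_ms = 1e3 / seg.rate
    for i0, i1 in _runs(status == STATUS_MISSING):
        dur_ms = (i1 - i0) * dt_ms
        if cfg.blink_min_ms <= dur_ms <= cfg.blink_max_ms:
            status[i0:i1] = STATUS_BLINK
            lo = max(0, i0 - n_pad)
            hi = min(len(status), i1 + n_pad)
            for j in list(range(lo, i0)) + list(range(i1, hi)):
                if status[j] == STATUS_VALID:
                    status[j] = STATUS_EXCLUDED
    seg.data["status"] = status
    return seg


def drop_implausible(segment: TrialSegment, geometry: ScreenGeometry,
                     cfg: CleaningConfig) -> TrialSegment:
    """Drop samples implying impossible eye kinematics.

    Velocity rule: a forward scan compares each valid sample against the
    last accepted one on *raw* (pre-smoothing) combined coordinates; a
    sample whose implied velocity exceeds 1000 deg/s is labelled
    ``implausible`` and does not advance the anchor, so an isolated spike
    is dropped without contaminating its neighbours.

    Acceleration rule: sample-to-sample acceleration at 300 Hz is
    noise-dominated (tracker jitter alone produces tens of thousands of
    deg/s^2), so the 10000 deg/s^2 criterion is evaluated on a local-
    polynomial (Savitzky-Golay, same 70 ms length) estimate of the
    velocity series of the surviving samples; genuine artefact spikes are
    already caught by the raw velocity rule.
    """
    seg = segment.copy()
    status = seg.data["status"].to_numpy(dtype=object)
    t = seg.data["t"].to_numpy()
    x = seg.data["x"].to_numpy()
    y = seg.data["y"].to_numpy()

    last = -1  # index of last accepted sample
    for i in np.flatnonzero(status == STATUS_VALID):
        if last < 0:
            last = i
            continue
        dt = t[i] - t[last]
        v = px_to_deg(x[i] - x[last], y[i] - y[last], geometry) / dt
        if v > cfg.max_velocity:
            status[i] = STATUS_IMPLAUSIBLE
            continue
        last = i

    # acceleration on smoothed velocity, within surviving valid runs
    w = cfg.sg_window_samples(segment.rate)
    for i0, i1 in _runs(status == STATUS_VALID):
        if i1 - i0 < max(w, 5):
            continue
        dt = np.diff(t[i0:i1])
        v = px_to_deg(np.diff(x[i0:i1]), np.diff(y[i0:i1]), geometry) / dt
        w_run = w if len(v) >= w else len(v) - (1 - len(v) % 2)
        v_sm = savgol_filter(v, w_run, cfg.sg_polyorder)
        acc = np.abs(np.diff(v_sm)) / dt[1:]
        for j in np.flatnonzero(acc > cfg.max_acceleration):
            status[i0 + j + 1] = STATUS_IMPLAUSIBLE
    seg.data["status"] = status
    return seg


def smooth_gaze(segment: TrialSegment, cfg: CleaningConfig) -> TrialSegment:
    """Savitzky-Golay smoothing (70 ms window) within valid runs only.

    The filter is never applied across blink or missing gaps; runs shorter
    than the window are copied through unsmoothed and logged.  Smoothed
    coordinates go to ``x_sm``/``y_sm``; raw columns stay untouched.
    """
    seg = segment.copy()
    w = cfg.sg_window_samples(seg.rate)
    status = seg.data["status"].to_numpy(dtype=object)
    xs = seg.data["x"].to_numpy(dtype=float).copy()
    ys = seg.data["y"].to_numpy(dtype=float).copy()
    for i0, i1 in _runs(status == STATUS_VALID):
        if i1 - i0 < w:
            log.debug("run of %d samples shorter than SG window (%d); "
                      "left unsmoothed", i1 - i0, w)
            continue
        xs[i0:i1] = savgol_filter(xs[i0:i1], w, cfg.sg_polyorder)
        ys[i0:i1] = savgol_filter(ys[i0:i1], w, cfg.sg_polyorder)
    seg.data["x_sm"] = xs
    seg.data["y_sm"] = ys
    return seg


def compute_velocity(segment: TrialSegment,
                     geometry: ScreenGeometry) -> TrialSegment:
    """Central-difference angular velocity and acceleration on smoothed
    coordinates; undefined (NaN) at valid-run edges and in gaps."""
    seg = segment.copy()
    t = seg.data["t"].to_numpy()
    xs = seg.data["x_sm"].to_numpy()
    ys = seg.data["y_sm"].to_numpy()
    status = seg.data["status"].to_numpy(dtype=object)
    vel = np.full(len(t), np.nan)
    for i0, i1 in _runs(status == STATUS_VALID):
        if i1 - i0 < 3:
            continue
        sl = slice(i0 + 1, i1 - 1)
        dt2 = t[i0 + 2:i1] - t[i0:i1 - 2]
        disp = px_to_deg(xs[i0 + 2:i1] - xs[i0:i1 - 2],
                         ys[i0 + 2:i1] - ys[i0:i1 - 2], geometry)
        vel[sl] = disp / dt2
    acc = np.full(len(t), np.nan)
    ok = np.isfinite(vel)
    for i0, i1 in _runs(ok):
        if i1 - i0 < 3:
            continue
        sl = slice(i0 + 1, i1 - 1)
        acc[sl] = (vel[i0 + 2:i1] - vel[i0:i1 - 2]) / (t[i0 + 2:i1] - t[i0:i1 - 2])
    seg.data["vel_deg"] = vel
    seg.data["acc_deg"] = acc
    return seg


@dataclass(frozen=True)
class SaccadeThresholds:
    peak: float  # deg/s, detection threshold
    onset: float  # deg/s, onset/offset extension threshold
    iterations: int = 0
    fallback: bool = False


def adaptive_saccade_threshold(velocity: np.ndarray,
                               cfg: CleaningConfig,
                               rate: float = 300.0) -> SaccadeThresholds:
    """Data-driven saccade detection threshold.

    Iterates ``PT_n = mean + 6 SD`` of samples below ``PT_{n-1}`` starting
    from 100 deg/s until the change is below 1 deg/s (or 50 iterations).
    The onset/offset threshold is mean + 3 SD of the final sub-threshold
    samples.  With too little defined velocity the configured initial
    threshold is used as a fixed fallback; a degenerate (near-zero)
    solution is floored at ``pt_floor``.
    """
    v = np.asarray(velocity, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < cfg.pt_min_samples_s * rate:
        log.info("too few velocity samples (%d); fixed threshold fallback",
                 v.size)
        return SaccadeThresholds(cfg.pt_initial, cfg.pt_initial / 2.0,
                                 fallback=True)
    pt = cfg.pt_initial
    mean = sd = 0.0
    it = 0
    for it in range(1, cfg.pt_max_iter + 1):
        sub = v[v < pt]
        if sub.size == 0:
            break
        mean, sd = float(np.mean(sub)), float(np.std(sub))
        new = mean + cfg.pt_peak_sd_mult * sd
        done = abs(new - pt) < cfg.pt_tol
        pt = new
        if done:
            break
    onset = mean + cfg.pt_onset_sd_mult * sd
    if pt < cfg.pt_floor:
        log.info("degenerate adaptive threshold %.3f; floored at %.1f",
                 pt, cfg.pt_floor)
        return SaccadeThresholds(cfg.pt_floor, cfg.pt_floor, iterations=it)
    return SaccadeThresholds(pt, onset, iterations=it)


def detect_saccades(segment: TrialSegment, thresholds: SaccadeThresholds,
                    geometry: ScreenGeometry,
                    cfg: CleaningConfig) -> list[GazeEvent]:
    """Velocity-threshold saccade detection.

    A saccade is a maximal run with velocity at or above the peak
    threshold, extended both ways to the onset/offset threshold crossing;
    runs shorter than 10 ms or with an amplitude below the microsaccade-
    scale minimum are discarded (correlated noise can push the smoothed
    velocity over an adaptive threshold for a few samples without any
    real gaze shift).  Amplitude is the angular distance between the
    smoothed endpoint positions.
    """
    data = segment.data
    t = data["t"].to_numpy()
    vel = data["vel_deg"].to_numpy()
    xs = data["x_sm"].to_numpy()
    ys = data["y_sm"].to_numpy()
    above = np.isfinite(vel) & (vel >= thresholds.peak)
    ext = np.isfinite(vel) & (vel >= thresholds.onset)

    merge_gap = int(round(cfg.saccade_merge_gap_ms * 1e-3 * segment.rate))
    intervals: list[list[int]] = []
    for i0, i1 in _runs(above):
        lo, hi = i0, i1
        while lo > 0 and ext[lo - 1]:
            lo -= 1
        while hi < len(vel) and ext[hi]:
            hi += 1
        # candidates split by a sub-fixation-length gap (e.g. a dropped
        # sample mid-flight) belong to one movement
        if intervals and lo - intervals[-1][1] <= merge_gap:
            intervals[-1][1] = max(intervals[-1][1], hi)
        else:
            intervals.append([lo, hi])

    min_n = max(2, int(round(cfg.min_saccade_duration_ms * 1e-3 * segment.rate)))
    events = []
    for lo, hi in intervals:
        if hi - lo < min_n:
            continue
        amp = float(px_to_deg(xs[hi - 1] - xs[lo], ys[hi - 1] - ys[lo], geometry))
        if amp < cfg.min_saccade_amplitude_deg:
            continue
        events.append(GazeEvent(
            kind="saccade", onset=float(t[lo]), offset=float(t[hi - 1]),
            amplitude_deg=amp, peak_velocity=float(np.nanmax(vel[lo:hi])),
        ))
    return events


def _stable_mask(segment: TrialSegment, geometry: ScreenGeometry,
                 cfg: CleaningConfig) -> np.ndarray:
    """Per-sample gaze-stability indicator for fixation classification.

    ``velocity`` mode: smoothed angular velocity below the configured
    limit (undefined velocities at run edges do not disqualify).
    ``dispersion`` mode: angular position range within a centred 100 ms
    window below the dispersion limit.
    """
    data = segment.data
    if cfg.fixation_criterion == "velocity":
        vel = data["vel_deg"].to_numpy()
        return ~(np.isfinite(vel) & (vel >= cfg.fixation_max_velocity))
    # dispersion mode: centred rolling position range
    import pandas as pd

    half = max(1, int(round(0.5 * cfg.fixation_min_duration_ms * 1e-3
                            * segment.rate)))
    w = 2 * half + 1
    xs = pd.Series(data["x_sm"].to_numpy())
    ys = pd.Series(data["y_sm"].to_numpy())
    rx = (xs.rolling(w, center=True, min_periods=1).max()
          - xs.rolling(w, center=True, min_periods=1).min()).to_numpy()
    ry = (ys.rolling(w, center=True, min_periods=1).max()
          - ys.rolling(w, center=True, min_periods=1).min()).to_numpy()
    span = px_to_deg(rx, ry, geometry)
    return np.isfinite(span) & (span < cfg.fixation_dispersion_deg)


def detect_fixations(segment: TrialSegment, saccades: list[GazeEvent],
                     geometry: ScreenGeometry,
                     cfg: CleaningConfig) -> list[GazeEvent]:
    """Fixations: stable valid runs of >= 100 ms outside all saccades.

    Centroid is the mean smoothed position over the run.
    """
    data = segment.data
    t = data["t"].to_numpy()
    status = data["status"].to_numpy(dtype=object)
    candidate = status == STATUS_VALID
    for s in saccades:
        candidate &= ~((t >= s.onset) & (t <= s.offset))
    candidate &= _stable_mask(segment, geometry, cfg)

    min_n = int(np.ceil(cfg.fixation_min_duration_ms * 1e-3 * segment.rate))
    xs = data["x_sm"].to_numpy()
    ys = data["y_sm"].to_numpy()
    events = []
    for i0, i1 in _runs(candidate):
        if i1 - i0 < min_n:
            continue
        events.append(GazeEvent(
            kind="fixation", onset=float(t[i0]), offset=float(t[i1 - 1]),
            centroid_x=float(np.mean(xs[i0:i1])),
            centroid_y=float(np.mean(ys[i0:i1])),
        ))
    return events


def trial_quality(segment: TrialSegment,
                  cfg: CleaningConfig) -> tuple[float, bool]:
    """Missing-data fraction and the <50%-data drop rule.

    A trial is dropped when *less than* half of its samples remain valid;
    exactly half retained is kept.
    """
    status = segment.data["status"].to_numpy(dtype=object)
    missing_fraction = float(np.mean(status != STATUS_VALID))
    dropped = (1.0 - missing_fraction) < cfg.trial_min_valid_fraction
    return missing_fraction, dropped


def events_to_frame(events: list[GazeEvent], **ids):
    """Tabulate events for the event CSV; ``ids`` adds constant columns."""
    import pandas as pd

    rows = [
        {**ids, "kind": e.kind, "onset": e.onset, "offset": e.offset,
         "centroid_x_px": e.centroid_x, "centroid_y_px": e.centroid_y,
         "amplitude_deg": e.amplitude_deg, "peak_vel": e.peak_velocity}
        for e in events
    ]
    return pd.DataFrame(rows)
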