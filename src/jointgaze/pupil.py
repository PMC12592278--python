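"""Pupil trace cleaning and per-trial baseline / evoked-response features.

Each eye's diameter trace is cleaned separately: values outside the
physiologically plausible 2-8 mm band are dropped, outliers deviating more
than 3 median absolute deviations from a 150 ms rolling median are dropped,
and gaps up to 150 ms are linearly interpolated.  The two eyes are then
averaged sample-wise (single valid eye used when only one is available).

Per trial, the baseline pupil size (BPS) is the mean diameter over the
first 500 ms (the first half of the attention-grabber phase, before the
luminance-adaptation transient).  The trace is normalized by subtracting
BPS, and the stimulus-evoked pupillary response (SEPR) is the mean
normalized diameter over 4.5-5.5 s, the dilation window following target
cueing (which starts at 3 s).  SEPR may be negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TrialSegment
from .events import _runs

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PupilConfig:
    min_mm: float = 2.0
    max_mm: float = 8.0
    mad_multiplier: float = 3.0
    rolling_window_ms: float = 150.0
    interp_max_ms: float = 150.0
    bps_window: tuple[float, float] = (0.0, 0.5)
    sepr_window: tuple[float, float] = (4.5, 5.5)
    min_coverage: float = 0.5  # valid fraction required inside a window

    def __post_init__(self) -> None:
        if self.min_mm >= self.max_mm:
            raise ValueError("min_mm must be below max_mm")
        if not (0.0 < self.min_coverage <= 1.0):
            raise ValueError("min_coverage must be in (0, 1]")


def _mad_filter(values: np.ndarray, window: int, mult: float) -> np.ndarray:
    """Drop samples deviating more than ``mult`` x MAD from the rolling
    median of a centred window; returns a copy with outliers as NaN."""
    s = pd.Series(values)
    med = s.rolling(window, center=True, min_periods=1).median()
    dev = (s - med).abs()
    mad = dev.rolling(window, center=True, min_periods=1).median()
    out = values.copy()
    out[(dev > mult * mad).to_numpy()] = np.nan
    return out


def _interpolate_gaps(t: np.ndarray, values: np.ndarray,
                      max_gap_s: float) -> np.ndarray:
    """Linearly bridge NaN gaps no longer than ``max_gap_s`` that are
    flanked by valid samples; valid samples are never altered."""
    out = values.copy()
    finite = np.isfinite(out)
    for i0, i1 in _runs(~finite):
        if i0 == 0 or i1 == len(out):
            continue  # no flanking sample on one side
        dt_local = (t[i1] - t[i0 - 1]) / (i1 - i0 + 1)
        if (i1 - i0) * dt_local > max_gap_s + 1e-12:
            continue
        lo, hi = i0 - 1, i1
        frac = (t[i0:i1] - t[lo]) / (t[hi] - t[lo])
        out[i0:i1] = out[lo] + frac * (out[hi] - out[lo])
    return out


def clean_pupil(segment: TrialSegment, cfg: PupilConfig = PupilConfig()
                ) -> TrialSegment:
    """Range filter, rolling-MAD outlier filter and gap interpolation,
    applied per eye; cleaned traces go to ``pupil_left_c``/``pupil_right_c``."""
    seg = segment.copy()
    t = seg.data["t"].to_numpy()
    window = max(1, int(round(cfg.rolling_window_ms * 1e-3 * seg.rate)))
    for eye in ("left", "right"):
        p = seg.data[f"pupil_{eye}"].to_numpy(dtype=float).copy()
        p[(p < cfg.min_mm) | (p > cfg.max_mm)] = np.nan
        p = _mad_filter(p, window, cfg.mad_multiplier)
        p = _interpolate_gaps(t, p, cfg.interp_max_ms * 1e-3)
        seg.data[f"pupil_{eye}_c"] = p
    return seg


def combine_eyes(segment: TrialSegment) -> np.ndarray:
    """Binocular mean pupil diameter; single eye when only one is valid."""
    pl = segment.data["pupil_left_c"].to_numpy(dtype=float)
    pr = segment.data["pupil_right_c"].to_numpy(dtype=float)
    lv, rv = np.isfinite(pl), np.isfinite(pr)
    return np.where(lv & rv, 0.5 * (pl + pr),
                    np.where(lv, pl, np.where(rv, pr, np.nan)))


def _window_mean(t: np.ndarray, values: np.ndarray,
                 window: tuple[float, float], min_coverage: float
                 ) -> float | None:
    lo, hi = window
    mask = (t >= lo) & (t < hi)
    if not mask.any():
        return None
    vals = values[mask]
    coverage = float(np.mean(np.isfinite(vals)))
    if coverage < min_coverage:
        log.info("window [%.2f, %.2f) coverage %.2f below %.2f; "
                 "feature absent", lo, hi, coverage, min_coverage)
        return None
    return float(np.nanmean(vals))


def compute_bps(t: np.ndarray, pupil: np.ndarray,
                cfg: PupilConfig = PupilConfig()) -> float | None:
    """Baseline pupil size: mean diameter over the first 500 ms."""
    return _window_mean(t, pupil, cfg.bps_window, cfg.min_coverage)


def normalize_trial(pupil: np.ndarray, bps: float) -> np.ndarray:
    """Baseline-subtracted trace (missing samples stay missing)."""
    return pupil - bps


def compute_sepr(t: np.ndarray, normalized: np.ndarray,
                 cfg: PupilConfig = PupilConfig()) -> float | None:
    """Stimulus-evoked pupillary response: mean normalized diameter over
    the 4.5-5.5 s dilation window; may be negative."""
    return _window_mean(t, normalized, cfg.sepr_window, cfg.min_coverage)


def pupil_features(segment: TrialSegment, cfg: PupilConfig = PupilConfig()
                   ) -> tuple[float | None, float | None, float]:
    """Run the pupil chain on one trial: clean per eye, combine, BPS,
    normalize, SEPR.  Returns (bps, sepr, missing_fraction); absent
    features are None, never imputed."""
    seg = clean_pupil(segment, cfg)
    pupil = combine_eyes(seg)
    t = seg.data["t"].to_numpy()
    missing_fraction = float(np.mean(~np.isfinite(pupil)))
    bps = compute_bps(t, pupil, cfg)
    if bps is None:
        return None, None, missing_fraction
    sepr = compute_sepr(t, normalize_trial(pupil, bps), cfg)
    return bps, sepr, missing_fraction
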