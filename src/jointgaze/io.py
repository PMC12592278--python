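"""Session file I/O, trial segmentation and pixel/angle conversion.

Gaze sample files are tab-separated with one row per sample and columns
``time`` (monotone; microseconds, milliseconds or seconds, auto-detected),
``x_left  y_left  x_right  y_right`` (screen pixels, origin top-left),
``pupil_left  pupil_right`` (millimetres) and ``valid_left  valid_right``
(0/1 tracker validity).  Streams carry a per-sample ``status`` label that
only the documented cleaning steps may change:

    valid -> missing | blink | excluded | implausible

All time windows in this package are half-open ``[t0, t1)``; trial-local
time zero is the attention-grabber onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .paradigm import ParadigmSpec, ScreenGeometry

log = logging.getLogger(__name__)

STATUS_VALID = "valid"
STATUS_MISSING = "missing"
STATUS_BLINK = "blink"
STATUS_EXCLUDED = "excluded"
STATUS_IMPLAUSIBLE = "implausible"

GAZE_COLUMNS = [
    "time", "x_left", "y_left", "x_right", "y_right",
    "pupil_left", "pupil_right", "valid_left", "valid_right",
]


@dataclass
class SampleStream:
    """Time-indexed binocular gaze/pupil samples.

    ``data`` holds columns ``t`` (seconds), the per-eye gaze/pupil/validity
    channels, combined gaze ``x, y`` (average of valid eyes) and ``status``.
    """

    data: pd.DataFrame
    rate: float

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "SampleStream":
        return SampleStream(self.data.copy(), self.rate)


@dataclass
class TrialSegment:
    """One trial's slice of a session with its condition labels."""

    trial_id: int
    cueing: str
    stimulus: str
    target_side: str
    onset: float  # session time of trial-local zero
    data: pd.DataFrame  # trial-local t
    rate: float
    paradigm: ParadigmSpec
    dropped: bool = False
    drop_reason: str = ""
    notes: dict = field(default_factory=dict)

    def copy(self) -> "TrialSegment":
        return replace(self, data=self.data.copy(), notes=dict(self.notes))


def px_to_deg(dx_px, dy_px, geometry: ScreenGeometry):
    """Angular distance (degrees) spanned by a pixel displacement.

    Each axis is converted with ``atan(pitch * d / distance)`` and the two
    axis angles are combined as a Euclidean norm.
    """
    pitch = geometry.pixel_pitch_mm
    d = geometry.viewing_distance_mm
    ax = np.degrees(np.arctan(pitch * np.asarray(dx_px, dtype=float) / d))
    ay = np.degrees(np.arctan(pitch * np.asarray(dy_px, dtype=float) / d))
    return np.hypot(ax, ay)


def deg_to_px(angle_deg, geometry: ScreenGeometry):
    """Inverse of the per-axis conversion (single axis)."""
    pitch = geometry.pixel_pitch_mm
    d = geometry.viewing_distance_mm
    return d * np.tan(np.radians(np.asarray(angle_deg, dtype=float))) / pitch


def _detect_time_unit(raw_time: np.ndarray) -> float:
    """Return the factor that converts raw timestamps to seconds.

    Decided from the median inter-sample difference: ~3333 for a 300 Hz
    recording in microseconds, ~3.3 in milliseconds, ~0.0033 in seconds.
    """
    if len(raw_time) < 2:
        return 1.0
    dt = float(np.median(np.diff(raw_time)))
    if dt >= 500.0:
        return 1e-6
    if dt >= 0.5:
        return 1e-3
    return 1.0


def combine_gaze(data: pd.DataFrame) -> pd.DataFrame:
    """Add combined gaze columns ``x, y``: binocular average where both
    eyes are valid, the single valid eye otherwise, NaN when neither."""
    lv = data["valid_left"].to_numpy(dtype=bool) & np.isfinite(data["x_left"])
    rv = data["valid_right"].to_numpy(dtype=bool) & np.isfinite(data["x_right"])
    xl, yl = data["x_left"].to_numpy(float), data["y_left"].to_numpy(float)
    xr, yr = data["x_right"].to_numpy(float), data["y_right"].to_numpy(float)
    x = np.where(lv & rv, 0.5 * (xl + xr), np.where(lv, xl, np.where(rv, xr, np.nan)))
    y = np.where(lv & rv, 0.5 * (yl + yr), np.where(lv, yl, np.where(rv, yr, np.nan)))
    data = data.copy()
    data["x"] = x
    data["y"] = y
    return data


def read_gaze_file(path, time_unit: float | None = None) -> SampleStream:
    """Read a tab-separated gaze sample file.

    Samples with an invalid tracker flag or absent coordinates get status
    ``missing``; rows are never reordered.  Unknown columns are ignored
    with a log line; non-monotone timestamps raise ``ValueError`` naming
    the first offending row.
    """
    raw = pd.read_csv(path, sep="\t")
    unknown = [c for c in raw.columns if c not in GAZE_COLUMNS]
    if unknown:
        log.info("ignoring unknown columns in %s: %s", path, unknown)
    missing_cols = [c for c in GAZE_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"gaze file {path} lacks columns {missing_cols}")

    raw_time = raw["time"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(raw_time) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-monotone timestamp at row {int(bad[0]) + 1} of {path}"
        )
    if time_unit is None:
        time_unit = _detect_time_unit(raw_time)
        log.info("detected time unit factor %g for %s", time_unit, path)
    t = (raw_time - raw_time[0]) * time_unit

    data = raw[GAZE_COLUMNS[1:]].copy()
    data.insert(0, "t", t)
    data["valid_left"] = data["valid_left"].astype(bool)
    data["valid_right"] = data["valid_right"].astype(bool)
    data = combine_gaze(data)
    has_gaze = np.isfinite(data["x"].to_numpy())
    data["status"] = np.where(has_gaze, STATUS_VALID, STATUS_MISSING)

    rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else float("nan")
    return SampleStream(data, rate)


def write_gaze_file(stream: SampleStream, path) -> None:
    """Write a stream back to the tab-separated sample dialect."""
    out = stream.data.copy()
    out["time"] = np.round(out["t"] * 1e6).astype("int64")  # microseconds
    out["valid_left"] = out["valid_left"].astype(int)
    out["valid_right"] = out["valid_right"].astype(int)
    out[GAZE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.4f")


def segment_trials(stream: SampleStream, trial_log: pd.DataFrame,
                   paradigm: ParadigmSpec) -> list[TrialSegment]:
    """Cut a session stream into per-trial segments.

    Every in-trial sample lands in exactly one segment; samples outside all
    trials are discarded.  Overlapping trial windows are rejected; a trial
    extending past the end of the stream is kept but marked dropped with
    reason ``truncated``.
    """
    trial_log = trial_log.sort_values("onset_s").reset_index(drop=True)
    onsets = trial_log["onset_s"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) < paradigm.trial_duration):
        raise ValueError("trial windows overlap")

    t = stream.data["t"].to_numpy()
    t_end = t[-1] if len(t) else 0.0
    segments: list[TrialSegment] = []
    for row in trial_log.itertuples(index=False):
        lo, hi = row.onset_s, row.onset_s + paradigm.trial_duration
        mask = (t >= lo) & (t < hi)
        data = stream.data.loc[mask].copy()
        data["t"] = data["t"] - lo
        data = data.reset_index(drop=True)
        seg = TrialSegment(
            trial_id=int(row.trial), cueing=row.cueing, stimulus=row.stimulus,
            target_side=row.target_side, onset=float(lo), data=data,
            rate=stream.rate, paradigm=paradigm,
        )
        # half a sample of slack so a trial ending exactly at the last
        # sample is not spuriously truncated
        if hi > t_end + 1.5 / stream.rate:
            seg.dropped = True
            seg.drop_reason = "truncated"
        segments.append(seg)
    return segments


FEATURE_COLUMNS = [
    "participant", "group", "timepoint", "trial",
    "cueing", "stimulus", "target_side",
    "rja", "rja_latency_s", "rja_duration_s", "total_fixation_duration_s",
    "bps_mm", "sepr_mm", "missing_fraction", "pupil_missing_fraction",
]


def write_features_table(features: pd.DataFrame, path) -> None:
    """Write the per-trial features CSV with a stable column order.

    Duplicate (participant, timepoint, trial) keys are an error.
    """
    key = ["participant", "timepoint", "trial"]
    if features.duplicated(subset=key).any():
        dup = features[features.duplicated(subset=key)].iloc[0]
        raise ValueError(
            "duplicate feature row for "
            f"({dup['participant']}, {dup['timepoint']}, {dup['trial']})"
        )
    cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    cols += [c for c in features.columns if c not in cols]
    features[cols].to_csv(path, index=False, float_format="%.12g")


def read_features_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "rja" in table.columns:
        table["rja"] = table["rja"].astype(bool)
    return table


def write_trial_log(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.6f")


def read_trial_log(path) -> pd.DataFrame:
    return pd.read_csv(path)
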