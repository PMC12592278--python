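"""Trial paradigm, screen geometry and area-of-interest (AOI) definitions.

The gaze-following task consists of 16 trials of 11 s each.  Every trial
runs through four phases: an attention grabber at the future head location
(0-1 s), an intro in which a model looks into the camera while two target
objects are visible (1-3 s), a target-cueing phase in which the model cues
one object by gaze, facial expression or pointing (3-9 s), and an outro with
direct gaze again (9-11 s).  Trials cross four cueing conditions with four
object stimuli; the side of the cued object is counterbalanced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CUEING_LEVELS = ("neutral", "mild", "intense", "neutral+pointing")
STIMULI = ("rabbit", "truck", "ball", "flower")
TARGET_SIDES = ("left", "right")
GROUPS = ("A-FFIP", "EIAU", "non-autistic")
TIMEPOINTS = ("BL", "ET", "FU")


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical presentation-screen model used for pixel/angle conversion.

    The physical size is derived from the diagonal and the pixel aspect
    ratio (a 27-inch 16:9 panel is 597.9 x 336.3 mm).  Viewing distance is
    not a property of the screen but is carried here because every
    conversion needs it; there is no sensible universal default for infant
    setups, so analyses must state it explicitly (650 mm is typical for a
    remote tracker).
    """

    width_px: int = 1920
    height_px: int = 1080
    diagonal_inch: float = 27.0
    viewing_distance_mm: float = 650.0

    def __post_init__(self) -> None:
        if self.viewing_distance_mm <= 0:
            raise ValueError("viewing distance must be positive")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("screen resolution must be positive")

    @property
    def diagonal_mm(self) -> float:
        return self.diagonal_inch * 25.4

    @property
    def width_mm(self) -> float:
        aspect = self.width_px / self.height_px
        return self.diagonal_mm * aspect / math.hypot(aspect, 1.0)

    @property
    def height_mm(self) -> float:
        return self.width_mm * self.height_px / self.width_px

    @property
    def pixel_pitch_mm(self) -> float:
        """Physical size of one (square) pixel in millimetres."""
        return self.width_mm / self.width_px


@dataclass(frozen=True)
class ParadigmSpec:
    """Timing and design of the reactive-joint-attention paradigm."""

    n_trials: int = 16
    trial_duration: float = 11.0
    attention_grabber_onset: float = 0.0
    intro_onset: float = 1.0
    cueing_onset: float = 3.0
    outro_onset: float = 9.0
    sampling_rate: float = 300.0
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)

    def __post_init__(self) -> None:
        onsets = (
            self.attention_grabber_onset,
            self.intro_onset,
            self.cueing_onset,
            self.outro_onset,
        )
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("phase onsets must be strictly increasing")
        if onsets[-1] >= self.trial_duration:
            raise ValueError("phase onsets must lie within the trial")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def phase_onsets(self) -> dict[str, float]:
        return {
            "attention_grabber": self.attention_grabber_onset,
            "intro": self.intro_onset,
            "cueing": self.cueing_onset,
            "outro": self.outro_onset,
        }

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_duration * self.sampling_rate))

    def condition_table(self, seed: int = 0) -> pd.DataFrame:
        """Return the 16-trial condition design in pseudorandom order.

        The full cross of cueing condition and stimulus gives 16 trials;
        target side alternates within each cueing condition so both sides
        appear equally often (8/8).  Presentation order is a seeded
        permutation within each of two blocks of eight.
        """
        rows = []
        for i, cue in enumerate(CUEING_LEVELS):
            for j, stim in enumerate(STIMULI):
                side = TARGET_SIDES[(i + j) % 2]
                rows.append({"cueing": cue, "stimulus": stim, "target_side": side})
        table = pd.DataFrame(rows)
        rng = np.random.default_rng(seed)
        # two blocks of eight; each block holds two trials per cueing level
        order = np.argsort(np.tile(rng.permutation(8), 2) + np.repeat([0, 100], 8))
        interleave = np.arange(16).reshape(2, 8).T.ravel()  # alternate levels
        table = table.iloc[interleave].iloc[order].reset_index(drop=True)
        table.insert(0, "trial", np.arange(1, len(table) + 1))
        return table


@dataclass(frozen=True)
class AOI:
    """Axis-aligned screen region; membership is half-open ([x0, x1) etc.)."""

    name: str
    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"AOI {self.name!r} is degenerate")

    def contains(self, x: float, y: float) -> bool:
        return (self.x0 <= x < self.x1) and (self.y0 <= y < self.y1)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def overlaps(self, other: "AOI") -> bool:
        return not (
            self.x1 <= other.x0
            or other.x1 <= self.x0
            or self.y1 <= other.y0
            or other.y1 <= self.y0
        )


@dataclass(frozen=True)
class AOISet:
    """The three regions the scoring rule refers to.

    The layout is constant across trial phases; the pointing condition uses
    the same regions (no separate hand region), so scoring has no
    condition-dependent branches.
    """

    head: AOI
    target_left: AOI
    target_right: AOI

    def __post_init__(self) -> None:
        for t in (self.target_left, self.target_right):
            if self.head.overlaps(t):
                raise ValueError("head AOI must not overlap target AOIs")

    def target(self, side: str) -> AOI:
        if side == "left":
            return self.target_left
        if side == "right":
            return self.target_right
        raise ValueError(f"unknown target side {side!r}")

    def __iter__(self):
        return iter((self.head, self.target_left, self.target_right))


def default_aois() -> AOISet:
    """AOI layout for the synthetic paradigm on a 1920x1080 screen.

    The head region sits top-centre where the model's face appears; the two
    object regions sit left and right below it.
    """
    return AOISet(
        head=AOI("head", 760.0, 80.0, 1160.0, 520.0),
        target_left=AOI("target_left", 140.0, 560.0, 620.0, 1000.0),
        target_right=AOI("target_right", 1300.0, 560.0, 1780.0, 1000.0),
    )


def write_aoi_file(aois: AOISet, path) -> None:
    rows = [
        {"name": a.name, "x0": a.x0, "y0": a.y0, "x1": a.x1, "y1": a.y1,
         "active_phase": "all"}
        for a in aois
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_aoi_file(path) -> AOISet:
    table = pd.read_csv(path).set_index("name")

    def make(name: str) -> AOI:
        r = table.loc[name]
        return AOI(name, float(r.x0), float(r.y0), float(r.x1), float(r.y1))

    return AOISet(head=make("head"), target_left=make("target_left"),
                  target_right=make("target_right"))
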