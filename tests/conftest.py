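import numpy as np
import pandas as pd
import pytest

from jointgaze import (CleaningConfig, ParadigmSpec, ScreenGeometry,
                       default_aois)
from jointgaze.io import STATUS_VALID, SampleStream, TrialSegment


@pytest.fixture(scope="session")
def paradigm() -> ParadigmSpec:
    return ParadigmSpec()


@pytest.fixture(scope="session")
def geometry(paradigm) -> ScreenGeometry:
    return paradigm.screen


@pytest.fixture(scope="session")
def aois():
    return default_aois()


@pytest.fixture
def cleaning_cfg() -> CleaningConfig:
    return CleaningConfig()


def make_segment(paradigm, *, x=None, y=None, pupil=None, status=None,
                 n=None, target_side="left") -> TrialSegment:
    """Build a trial segment from explicit channel arrays (constant screen
    centre and 4 mm pupil by default)."""
    if n is None:
        for arr in (x, y, pupil, status):
            if arr is not None:
                n = len(arr)
                break
        else:
            n = paradigm.samples_per_trial
    t = np.arange(n) / paradigm.sampling_rate
    x = np.full(n, 960.0) if x is None else np.asarray(x, dtype=float)
    y = np.full(n, 540.0) if y is None else np.asarray(y, dtype=float)
    pupil = np.full(n, 4.0) if pupil is None else np.asarray(pupil, dtype=float)
    status = (np.full(n, STATUS_VALID, dtype=object) if status is None
              else np.asarray(status, dtype=object))
    valid = status == STATUS_VALID
    data = pd.DataFrame({
        "t": t,
        "x_left": x, "y_left": y, "x_right": x, "y_right": y,
        "pupil_left": pupil, "pupil_right": pupil,
        "valid_left": valid, "valid_right": valid,
        "x": x.copy(), "y": y.copy(),
        "status": status,
    })
    gone = ~valid
    for col in ("x_left", "y_left", "x_right", "y_right", "x", "y",
                "pupil_left", "pupil_right"):
        data.loc[gone, col] = np.nan
    return TrialSegment(trial_id=1, cueing="neutral", stimulus="ball",
                        target_side=target_side, onset=0.0, data=data,
                        rate=paradigm.sampling_rate, paradigm=paradigm)


@pytest.fixture
def segment_factory(paradigm):
    def factory(**kwargs):
        return make_segment(paradigm, **kwargs)
    return factory
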