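import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from lakecolor.synthetic import SyntheticConfig  # noqa: E402

#: Representative in-class (tp, color) values (class medians).
CLASS_POINTS = {
    "blue": (16.5, 11.0),
    "green": (65.0, 15.0),
    "brown": (20.0, 30.0),
    "murky": (110.0, 30.0),
}


def make_survey_frame(n=12, year=2007, seed=0, weight=10.0):
    """Small valid survey table with a mix of classes."""
    rng = np.random.default_rng(seed)
    classes = [list(CLASS_POINTS)[i % 4] for i in range(n)]
    tp = [CLASS_POINTS[c][0] + rng.uniform(-1, 1) for c in classes]
    color = [CLASS_POINTS[c][1] + rng.uniform(-1, 1) for c in classes]
    return pd.DataFrame({
        "site_id": [f"L{i:03d}" for i in range(n)],
        "year": year,
        "ecoregion": ["East" if i % 2 else "West" for i in range(n)],
        "weight": weight,
        "lat": rng.uniform(30, 48, n).round(4),
        "lon": rng.uniform(-120, -70, n).round(4),
        "tp": np.round(tp, 3),
        "color": np.round(color, 3),
        "tp_below_detection": False,
        "area_ha": rng.uniform(5, 500, n).round(2),
    })


def paired_frame(points_t1, points_t2):
    """Build a paired table from lists of (tp, color) tuples."""
    n = len(points_t1)
    return pd.DataFrame({
        "site_id": [f"P{i:03d}" for i in range(n)],
        "tp_t1": [p[0] for p in points_t1],
        "color_t1": [p[1] for p in points_t1],
        "tp_t2": [p[0] for p in points_t2],
        "color_t2": [p[1] for p in points_t2],
    })


@pytest.fixture
def survey_frame():
    return make_survey_frame()


@pytest.fixture
def survey_csv(tmp_path, survey_frame):
    path = tmp_path / "survey.csv"
    survey_frame.to_csv(path, index=False)
    return path


@pytest.fixture
def small_config():
    """Scaled-down generator configuration for fast tests."""
    return SyntheticConfig(
        strata=(("West", 400, 60), ("Center", 400, 60), ("East", 400, 60)),
    )
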