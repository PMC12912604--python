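import numpy as np
import pandas as pd
import pytest

from greensim.config import study_case_config
from greensim.roof_optics import GlazingOptics, RoofGeometry
from greensim.simulator import build_system, integrate, synthesize_forcing
from greensim.weather import synthesize_weather


@pytest.fixture(scope="session")
def glazing():
    return GlazingOptics()


@pytest.fixture(scope="session")
def roof_geom():
    return RoofGeometry()


@pytest.fixture(scope="session")
def study_cfg():
    # coarse view-factor cells keep the radiation pipeline fast in tests
    return study_case_config(vf_cell_size=8.0)


@pytest.fixture(scope="session")
def winter_day():
    w = synthesize_weather(1, seed=11, start="2015-01-12")
    f = synthesize_forcing(w, seed=11)
    return w, f


@pytest.fixture(scope="session")
def summer_day():
    w = synthesize_weather(1, seed=12, start="2015-07-05")
    f = synthesize_forcing(w, seed=12)
    return w, f


@pytest.fixture(scope="session")
def short_run(study_cfg, winter_day):
    """A 4-hour winter-night simulation reused by several checks."""
    w, f = winter_day
    model = build_system(study_cfg)
    return integrate(model, w.iloc[:48], f.iloc[:48])
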