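import numpy as np
import pandas as pd
import pytest

import ctcrw


def make_track(lons, lats, start="2018-01-01", gap_h=6.0, animal_id="w1",
               meta=None, project=True):
    """Build a projected Track from lon/lat sequences with regular gaps."""
    n = len(lons)
    times = pd.date_range(start, periods=n, freq=pd.Timedelta(hours=gap_h),
                          tz="UTC")
    fixes = pd.DataFrame({"time": times, "lon": lons, "lat": lats,
                          "lc": ["3"] * n, "smaj": np.nan, "smin": np.nan,
                          "eor": np.nan})
    tr = ctcrw.Track(meta=meta or ctcrw.AnimalMeta(animal_id=animal_id),
                     fixes=fixes)
    return ctcrw.project(tr) if project else tr


@pytest.fixture(scope="session")
def small_fleet():
    """A small simulated fleet with truth, shared across tests."""
    cfg = ctcrw.SimConfig.recovery_default(seed=7)
    cfg.n_animals, cfg.n_group1, cfg.n_fixes = 8, 4, 100
    stack = ctcrw.gen_covariate_fields(cfg, 7)
    tel, meta, truth = ctcrw.gen_fleet(cfg, stack, 7)
    return cfg, stack, tel, meta, truth


@pytest.fixture(scope="session")
def deployment_table():
    return ctcrw.datasets.deployment_summary()
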