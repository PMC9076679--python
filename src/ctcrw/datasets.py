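"""Reference data shipped with the package.

``deployment_summary`` is the published per-animal deployment and
tracking summary for the 22 satellite-tagged Southwest Atlantic humpback
whales retained after censoring (2003–2019, two tagging periods).
``best_pmodel`` carries the published coefficient table of the best
pooled model (DEPTH + SST + CURL + SSTA + ICE08 with sex-group
deviations). Both serve as inputs for reproducing the printed
descriptive statistics and ice-effect ratios.
"""

from __future__ import annotations

import importlib.resources
import io
import json

import numpy as np
import pandas as pd
from shapely.geometry import shape

from .linkfit import LinkCoefficients

_DEPLOYMENT_CSV = """\
id,sex,cp,sr,locs,start,end,date50s,m_time,td,ice08_pct,ice10_pct
2003-24642,F,Yes,Mo,504,2003-12-28,2004-05-18,2004-02-02,36,142,59.1,61.5
2005-10946,F,Yes,Mo,132,2005-10-25,2006-01-03,2005-12-02,38,70,17.4,34.1
2005-24641,F,Yes,Mo,159,2005-10-27,2006-02-08,2005-12-26,60,104,10.7,11.3
2009-87783,F,Yes,Mo,577,2009-10-19,2010-02-03,2009-12-29,71,107,21.8,0.0
2009-87771,U,No,Ad,362,2009-09-21,2009-11-13,2009-10-19,28,53,35.6,13.5
2012-111871,F,Yes,Mo,2385,2012-11-25,2013-04-20,2013-01-02,38,146,52.8,73.9
2012-121189,M,No,Ad,1546,2012-10-25,2013-07-26,2012-12-14,50,274,61.3,61.1
2012-87632,F,Yes,Mo,1335,2013-01-20,2013-04-13,,,83,100.0,100.0
2017-172000,U,No,Ad,781,2017-12-07,2018-01-21,2018-01-03,27,45,0.0,0.0
2017-172002,F,Yes,Mo,1763,2017-11-16,2018-03-11,2017-12-21,35,115,7.1,5.0
2017-84484,M,No,Es,704,2017-12-05,2018-01-14,2018-01-07,33,40,0.0,0.0
2017-111870,M,No,Un,1849,2017-11-03,2018-02-07,2017-12-01,28,96,0.0,0.0
2017-172001,F,Yes,Mo,2226,2017-11-28,2018-03-17,2017-12-26,28,109,45.0,29.2
2017-121203,M,No,Es,2051,2017-10-26,2018-02-05,2017-11-22,27,102,21.2,19.3
2017-120937,M,No,Es,1733,2017-10-30,2018-01-19,2017-11-24,25,81,0.0,0.0
2018-84485,F,Yes,Mo,810,2018-12-04,2019-01-24,2019-01-04,31,51,0.0,0.0
2018-112696,F,Yes,Mo,700,2018-10-26,2018-12-06,2018-11-29,34,41,0.0,0.0
2018-172008,M,No,Es,2252,2018-10-22,2019-02-06,2018-11-26,35,107,67.2,69.5
2018-121191,F,Yes,Mo,894,2018-11-29,2019-01-17,2019-01-09,41,49,0.0,0.0
2018-171994,M,No,Es,1291,2018-10-25,2018-12-22,2018-11-30,36,58,0.0,0.0
2019-194591,U,No,Ad,1204,2019-10-27,2020-01-10,2019-12-16,50,75,0.0,0.0
2019-194601,F,Yes,Mo,402,2019-10-24,2019-12-10,2019-12-01,38,47,0.0,0.0
"""

#: best pooled model: covariate order, sigma-predictor (A) and
#: beta-predictor (B) coefficients with sex-group deviations (a, b).
_BEST_PMODEL = {
    "covariates": ["DEPTH", "SST", "CURL", "SSTA", "ICE08"],
    "A0": 8.94, "a0": -0.02,
    "A": [0.06, 0.37, 0.15, -0.13, -0.08],
    "a": [-0.17, 0.06, -0.05, 0.09, -0.39],
    "B0": -0.60, "b0": -0.12,
    "B": [-0.01, -0.68, -0.17, 0.13, 0.47],
    "b": [0.18, 0.11, -0.23, -0.11, 2.17],
}

_BEST_PMODEL_SE = {
    "A0": 0.02, "a0": 0.02,
    "A": [0.02, 0.02, 0.01, 0.01, 0.03],
    "a": [0.02, 0.03, 0.02, 0.02, 0.04],
    "B0": 0.03, "b0": 0.05,
    "B": [0.03, 0.03, 0.03, 0.02, 0.08],
    "b": [0.04, 0.05, 0.04, 0.03, 0.15],
}


def deployment_summary() -> pd.DataFrame:
    """Published 22-whale deployment/tracking summary table.

    Columns: id, sex (F/M/U), cp (calf presence), sr (social role), locs,
    start, end, date50s (first crossing of 50°S), m_time (migratory
    duration, days; NA for the track entirely south of the Polar Front),
    td (tracking duration, days), ice08_pct, ice10_pct. The m_time and
    period groupings reproduce the published descriptive statistics.
    """
    df = pd.read_csv(io.StringIO(_DEPLOYMENT_CSV))
    for col in ("start", "end", "date50s"):
        df[col] = pd.to_datetime(df[col])
    df["period"] = np.where(df["id"].str[:4].astype(int) <= 2012, 1, 2)
    return df


def best_pmodel() -> tuple[LinkCoefficients, dict]:
    """Published best pooled-model coefficients (sex grouping) and SEs."""
    d = _BEST_PMODEL
    coefs = LinkCoefficients(
        covariates=list(d["covariates"]),
        A0=d["A0"], a0=d["a0"], A=np.array(d["A"]), a=np.array(d["a"]),
        B0=d["B0"], b0=d["b0"], B=np.array(d["B"]), b=np.array(d["b"]))
    return coefs, json.loads(json.dumps(_BEST_PMODEL_SE))


def shelf_polygon():
    """Synthetic proxy polygon for the Brazilian continental shelf.

    A hand-drawn stand-in for the ~200 m isobath between 34°S and 5°S,
    used as the default pre-migration censoring boundary; replace with a
    real isobath polygon for real-data work.
    """
    ref = importlib.resources.files("ctcrw") / "data" / "brazil_shelf_synthetic.geojson"
    gj = json.loads(ref.read_text())
    return shape(gj["features"][0]["geometry"])
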