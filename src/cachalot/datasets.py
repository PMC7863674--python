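"""Bundled reference dataset: movement summaries of 21 satellite-tracked
sperm whales from Mauritius (south-west Indian Ocean).

Per-whale season segments with the tag type, sex, deployment dates,
number of Argos locations, tracking duration (days), cumulative distance
(km) and mean horizontal speed (km/h), split into the wet (Dec-Mar) and
dry (Apr-Nov) monsoon seasons. Useful as a realistic target for the
summary-statistics machinery: ``season_means`` on this table reproduces
the published per-season means.
"""

from __future__ import annotations

import io

import pandas as pd

_WHALE_SUMMARIES_CSV = """\
ptt,instrument,sex,start_date,end_date,n_locations,duration_days,distance_km,speed_kmh,season
3963a,SPLASH10,Male,2014-12-03,2015-01-19,163,47,1553.6,2.7,Wet
3965a,SPOT5,Female,2014-12-02,2015-01-09,110,38,1397.7,2.9,Wet
20158a,SPOT5,Female,2014-12-01,2015-01-05,77,35,1760.9,3.1,Wet
20160a,SPOT5,Female,2014-12-01,2014-12-21,50,20,825.03,3.0,Wet
20166b,SPOT5,Female,2014-12-02,2014-12-24,107,22,912.78,2.9,Wet
24642,SPOT6,Female,2018-12-01,2019-03-18,171,107,3066.6,2.8,Wet
26712,SPOT6,Female,2018-12-01,2018-12-30,74,29,1398.9,3.2,Wet
26715,SPOT6,Female,2018-12-01,2018-12-17,27,16,497.33,2.2,Wet
27261,SPOT6,Female,2018-12-01,2019-01-23,105,53,2064.5,3.2,Wet
50678b,SPLASH10,Female,2018-12-01,2018-12-27,83,26,1308.5,2.8,Wet
50681b,SPLASH10,Male,2018-12-02,2018-12-02,2,1,251.85,3.2,Wet
50682b,SPLASH10,Female,2018-12-01,2018-12-28,86,27,1353.2,3.7,Wet
50683b,SPLASH10,Female,2018-12-01,2018-12-03,4,2,99.2,2.2,Wet
7618,SPOT6,Female,2018-12-03,2019-01-20,132,48,2115.5,3.0,Wet
7926,SPOT6,Female,2018-12-01,2019-01-21,118,51,2437,3.4,Wet
37282,SPLASH10,Female,2016-05-04,2016-06-10,98,37,1275.3,2.6,Dry
50678,SPLASH10,Female,2016-05-05,2016-05-09,13,4,149.83,1.8,Dry
50681,SPLASH10,Female,2016-05-03,2016-06-05,106,33,1403.9,2.9,Dry
50682,SPLASH10,Female,2016-05-02,2016-05-23,107,21,1128,3.3,Dry
50683,SPLASH10,Female,2016-05-03,2016-05-09,26,6,222.16,2.7,Dry
93106,SPLASH10,Female,2016-05-01,2016-08-08,176,99,2517.4,2.3,Dry
24642,SPOT6,Female,2018-11-29,2018-11-30,5,1,45.903,2.1,Dry
26712,SPOT6,Female,2018-11-30,2018-11-30,2,1,0.048959,0.0,Dry
27261,SPOT6,Female,2018-11-30,2018-11-30,5,1,52.516,2.8,Dry
50678b,SPLASH10,Female,2018-11-24,2018-11-30,33,6,229.93,2.9,Dry
50681b,SPLASH10,Male,2018-11-24,2018-11-29,19,5,212.85,2.6,Dry
50682b,SPLASH10,Female,2018-11-29,2018-11-30,13,1,60.563,3.1,Dry
50683b,SPLASH10,Female,2018-11-24,2018-11-28,9,4,183.44,1.7,Dry
7618,SPOT6,Female,2018-11-25,2018-11-30,26,5,149.53,1.8,Dry
7926,SPOT6,Female,2018-11-29,2018-11-30,8,1,52.53,2.4,Dry
"""

#: published per-season means +/- SD for the summary columns, at the
#: precision they were reported (integers except speed).
PUBLISHED_SEASON_MEANS = {
    "Wet": {"n_locations": (87, 40), "duration_days": (35, 18),
            "distance_km": (1403, 611), "speed_kmh": (2.9, 0.3)},
    "Dry": {"n_locations": (43, 42), "duration_days": (15, 17),
            "distance_km": (512, 570), "speed_kmh": (2.3, 0.6)},
}


def whale_track_summaries() -> pd.DataFrame:
    """The 30 per-(whale, season) movement summary rows as a DataFrame."""
    df = pd.read_csv(io.StringIO(_WHALE_SUMMARIES_CSV))
    df = df.rename(columns={"ptt": "id"})
    return df
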