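"""Bundled reference measurements from the method's validation study.

Two small tables travel with the package so the validation statistics can
be recomputed without any download:

* ``OLDER_ADULT_TRIAL`` — the worked single-subject example: a 21.03 m
  tape-measured corridor walk of 30 strides per leg in 99.3 s, with the
  pipeline's per-leg distance estimates.
* ``load_validation_table()`` — the ten-participant motion-capture
  comparison: per leg, the optical reference and IMU-estimated travelled
  distance (m) and walk period (s).
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

OLDER_ADULT_TRIAL = {
    "actual_distance_m": 21.03,
    "estimated_right_m": 20.59,
    "estimated_left_m": 20.47,
    "total_time_s": 99.3,
    "strides_per_leg": 30,
    "steps_per_leg": 30,
}

_VALIDATION_CSV = """\
participant,leg,reference_distance_m,estimated_distance_m,reference_period_s,estimated_period_s
1,right,7.650,7.607,12.670,12.510
1,left,7.522,7.459,12.330,12.330
2,right,7.402,7.155,12.670,12.830
2,left,7.456,7.327,12.330,12.280
3,right,8.181,8.126,8.720,8.740
3,left,7.984,7.747,8.280,8.150
4,right,7.978,7.806,8.720,8.880
4,left,8.121,8.061,8.280,8.180
5,right,7.735,7.699,9.780,9.750
5,left,7.842,7.791,9.720,9.640
6,right,7.564,7.493,9.780,9.710
6,left,7.481,7.518,9.720,9.830
7,right,7.693,6.784,7.380,7.250
7,left,7.626,7.197,7.030,7.130
8,right,7.422,6.939,7.380,7.310
8,left,7.144,6.669,7.030,7.140
9,right,7.769,7.744,7.940,7.910
9,left,7.755,7.626,7.870,8.000
10,right,7.508,7.485,7.940,7.960
10,left,7.623,7.613,7.870,7.800
"""


def load_validation_table() -> pd.DataFrame:
    """Reference-vs-estimated distances and periods, one row per leg."""
    return pd.read_csv(StringIO(_VALIDATION_CSV))
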