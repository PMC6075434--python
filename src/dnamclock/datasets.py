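"""Small published datasets shipped with the package.

Currently one table: per-cell-line clock results for skin fibroblasts
from Hutchinson–Gilford progeria syndrome (HGPS) donors distributed by
The Progeria Research Foundation — chronological age, clock DNAm age and
the published epigenetic age acceleration (years; residual from the
original study's control reference fit, which is not itself published).
The table is the standard worked example for nonparametric group
comparison of acceleration values, e.g. classic-HGPS boys versus girls.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["hgps_fibroblasts"]

_HGPS_CSV = """\
cell_line,progeria,sex,age,dnam_age,age_accel
PSADFN086,NonClassic,m,0.58,0.39,-3.49
PSADFN257,NonClassic,m,1.83,4.44,-0.51
PSADFN257.replicate,NonClassic,m,1.8,4.84,-0.08
PSADFN317,NonClassic,m,3.8,8.86,2.23
PSADFN318,NonClassic,m,0.4,7.48,3.75
PSADFN392,NonClassic,m,7.3,21.61,11.99
HGADFN003,Classic,m,2,3.39,-1.70
HGADFN169,Classic,m,8.5,23.73,13.08
HGADFN143,Classic,m,8.8,15.61,4.71
HGADFN167,Classic,m,8.4,17.88,7.32
HGADFN271,Classic,m,1.3,10.73,6.24
HGADFN164,Classic,f,4.66,10.64,3.28
HGADFN178,Classic,f,6.92,4.36,-4.93
HGADFN122,Classic,f,5,6.96,-0.70
HGADFN127,Classic,f,3.8,2.10,-4.53
HGADFN155,Classic,f,1.1,0.59,-3.73
HGADFN188,Classic,f,2.3,1.23,-4.11
HGADFN367,Classic,f,3,17.10,11.16
"""


def hgps_fibroblasts() -> pd.DataFrame:
    """HGPS fibroblast clock results (published per-line values).

    Columns: cell_line, progeria ({Classic, NonClassic}), sex ({m, f}),
    age (years), dnam_age (years), age_accel (years).
    """
    return pd.read_csv(io.StringIO(_HGPS_CSV))
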