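"""Nonparametric group comparison.

The Kruskal–Wallis rank test is the workhorse for comparing epigenetic
age acceleration between small groups (cases vs controls, male vs female)
without normality assumptions: H is computed from tie-corrected rank sums
and referred to a chi-square distribution with (k − 1) degrees of
freedom.  Because H depends on the data only through ranks, it is
invariant under any strictly monotone transformation of the values.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["kruskal_wallis"]


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    ``values`` are the observations, ``groups`` the parallel group
    labels; there must be at least two distinct non-empty groups.  When
    every observation is identical the tie correction degenerates and the
    conventional (H, p) = (0, 1) is returned.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if len(v) != len(g):
        raise ValueError("values and groups differ in length")
    labels = sorted(set(g.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    parts = [v[g == lab] for lab in labels]
    for lab, part in zip(labels, parts):
        if len(part) == 0:
            raise ValueError(f"group {lab!r} has no samples")
    if np.all(v == v[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*parts)
    return float(h), float(p)
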