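"""Cell-culture population-doubling bookkeeping and DNAm-age trends.

In an ex vivo aging assay cells are counted at each passage, a fixed
number re-seeded, and population doubling (PD) computed from the count
ratio as

    PD = [log10(harvested) − log10(seeded)] × 3.32

with cumulative PD the running sum over passages.  The printed constant
3.32 approximates 1/log10(2) = 3.3219…; the approximation is the default
so that bookkeeping matches lab practice bit-for-bit, with the exact
constant available behind a flag.  A clock applied to DNA sampled along
the series yields a DNAm-age-versus-cumulative-PD trend whose slope
(years per doubling) quantifies culture-driven epigenetic aging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PassageRecord", "population_doubling", "cumulative_pd", "pd_age_trend"]

_APPROX_FACTOR = 3.32


@dataclass(frozen=True)
class PassageRecord:
    """One passaging step: counts in, counts out, optional DNA sample."""

    passage: int
    cells_seeded: float
    cells_harvested: float
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.passage < 0:
            raise ValueError("passage index must be >= 0")
        if self.cells_seeded <= 0 or self.cells_harvested <= 0:
            raise ValueError("cell counts must be positive")


def population_doubling(seeded: float, harvested: float, exact: bool = False) -> float:
    """Doublings between seeding and harvest from the two cell counts.

    ``exact=True`` uses 1/log10(2) in place of the conventional 3.32.
    """
    if seeded <= 0 or harvested <= 0:
        raise ValueError("cell counts must be positive")
    factor = 1.0 / math.log10(2.0) if exact else _APPROX_FACTOR
    return (math.log10(harvested) - math.log10(seeded)) * factor


def cumulative_pd(series, exact: bool = False) -> np.ndarray:
    """Cumulative population doubling at each passage of a series.

    ``series`` is a sequence of :class:`PassageRecord` with strictly
    increasing passage indices.  Harvests below the seed count give
    negative per-passage PD (the formula is applied as stated), so the
    running sum can dip.
    """
    series = list(series)
    idx = [r.passage for r in series]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ValueError("passage indices must be strictly increasing")
    pds = [population_doubling(r.cells_seeded, r.cells_harvested, exact) for r in series]
    return np.cumsum(pds) if pds else np.array([])


def pd_age_trend(cum_pd, dnam_ages) -> tuple[float, float]:
    """Least-squares slope (years per doubling) and Pearson r of DNAm age on PD."""
    x = np.asarray(cum_pd, dtype=float)
    y = np.asarray(dnam_ages, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired (cumulative PD, DNAm age) points")
    if x.std() == 0:
        raise ValueError("zero variance in cumulative PD; trend undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.rvalue)
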