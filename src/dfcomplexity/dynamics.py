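"""First/second-order and excursion-based summaries of an NMTS.

The excursions-from-median (EfM) statistic grades "how dynamic" a series
is by accumulating duration^a * amplitude^b over every maximal run of
samples on one side of the series median.  Compared to the variance it is
sensitive to the *persistence* of deviations, not only their size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError

__all__ = ["EfMParams", "SummaryStats", "summary", "efm"]


@dataclass(frozen=True)
class EfMParams:
    """Exponents weighting excursion duration (a) and amplitude (b)."""

    a: float = 0.9
    b: float = 1.0


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    variance: float  # sample variance, denominator n-1


def _values(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=float)


def summary(x) -> SummaryStats:
    """Arithmetic mean and sample variance of a series."""
    v = _values(x)
    if len(v) < 2:
        raise InsufficientDataError("summary needs length >= 2")
    return SummaryStats(float(v.mean()), float(v.var(ddof=1)))


def efm(x, params: EfMParams = EfMParams()) -> float:
    """Excursions from median: sum over excursions of t_l^a * h_l^b.

    Median crossings partition the series into excursions (maximal runs of
    constant nonzero sign of x - median); t_l is the run length in samples
    and h_l the maximum |x - median| within the run.  Samples exactly at
    the median terminate an excursion and belong to none.
    """
    v = _values(x)
    if len(v) < 3:
        raise InsufficientDataError("efm needs length >= 3")
    d = v - np.median(v)
    s = np.sign(d)
    total = 0.0
    run_len = 0
    run_max = 0.0
    prev = 0.0
    for di, si in zip(np.abs(d), s):
        if si != 0 and si == prev:
            run_len += 1
            run_max = max(run_max, di)
        else:
            if run_len:
                total += run_len**params.a * run_max**params.b
            run_len = 1 if si != 0 else 0
            run_max = di if si != 0 else 0.0
        prev = si
    if run_len:
        total += run_len**params.a * run_max**params.b
    return float(total)
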