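"""Modified permutation entropy (mPE) of a time series.

Ordinary permutation entropy assumes no two values in an embedding window
are equal; time series of thresholded network measures violate that
freely (the topology can be identical at consecutive time points), so the
modified scheme maps *tied* values to the same rank symbol.  Entropy is
the base-2 Shannon entropy of the empirical pattern distribution,
unnormalized, so an i.i.d. continuous series approaches log2(order!) bits
from below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError

__all__ = ["MPEParams", "mpe", "modified_patterns"]


@dataclass(frozen=True)
class MPEParams:
    """Ordinal-pattern length (order) and embedding lag in samples."""

    order: int = 7
    lag: int = 3

    def __post_init__(self) -> None:
        if self.order < 2 or self.lag < 1:
            raise InvalidParameterError("need order >= 2 and lag >= 1")


def modified_patterns(x: np.ndarray, params: MPEParams) -> np.ndarray:
    """Encode each lag-spaced window as its modified ordinal pattern.

    Ranks are dense ranks by ascending value: equal values (exact floating
    equality - thresholded-network series genuinely repeat) share a rank
    and the ranks are renumbered compactly, e.g. (0.3, 0.1, 0.3) -> (1, 0, 1).
    Patterns are packed into a single integer code per window.
    """
    x = np.asarray(x, dtype=float)
    order, lag = params.order, params.lag
    n_pat = len(x) - (order - 1) * lag
    if n_pat < 1:
        raise InsufficientDataError(
            f"series of length {len(x)} too short for order={order}, lag={lag}"
        )
    windows = x[np.arange(n_pat)[:, None] + np.arange(order) * lag]
    srt = np.argsort(windows, axis=1, kind="stable")
    sv = np.take_along_axis(windows, srt, axis=1)
    levels = np.zeros_like(windows, dtype=np.int64)
    levels[:, 1:] = np.cumsum(np.diff(sv, axis=1) > 0, axis=1)
    ranks = np.empty_like(levels)
    np.put_along_axis(ranks, srt, levels, axis=1)
    return ranks @ (order ** np.arange(order, dtype=np.int64))


def mpe(x, params: MPEParams = MPEParams()) -> float:
    """Modified permutation entropy in bits (unnormalized, overlapping
    windows with step 1)."""
    v = np.asarray(getattr(x, "values", x), dtype=float)
    if len(v) < params.order * params.lag + 1:
        raise InsufficientDataError("series too short for the embedding")
    codes = modified_patterns(v, params)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())
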