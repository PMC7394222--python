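"""Synthetic inputs for every pipeline stage.

Four generators stand in for the study data so the whole pipeline is
testable without recordings:

* exact fractional Gaussian noise (circulant embedding) - monofractal
  series with a known Hurst exponent, for estimator-recovery tests;
* random binomial multiplicative cascades - positive-control
  multifractal series with closed-form singularity support;
* band-limited coupled multichannel recordings - EEG-like inputs for the
  connectivity estimators;
* random dynamic networks with i.i.d. Gaussian edge weights - the
  null-model control for the complexity measures;
* two-group feature tables with planted mean shifts - classifier fixture.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .connectivity import DynamicConnectivityTensor, Recording
from .errors import InsufficientDataError, InvalidParameterError
from .filtering import bandpass_array

__all__ = [
    "FractalSeries",
    "RandomNetworkSpec",
    "gen_fgn",
    "gen_cascade",
    "gen_coupled_recording",
    "gen_random_dynamic_networks",
    "gen_two_group_features",
    "fgn_autocovariance",
    "cascade_singularity_support",
]


@dataclass
class FractalSeries:
    """A scalar series with (optionally) known nominal scaling exponent."""

    values: np.ndarray
    nominal_hurst: float | None
    kind: str  # {fgn, fbm, cascade, powerlaw}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < 8:
            raise InvalidParameterError("fractal series must have length >= 8")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("fractal series must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class RandomNetworkSpec:
    """Null-model dynamic networks: every edge weight at every time point
    i.i.d. Normal(edge_mean, edge_variance)."""

    n_nodes: int = 19
    n_timepoints: int = 2**15
    edge_mean: float = 0.3
    edge_variance: float = 3e-4
    cost: float = 0.35
    n_networks: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2 or self.n_timepoints < 1 or self.n_networks < 1:
            raise InvalidParameterError("invalid network dimensions")
        if self.edge_variance < 0:
            raise InvalidParameterError("edge_variance must be >= 0")
        if not 0 < self.cost <= 1:
            raise InvalidParameterError("cost must lie in (0, 1]")


def fgn_autocovariance(hurst: float, lags: np.ndarray) -> np.ndarray:
    """Closed-form fGn autocovariance
    gamma(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H) / 2 (unit variance)."""
    k = np.abs(np.asarray(lags, dtype=float))
    two_h = 2.0 * hurst
    return 0.5 * ((k + 1) ** two_h - 2 * k**two_h + np.abs(k - 1) ** two_h)


def gen_fgn(n: int, hurst: float, seed: int) -> FractalSeries:
    """Exact fractional Gaussian noise via circulant embedding.

    The covariance matrix of the returned sequence equals the closed-form
    fGn autocovariance exactly (the circulant eigenvalues are nonnegative
    for all H in (0, 1)), so recovery tests have a true H to recover.
    H = 0.5 reduces to white noise.
    """
    if not 0 < hurst < 1:
        raise InvalidParameterError("hurst must lie in (0, 1)")
    if n < 16:
        raise InvalidParameterError("need n >= 16")
    gamma = fgn_autocovariance(hurst, np.arange(n))
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, size 2n-2
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        raise InvalidParameterError("circulant embedding not nonnegative definite")
    lam = np.clip(lam, 0.0, None)
    m = len(row)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(lam / m) * z)  # real part has covariance gamma exactly
    return FractalSeries(x.real[:n], hurst, "fgn")


def gen_cascade(levels: int, p: float, seed: int) -> FractalSeries:
    """Random binomial multiplicative cascade of 2^levels bins.

    Starting from unit mass, each interval splits in two; one half (chosen
    at random) receives fraction p of the mass, the other 1-p.  The
    returned values are the bin masses, i.e. the increment series of the
    cumulative measure, whose analytic Hölder exponents span
    [-log2(max(p, 1-p)), -log2(min(p, 1-p))].  Total mass is conserved.
    """
    if not 0 < p < 1:
        raise InvalidParameterError("p must lie in (0, 1)")
    if levels < 4:
        raise InvalidParameterError("need levels >= 4")
    rng = np.random.default_rng(seed)
    mass = np.array([1.0])
    for lev in range(levels):
        flip = rng.random(len(mass)) < 0.5
        left = np.where(flip, p, 1.0 - p)
        mass = np.column_stack([mass * left, mass * (1.0 - left)]).ravel()
    return FractalSeries(mass, None, "cascade")


def cascade_singularity_support(p: float) -> float:
    """Width of the analytic singularity support of a binomial cascade:
    log2(max(p, 1-p) / min(p, 1-p)); zero for the degenerate p = 1/2."""
    hi, lo = max(p, 1 - p), min(p, 1 - p)
    return float(np.log2(hi / lo))


def gen_coupled_recording(
    n_channels: int,
    n_samples: int,
    fs: float,
    band: tuple[float, float],
    mixing: np.ndarray,
    noise_sd: float,
    seed: int,
) -> Recording:
    """Band-limited multichannel recording: mixing x sources + noise.

    Sources are independent Gaussian noise band-passed with the same
    zero-phase Butterworth as the preprocessing stage; channel j is
    sum_k mixing[j, k] * source_k plus independent white noise of SD
    ``noise_sd``.  Shared sources induce cross-channel coupling.
    """
    lf, hf = band
    mixing = np.atleast_2d(np.asarray(mixing, dtype=float))
    if mixing.shape[0] != n_channels:
        raise InvalidParameterError("mixing must have n_channels rows")
    if not np.all(np.isfinite(mixing)):
        raise InvalidParameterError("mixing must be finite")
    rng = np.random.default_rng(seed)
    n_sources = mixing.shape[1]
    sources = rng.standard_normal((n_sources, n_samples))
    sources = bandpass_array(sources, fs, lf, hf, axis=1)  # validates the band
    data = mixing @ sources + noise_sd * rng.standard_normal((n_channels, n_samples))
    return Recording(data, fs)


def _one_random_tensor(spec: RandomNetworkSpec, rng: np.random.Generator
                       ) -> DynamicConnectivityTensor:
    n, t = spec.n_nodes, spec.n_timepoints
    iu, ju = np.triu_indices(n, k=1)
    flat = rng.normal(spec.edge_mean, np.sqrt(spec.edge_variance), size=(t, len(iu)))
    w = np.zeros((t, n, n))
    w[:, iu, ju] = flat
    w[:, ju, iu] = flat
    return DynamicConnectivityTensor(w, np.arange(t), "SL")


def gen_random_dynamic_networks(
    spec: RandomNetworkSpec,
) -> Iterator[DynamicConnectivityTensor]:
    """Yield ``spec.n_networks`` random dynamic networks one at a time.

    Every upper-triangle weight at every time point is an independent
    Normal(edge_mean, edge_variance) draw; slices are symmetric with zero
    diagonal.  A generator is returned because one default-size tensor is
    ~95 MB; consume and discard.
    """
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.n_networks):
        yield _one_random_tensor(spec, rng)


def gen_two_group_features(
    n_per_group: int,
    n_features: int,
    shifted_features: tuple[int, ...] = (),
    shift_sd_units: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced two-class feature table with planted group differences.

    Features are unit-variance Gaussian; the listed feature columns are
    mean-shifted by ``shift_sd_units`` standard deviations in the second
    group ("SZ").  Returns a DataFrame with feature columns plus a
    ``group`` label column ("HC"/"SZ"), indexed by subject id.
    """
    if n_per_group < 2:
        raise InvalidParameterError("need n_per_group >= 2")
    shifted = tuple(shifted_features)
    if any(not 0 <= i < n_features for i in shifted):
        raise InvalidParameterError("shifted_features out of range")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((2 * n_per_group, n_features))
    x[n_per_group:, list(shifted)] += shift_sd_units
    labels = ["HC"] * n_per_group + ["SZ"] * n_per_group
    ids = [f"hc{i:02d}" for i in range(n_per_group)] + [
        f"sz{i:02d}" for i in range(n_per_group)
    ]
    df = pd.DataFrame(x, index=ids, columns=[f"f{i:02d}" for i in range(n_features)])
    df["group"] = labels
    return df
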