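"""Time-resolved functional connectivity estimation.

The primary estimator is the synchronization likelihood (SL), a
probability-type measure of generalized synchronization: two channels are
"synchronized" around time *i* to the extent that recurrences of their
delay-embedded state vectors coincide.  Phase-lag based estimators (PLI,
WPLI) are provided for validation; static connectivity is the time average
of the dynamic estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import hilbert

from .errors import InsufficientDataError, InvalidBandError, InvalidParameterError

__all__ = [
    "Recording",
    "EmbeddingParams",
    "DynamicConnectivityTensor",
    "derive_sl_parameters",
    "sl_dynamic",
    "truncate_tensor",
    "static_from_dynamic",
    "pli_dynamic",
    "wpli_dynamic",
]


@dataclass
class Recording:
    """A multichannel recording: ``samples`` is channels x time, ``fs`` in Hz."""

    samples: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] < 2:
            raise InvalidParameterError("recording needs >= 2 channels (channels x time)")
        if self.fs <= 0:
            raise InvalidParameterError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            bad = np.argwhere(~np.isfinite(self.samples))[0]
            raise InvalidParameterError(
                f"non-finite sample at channel {bad[0]}, index {bad[1]}"
            )
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise InvalidParameterError("channel_labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class EmbeddingParams:
    """SL parameters: embedding dimension m, lag L, Theiler window w1,
    outer window w2, recurrence fraction p_ref."""

    m: int
    L: int
    w1: int
    w2: int
    p_ref: float = 0.05

    def __post_init__(self) -> None:
        if self.m < 2 or self.L < 1:
            raise InvalidBandError("need m >= 2 and L >= 1")
        if not 0 < self.w1 < self.w2:
            raise InvalidParameterError("need 0 < w1 < w2")
        if not 0 < self.p_ref < 1:
            raise InvalidBandError("p_ref must lie in (0, 1)")

    @property
    def span(self) -> int:
        """Samples spanned by one delay vector."""
        return (self.m - 1) * self.L + 1


@dataclass
class DynamicConnectivityTensor:
    """Sequence of symmetric N x N weight matrices, one per valid time point."""

    weights: np.ndarray  # time x N x N
    time_index: np.ndarray  # sample index of each slice's center
    estimator_tag: str = "SL"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.time_index = np.asarray(self.time_index, dtype=int)
        if self.weights.ndim != 3 or self.weights.shape[1] != self.weights.shape[2]:
            raise InvalidParameterError("weights must be time x N x N")
        if len(self.time_index) != self.weights.shape[0]:
            raise InvalidParameterError("time_index length must match slice count")

    @property
    def n_times(self) -> int:
        return self.weights.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[1]

    def upper_triangle(self) -> np.ndarray:
        """Flattened upper-triangle weights, shape (time, N(N-1)/2)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[:, iu[0], iu[1]]


def derive_sl_parameters(
    fs: float,
    lf: float,
    hf: float,
    p_ref: float = 0.05,
    n_recurrences: int = 100,
) -> EmbeddingParams:
    """Derive SL embedding parameters from the frequency band.

    For a band-limited signal sampled at ``fs`` with band (lf, hf):
    L = floor(fs / (3 hf)), m = round(3 hf / lf) + 1, w1 = 2 L (m - 1)
    (the autocorrelation / Theiler exclusion window) and
    w2 = w1 + ceil(n_recurrences / (2 p_ref)) - 1, sized so the window
    holds ~``n_recurrences`` recurrences at resolution ``p_ref``.

    For 250 Hz delta-band EEG (0.5-4 Hz, p_ref=0.05) this gives the
    standard quadruple m=25, L=20, w1=960, w2=1959.
    """
    if not 0 < lf < hf < fs / 2:
        raise InvalidBandError(f"band ({lf}, {hf}) invalid for fs={fs}")
    if not 0 < p_ref < 1:
        raise InvalidBandError("p_ref must lie in (0, 1)")
    L = int(math.floor(fs / (3.0 * hf)))
    m = int(round(3.0 * hf / lf)) + 1
    if m < 2 or L < 1:
        raise InvalidBandError(f"band ({lf}, {hf}) at fs={fs} yields m={m}, L={L}")
    w1 = 2 * L * (m - 1)
    w2 = w1 + int(math.ceil(n_recurrences / (2.0 * p_ref))) - 1
    return EmbeddingParams(m=m, L=L, w1=w1, w2=w2, p_ref=p_ref)


def _delay_embed(x: np.ndarray, m: int, L: int) -> np.ndarray:
    """Delay vectors X_i = (x_i, x_{i+L}, ..., x_{i+(m-1)L}); shape (n_emb, m)."""
    span = (m - 1) * L + 1
    if len(x) < span:
        raise InsufficientDataError("series shorter than one embedding span")
    return sliding_window_view(x, span)[:, ::L]


def sl_dynamic(
    rec: Recording,
    params: EmbeddingParams,
    chunk: int = 256,
) -> DynamicConnectivityTensor:
    """Synchronization likelihood between all channel pairs, per time point.

    For every channel k and anchor time i, the critical distance eps_{k,i}
    is the empirical p_ref-quantile of Euclidean distances between the
    delay vector X_{k,i} and vectors X_{k,j} at window times
    w1 < |i - j| < w2.  SL between channels k and l at time i is the
    fraction of window times where *both* channels recur, normalized by
    the expected fraction p_ref:

        SL_{kl,i} = #{j : d_k(i,j) <= eps_{k,i} and d_l(i,j) <= eps_{l,i}}
                    / (p_ref * n_window)

    clipped to [0, 1].  Only anchors with a full two-sided window are kept,
    so every estimate has identical variance.
    """
    m, L, w1, w2, p_ref = params.m, params.L, params.w1, params.w2, params.p_ref
    emb = np.stack([_delay_embed(ch, m, L) for ch in rec.samples])  # (C, n_emb, m)
    n_ch, n_emb, _ = emb.shape
    offsets = np.arange(w1 + 1, w2)
    offsets = np.concatenate([-offsets[::-1], offsets])  # symmetric window
    n_w = len(offsets)
    if n_w < 2:
        raise InvalidParameterError("window (w1, w2) contains no recurrence times")
    first, last = w2 - 1, n_emb - w2  # inclusive valid anchor range
    if last < first:
        raise InsufficientDataError(
            f"record supports no anchor with a full +/-{w2 - 1} window "
            f"(only {n_emb} embedded points)"
        )
    centers = np.arange(first, last + 1)
    n_t = len(centers)
    sl = np.empty((n_t, n_ch, n_ch))
    denom = p_ref * n_w
    for start in range(0, n_t, chunk):
        cs = centers[start : start + chunk]  # anchors in this chunk
        js = cs[:, None] + offsets[None, :]  # (b, n_w)
        # distances: (C, b, n_w)
        diff = emb[:, cs, None, :] - emb[:, js, :]
        dist = np.sqrt(np.einsum("cbwm,cbwm->cbw", diff, diff))
        eps = np.quantile(dist, p_ref, axis=2, keepdims=True)
        rec_ind = (dist <= eps).astype(float)  # recurrence indicators
        counts = np.einsum("cbw,dbw->bcd", rec_ind, rec_ind)
        sl[start : start + len(cs)] = counts / denom
    np.clip(sl, 0.0, 1.0, out=sl)
    idx = np.arange(n_ch)
    sl[:, idx, idx] = 0.0
    # map embedded-anchor index to the raw-sample center of its delay vector
    sample_centers = centers + (m - 1) * L // 2
    return DynamicConnectivityTensor(sl, sample_centers, "SL")


def truncate_tensor(t: DynamicConnectivityTensor, n: int = 2**15) -> DynamicConnectivityTensor:
    """Keep the first ``n`` consecutive slices."""
    if t.n_times < n:
        raise InsufficientDataError(f"tensor has {t.n_times} slices, need {n}")
    return DynamicConnectivityTensor(
        t.weights[:n].copy(), t.time_index[:n].copy(), t.estimator_tag
    )


def static_from_dynamic(t: DynamicConnectivityTensor) -> np.ndarray:
    """Static connectivity: element-wise time average of the tensor."""
    if t.n_times < 1:
        raise InsufficientDataError("empty tensor")
    return t.weights.mean(axis=0)


def _analytic_phases(rec: Recording) -> np.ndarray:
    return np.asarray(hilbert(rec.samples, axis=1))


def _windowed_pairwise(rec: Recording, window: int, step: int, stat):
    if window < 16:
        raise InvalidParameterError("window must be >= 16 samples")
    n = rec.n_samples
    if window > n:
        raise InsufficientDataError(f"window {window} longer than record ({n})")
    z = _analytic_phases(rec)
    n_ch = rec.n_channels
    starts = np.arange(0, n - window + 1, step)
    out = np.zeros((len(starts), n_ch, n_ch))
    iu = np.triu_indices(n_ch, k=1)
    for a, b in zip(*iu):
        cross = z[a] * np.conj(z[b])
        cross_im = np.imag(cross)
        # discount numerically-zero lags: |Im C| at rounding level of |C|
        # must count as sign(0) = 0, or identical channels pick up noise
        cross_im = np.where(np.abs(cross_im) > 1e-10 * np.abs(cross), cross_im, 0.0)
        vals = stat(cross_im, window, starts)
        out[:, a, b] = vals
        out[:, b, a] = vals
    centers = starts + window // 2
    return out, centers


def _window_sums(x: np.ndarray, window: int, starts: np.ndarray) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(x)])
    return c[starts + window] - c[starts]


def pli_dynamic(
    rec: Recording, window: int, step: int = 1
) -> DynamicConnectivityTensor:
    """Phase lag index per sliding window.

    PLI = |mean sign(delta-phi)| where delta-phi is the instantaneous phase
    difference of the analytic signals; sign(0) contributes 0, so exactly
    zero-lag samples are discounted.
    """

    def stat(cross_im, window, starts):
        return np.abs(_window_sums(np.sign(cross_im), window, starts)) / window

    out, centers = _windowed_pairwise(rec, window, step, stat)
    return DynamicConnectivityTensor(out, centers, "PLI")


def wpli_dynamic(
    rec: Recording, window: int, step: int = 1
) -> DynamicConnectivityTensor:
    """Weighted phase lag index per sliding window.

    WPLI = |mean Im C| / mean |Im C| with C the per-sample cross-spectrum of
    the analytic signals; 0 when the denominator vanishes (e.g. zero lag).
    """

    def stat(cross_im, window, starts):
        num = np.abs(_window_sums(cross_im, window, starts))
        den = _window_sums(np.abs(cross_im), window, starts)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        return vals

    out, centers = _windowed_pairwise(rec, window, step, stat)
    return DynamicConnectivityTensor(out, centers, "WPLI")
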