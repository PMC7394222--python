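"""Focus-based multifractal analysis by signal summation conversion (SSC).

The noise-like input is converted to a walk by cumulative summation; the
scaling function

    S(q, s) = { (1/N_s) sum_v sigma(v, s)^q }^(1/q)

collects the q-th power means of per-window dispersions (bridge-detrended
standard deviations) across dyadic window sizes s.  For a finite record
all moment orders share one value at s = N - the *focus* - so the
generalized Hurst exponents H(q) are estimated by a joint least-squares
regression of ln S(q, s) on ln s anchored at the focus:

    ln S(q, s) ~ ln F + H(q) (ln s - ln N).

Anchoring every q at a common intercept is what keeps H(q) monotonically
decreasing in practice and makes the subsequent Legendre transform
(tau(q) = q H(q) - 1, h = dtau/dq, D(h) = q h - tau) well behaved.  The
spectrum is summarized by h_max, the Hölder exponent at the peak of D(h)
(global long-range autocorrelation strength), and FWHM, the full width of
D(h) at half maximum (degree of multifractality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSignalError, InsufficientDataError, MalformedSpectrumError

__all__ = [
    "ScalingGrid",
    "ScalingFunction",
    "MultifractalSpectrum",
    "ssc_profile",
    "scaling_function",
    "focus_regression",
    "legendre_spectrum",
    "mf_features",
    "mf_spectrum",
]


@dataclass(frozen=True)
class ScalingGrid:
    """Dyadic window sizes and moment orders for the scaling function."""

    scales: tuple
    q_values: tuple = tuple(range(-15, 16))

    @classmethod
    def for_length(
        cls,
        n: int,
        min_exp: int = 3,
        max_exp: int = 13,
        q_values: tuple = tuple(range(-15, 16)),
    ) -> "ScalingGrid":
        """Default grid: s = 2^k for k = min_exp..max_exp, capped at N/4.

        The lower limit keeps >= 8 points per window; the upper limit keeps
        >= 4 windows per scale.
        """
        hi = min(max_exp, int(np.floor(np.log2(n / 4))))
        if hi < min_exp:
            raise InsufficientDataError(f"series of length {n} supports no scales")
        return cls(tuple(int(2**k) for k in range(min_exp, hi + 1)), tuple(q_values))

    def __post_init__(self) -> None:
        if len(self.scales) < 1 or min(self.scales) < 8:
            raise InsufficientDataError("need scales >= 8 samples")
        if 0 not in self.q_values:
            raise MalformedSpectrumError("q grid must contain 0 (geometric-mean limit)")


@dataclass
class ScalingFunction:
    """ln S(q, s) on the grid plus per-scale window counts."""

    ln_s_values: np.ndarray  # (n_q, n_scales)
    window_counts: np.ndarray  # (n_scales,)
    grid: ScalingGrid
    n: int  # profile length (focus abscissa)


@dataclass
class MultifractalSpectrum:
    """Legendre spectrum of one series with its scalar summaries."""

    q: np.ndarray
    H: np.ndarray  # generalized Hurst exponents
    focus: float  # ln F, fitted intercept at ln N
    tau: np.ndarray
    h: np.ndarray  # Hölder exponents
    D: np.ndarray  # singularity dimensions
    h_max: float
    fwhm: float
    fit_sse: float
    flags: dict = field(default_factory=dict)


def ssc_profile(x) -> np.ndarray:
    """Cumulative sum of the mean-centered series (noise -> walk)."""
    v = np.asarray(getattr(x, "values", x), dtype=float)
    if len(v) < 32:
        raise InsufficientDataError("profile needs length >= 32")
    return np.cumsum(v - v.mean())


def _window_sigmas(
    profile: np.ndarray, s: int, bridge_detrend: bool, ddof: int
) -> np.ndarray:
    n_w = len(profile) // s
    seg = profile[: n_w * s].reshape(n_w, s)
    if bridge_detrend:
        t = np.arange(s) / (s - 1)
        seg = seg - (seg[:, :1] + (seg[:, -1:] - seg[:, :1]) * t)
    return seg.std(axis=1, ddof=ddof)


def scaling_function(
    profile: np.ndarray,
    grid: ScalingGrid,
    bridge_detrend: bool = True,
    ddof: int = 1,
) -> ScalingFunction:
    """Evaluate ln S(q, s) over the grid.

    Per scale the profile is cut into floor(N/s) non-overlapping windows;
    sigma(v, s) is the standard deviation of the bridge-detrended window
    (line through its endpoints removed).  q = 0 uses the geometric-mean
    limit S(0, s) = exp(mean ln sigma).  Powers are evaluated in log space
    so |q| = 15 stays finite.

    Windows with sigma = 0 (locally constant signal, for which S(q < 0)
    is undefined) are excluded from the power means; a scale where every
    window degenerates raises DegenerateSignalError.
    """
    profile = np.asarray(profile, dtype=float)
    n = len(profile)
    qs = np.asarray(grid.q_values, dtype=float)
    scales = np.asarray(grid.scales, dtype=int)
    if scales.max() > n:
        raise InsufficientDataError("largest scale exceeds profile length")
    ln_s_vals = np.empty((len(qs), len(scales)))
    counts = np.empty(len(scales), dtype=int)
    for j, s in enumerate(scales):
        sig = _window_sigmas(profile, int(s), bridge_detrend, ddof)
        sig = sig[sig > 0]
        counts[j] = len(sig)
        if len(sig) == 0:
            raise DegenerateSignalError(
                f"all windows constant at scale {s} (sigma = 0 everywhere)"
            )
        ln_sig = np.log(sig)
        for i, q in enumerate(qs):
            if q == 0:
                ln_s_vals[i, j] = ln_sig.mean()
            else:
                mx = np.max(q * ln_sig)
                ln_s_vals[i, j] = (mx + np.log(np.mean(np.exp(q * ln_sig - mx)))) / q
    return ScalingFunction(ln_s_vals, counts, grid, n)


def focus_regression(sf: ScalingFunction) -> tuple[np.ndarray, float, float]:
    """Fit ln S(q, s) = ln F + H(q) (ln s - ln N) jointly over all (q, s).

    The intercept ln F (the focus) is shared by every q; the closed-form
    normal equations are solved directly.  Returns (H, ln F, SSE).
    """
    y = sf.ln_s_values
    scales = np.asarray(sf.grid.scales, dtype=float)
    if len(scales) < 3:
        raise InsufficientDataError("focus regression needs >= 3 scales")
    u = np.log(scales) - np.log(sf.n)
    su, suu, n_s = u.sum(), (u * u).sum(), len(u)
    n_q = y.shape[0]
    denom = n_q * (n_s - su * su / suu)
    if abs(denom) < 1e-12:
        raise InsufficientDataError("singular design: scales not distinct")
    ln_f = (y.sum() - (su / suu) * (y * u).sum()) / denom
    H = (y @ u - ln_f * su) / suu
    resid = y - (ln_f + H[:, None] * u[None, :])
    return H, float(ln_f), float((resid**2).sum())


def legendre_spectrum(
    H: np.ndarray,
    grid: ScalingGrid,
    focus: float = np.nan,
    fit_sse: float = np.nan,
) -> MultifractalSpectrum:
    """Legendre transform of H(q) and its scalar summaries.

    tau(q) = q H(q) - 1; h = dtau/dq by central differences (one-sided at
    the ends); D(h) = q h - tau.  h_max is h at the maximum of D; FWHM is
    the width of {h : D(h) >= D_max - 1/2}, crossings located by linear
    interpolation on each limb.  A limb that never descends to the half
    level within the q range is truncated at its extreme h and flagged
    rather than extrapolated.
    """
    qs = np.asarray(grid.q_values, dtype=float)
    H = np.asarray(H, dtype=float)
    if H.shape != qs.shape:
        raise MalformedSpectrumError("H must be defined on the full q grid")
    tau = qs * H - 1.0
    h = np.gradient(tau, qs)
    D = qs * h - tau
    flags: dict = {}
    if np.any(np.diff(h) > 1e-10):
        flags["h_nonmonotone"] = True
        warnings.warn(
            "h(q) is not monotonically decreasing; spectrum may be multivalued",
            RuntimeWarning,
            stacklevel=2,
        )
    if np.ptp(h) < 1e-10:
        # monofractal limit: tau linear, spectrum collapses to the point (H0, 1)
        return MultifractalSpectrum(
            q=qs, H=H, focus=focus, tau=tau, h=h, D=D,
            h_max=float(h.mean()), fwhm=0.0, fit_sse=fit_sse, flags=flags,
        )
    i_max = int(np.argmax(D))
    if i_max in (0, len(qs) - 1):
        raise MalformedSpectrumError(
            "singularity spectrum peaks at the q-grid boundary; no interior maximum"
        )
    h_max = float(h[i_max])
    half = D[i_max] - 0.5

    def limb_cross(indices: np.ndarray) -> float | None:
        # walk away from the peak; first half-level crossing, interpolated in h
        for a, b in zip(indices[:-1], indices[1:]):
            if (D[a] - half) >= 0 > (D[b] - half):
                t = (D[a] - half) / (D[a] - D[b])
                return float(h[a] + t * (h[b] - h[a]))
        return None

    right = limb_cross(np.arange(i_max, len(qs)))  # q > q_peak: small h
    left = limb_cross(np.arange(i_max, -1, -1))  # q < q_peak: large h
    if right is None:
        right = float(h[-1])
        flags["fwhm_truncated_right"] = True
    if left is None:
        left = float(h[0])
        flags["fwhm_truncated_left"] = True
    fwhm = float(abs(left - right))
    return MultifractalSpectrum(
        q=qs, H=H, focus=focus, tau=tau, h=h, D=D,
        h_max=h_max, fwhm=fwhm, fit_sse=fit_sse, flags=flags,
    )


def mf_spectrum(
    x,
    grid: ScalingGrid | None = None,
    bridge_detrend: bool = True,
    ddof: int = 1,
) -> MultifractalSpectrum:
    """Full FMF-SSC analysis of a noise-like series."""
    v = np.asarray(getattr(x, "values", x), dtype=float)
    if grid is None:
        grid = ScalingGrid.for_length(len(v))
    profile = ssc_profile(v)
    sf = scaling_function(profile, grid, bridge_detrend=bridge_detrend, ddof=ddof)
    H, ln_f, sse = focus_regression(sf)
    return legendre_spectrum(H, grid, focus=ln_f, fit_sse=sse)


def mf_features(x, grid: ScalingGrid | None = None) -> tuple[float, float]:
    """(h_max, FWHM) of a series under the default analysis settings."""
    spec = mf_spectrum(x, grid)
    return spec.h_max, spec.fwhm
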