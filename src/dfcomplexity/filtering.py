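"""Zero-phase Butterworth band-pass and notch filtering."""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt, iirnotch, sosfiltfilt

from .connectivity import Recording
from .errors import InvalidBandError

__all__ = ["bandpass_array", "bandpass"]


def bandpass_array(
    x: np.ndarray,
    fs: float,
    lf: float,
    hf: float,
    order: int = 5,
    notch: float | None = None,
    axis: int = -1,
) -> np.ndarray:
    """Forward-backward Butterworth band-pass (effective order doubled,
    zero phase), with an optional line-noise notch."""
    if not 0 < lf < hf < fs / 2:
        raise InvalidBandError(f"band ({lf}, {hf}) outside (0, Nyquist) for fs={fs}")
    sos = butter(order, [lf, hf], btype="bandpass", fs=fs, output="sos")
    y = sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)
    if notch is not None:
        if not 0 < notch < fs / 2:
            raise InvalidBandError(f"notch {notch} outside (0, Nyquist)")
        b, a = iirnotch(notch, Q=30.0, fs=fs)
        y = filtfilt(b, a, y, axis=axis)
    return y


def bandpass(
    rec: Recording,
    lf: float,
    hf: float,
    order: int = 5,
    notch: float | None = None,
) -> Recording:
    """Band-pass a recording channel-wise; returns a new Recording."""
    y = bandpass_array(rec.samples, rec.fs, lf, hf, order=order, notch=notch, axis=1)
    return Recording(y, rec.fs, list(rec.channel_labels))
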