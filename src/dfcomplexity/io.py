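"""Recording ingestion and delimited-table output.

CSV dialect for recordings: comma-separated, header row of channel
labels, one column per channel, one row per sample; the sampling rate
travels separately (argument or JSON sidecar).  EDF files are read
through MNE.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import Recording
from .errors import InvalidParameterError

__all__ = ["read_recording", "write_recording_csv"]


def write_recording_csv(rec: Recording, path: str | Path, sidecar: bool = True) -> Path:
    """Write a recording as CSV (samples x channels) plus a JSON sidecar
    holding the sampling rate."""
    path = Path(path)
    pd.DataFrame(rec.samples.T, columns=rec.channel_labels).to_csv(path, index=False)
    if sidecar:
        meta = {"fs": rec.fs, "channel_labels": list(rec.channel_labels)}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def _read_csv_recording(path: Path, fs: float | None) -> Recording:
    if fs is None:
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            fs = json.loads(sidecar.read_text())["fs"]
        else:
            raise InvalidParameterError(
                "CSV recordings need a sampling-rate argument or JSON sidecar"
            )
    df = pd.read_csv(path)
    data = df.to_numpy(dtype=float).T
    if not np.all(np.isfinite(data)):
        ch, idx = np.argwhere(~np.isfinite(data))[0]
        raise InvalidParameterError(
            f"{path}: non-finite value in channel '{df.columns[ch]}' at sample {idx}"
        )
    return Recording(data, float(fs), list(df.columns))


def _read_edf_recording(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def read_recording(
    path: str | Path, format: str | None = None, fs: float | None = None
) -> Recording:
    """Read a recording from CSV or EDF; format inferred from the suffix
    when not given."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt == "CSV":
        return _read_csv_recording(path, fs)
    if fmt == "EDF":
        return _read_edf_recording(path)
    raise InvalidParameterError(f"unsupported recording format: {fmt}")
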