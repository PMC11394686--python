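"""Recording and table I/O.

Primary interchange format: one delimited numeric file per subject
(columns = region labels) plus a JSON sidecar carrying subject, group,
sampling rate, and state intervals.  EDF reading is supported when mne is
installed (channel labels must match region names; annotations named
'rest'/'walk' supply the state intervals).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import LfpRecording


def write_recording(rec: LfpRecording, out_dir: str | Path) -> tuple[Path, Path]:
    """Write <subject>.csv (signals) and <subject>.json (metadata sidecar)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sig_path = out_dir / f"{rec.subject_id}.csv"
    meta_path = out_dir / f"{rec.subject_id}.json"
    pd.DataFrame(rec.channels).to_csv(sig_path, index=False, float_format="%.6f")
    meta = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "fs": rec.fs,
        "state_intervals": [list(iv) for iv in rec.state_intervals],
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return sig_path, meta_path


def read_recording(sig_path: str | Path) -> LfpRecording:
    """Read a delimited signal file with its JSON sidecar."""
    sig_path = Path(sig_path)
    meta_path = sig_path.with_suffix(".json")
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata sidecar {meta_path} not found")
    meta = json.loads(meta_path.read_text())
    df = pd.read_csv(sig_path)
    return LfpRecording(
        subject_id=meta["subject_id"],
        group=meta["group"],
        fs=float(meta["fs"]),
        channels={c: df[c].to_numpy(dtype=float) for c in df.columns},
        state_intervals=[(s, float(a), float(b)) for s, a, b in meta["state_intervals"]],
    )


def read_recording_dir(directory: str | Path) -> list[LfpRecording]:
    """All <subject>.csv/<subject>.json pairs in a directory, sorted by name."""
    directory = Path(directory)
    recs = [
        read_recording(p)
        for p in sorted(directory.glob("*.csv"))
        if p.with_suffix(".json").exists()
    ]
    if not recs:
        raise FileNotFoundError(f"no recording csv+json pairs in {directory}")
    return recs


def read_edf_recording(
    path: str | Path, subject_id: str, group: str
) -> LfpRecording:
    """Read an EDF file via mne; annotations 'rest'/'walk' become state intervals."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires mne (pip install mne)") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # mne returns volts
    channels = {name: data[i] for i, name in enumerate(raw.ch_names)}
    intervals = [
        (desc, float(onset), float(onset + dur))
        for onset, dur, desc in zip(
            raw.annotations.onset, raw.annotations.duration, raw.annotations.description
        )
        if desc in ("rest", "walk")
    ]
    return LfpRecording(subject_id, group, fs, channels, intervals)


def write_tables(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def nearest_float(x: float) -> float:  # small JSON helper
    return float(np.asarray(x).item())
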