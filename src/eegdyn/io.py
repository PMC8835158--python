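"""Reading and writing recordings, cohorts and result tables.

Recordings travel as flat little-endian float32 binary (time-major,
``.dat``) with a JSON sidecar carrying channel names, sampling rate,
units and shape; European Data Format files are read through ``mne``
when that package is installed.  Cohorts get a CSV manifest (subject id,
group, symptom score) next to the per-subject signal files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import ChannelMontage, default_montage
from .preprocess import Recording
from .synth import Cohort

__all__ = [
    "save_recording",
    "load_recording",
    "read_edf",
    "save_cohort",
    "load_cohort_manifest",
]


def save_recording(rec: Recording, path: str | Path) -> Path:
    """Write ``<path>.dat`` (float32 binary) and ``<path>.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dat = path.with_suffix(".dat")
    rec.data.astype("<f4").tofile(dat)
    sidecar = {
        "channels": list(rec.montage.names),
        "fs_hz": rec.fs_hz,
        "units": "uV",
        "n_samples": rec.n_samples,
        "dtype": "<f4",
        "order": "time_major",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return dat


def load_recording(path: str | Path,
                   montage: ChannelMontage | None = None) -> Recording:
    """Read a flat-binary + JSON-sidecar recording pair."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    raw = np.fromfile(path.with_suffix(".dat"), dtype=meta.get("dtype", "<f4"))
    n_ch = len(meta["channels"])
    data = raw.reshape(meta["n_samples"], n_ch).astype(float)
    if montage is None:
        default = default_montage()
        if list(default.names) == meta["channels"]:
            montage = default
        else:
            from .montage import generic_montage
            montage = ChannelMontage(
                names=tuple(meta["channels"]),
                positions=generic_montage(n_ch).positions,
                anterior_set=(), posterior_set=())
    return Recording(data=data, fs_hz=float(meta["fs_hz"]), montage=montage)


def read_edf(path: str | Path,
             montage: ChannelMontage | None = None) -> Recording:
    """Read a European Data Format file (requires the optional ``mne`` dep)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading EDF requires mne (pip install eegdyn[edf])") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data().T * 1e6  # volts -> microvolts
    if montage is None:
        names = tuple(raw.ch_names)
        from .montage import generic_montage
        montage = ChannelMontage(names=names,
                                 positions=generic_montage(len(names)).positions,
                                 anterior_set=(), posterior_set=())
    return Recording(data=data, fs_hz=float(raw.info["sfreq"]), montage=montage)


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write per-subject recordings and the cohort manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        save_recording(s.recording, out / s.subject_id)
        rows.append({"subject": s.subject_id, "group": s.group,
                     "score": round(s.score, 3),
                     "file": f"{s.subject_id}.dat"})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort_manifest(out_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(out_dir) / "manifest.csv")
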