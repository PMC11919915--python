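"""Readers and writers for recordings, template sets and result tables.

On-disk formats:

* recordings: EDF/BDF raw files (read via ``mne``) or the package's HDF5
  layout — ``/data`` (channels x samples, float64, microvolts) with attrs
  ``fs`` and ``reference``, ``/montage/names`` and ``/montage/positions``,
  and ``/bad_channels``; round-trips losslessly;
* montages: plain CSV (name, x, y, z);
* microstate template sets: JSON (K x C map matrix, letters, CV, GEV,
  level, channel names);
* label sequences: compact CSV (sample, label, abs_corr);
* parameter / evaluation / statistics tables: tidy CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .microstates import LabelSequence, MicrostateSet
from .montage import Montage
from .recording import Recording

__all__ = [
    "write_recording_h5", "read_recording_h5", "read_recording",
    "write_microstate_set", "read_microstate_set",
    "write_label_sequence", "read_label_sequence",
]


def write_recording_h5(recording: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=recording.data)
        d.attrs["unit"] = "uV"
        f.attrs["fs"] = recording.fs
        f.attrs["reference"] = recording.reference
        g = f.create_group("montage")
        g.create_dataset("names", data=np.array(recording.montage.names, dtype="S"))
        g.create_dataset("positions", data=recording.montage.positions)
        f.create_dataset("bad_channels",
                         data=np.array(sorted(recording.bad_channels), dtype="S"))


def read_recording_h5(path) -> Recording:
    with h5py.File(path, "r") as f:
        names = tuple(n.decode() for n in f["montage/names"][()])
        montage = Montage(names, f["montage/positions"][()])
        return Recording(
            data=f["data"][()], fs=float(f.attrs["fs"]), montage=montage,
            reference=str(f.attrs["reference"]),
            bad_channels={b.decode() for b in f["bad_channels"][()]},
        )


def read_recording(path, montage_path=None) -> Recording:
    """Read a recording from EDF/BDF or the HDF5 layout.

    EDF/BDF voltages are converted to microvolts.  When ``montage_path``
    is given, channels are matched *by name* to the montage and reordered
    to its row order; a name mismatch fails with the offending names.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        rec = read_recording_h5(path)
    elif path.suffix.lower() in (".edf", ".bdf"):
        import mne

        reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" \
            else mne.io.read_raw_edf
        raw = reader(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        n = len(raw.ch_names)
        from .montage import synthetic_montage

        montage = Montage(tuple(raw.ch_names),
                          synthetic_montage(n).positions)
        rec = Recording(data=data, fs=float(raw.info["sfreq"]), montage=montage,
                        reference="other")
    else:
        raise ValueError(f"unsupported recording container: {path.suffix!r}")

    if montage_path is not None:
        from .montage import read_montage_csv

        montage = read_montage_csv(montage_path)
        missing = set(montage.names) - set(rec.montage.names)
        extra = set(rec.montage.names) - set(montage.names)
        if missing or extra:
            raise ValueError(
                "channel-name mismatch between data and montage: "
                f"missing from data {sorted(missing)}, "
                f"unmatched in data {sorted(extra)}")
        order = [rec.montage.names.index(n) for n in montage.names]
        rec = Recording(data=rec.data[order], fs=rec.fs, montage=montage,
                        reference=rec.reference,
                        bad_channels=set(rec.bad_channels))
    return rec


def write_microstate_set(mset: MicrostateSet, path) -> None:
    payload = {
        "maps": mset.maps.tolist(),
        "cv": mset.cv,
        "gev": mset.gev,
        "level": mset.level,
        "letters": list(mset.letters) if mset.letters else None,
        "letter_corrs": mset.letter_corrs.tolist()
        if mset.letter_corrs is not None else None,
        "channel_names": list(mset.montage.names) if mset.montage else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_microstate_set(path, montage: Montage | None = None) -> MicrostateSet:
    payload = json.loads(Path(path).read_text())
    return MicrostateSet(
        maps=np.array(payload["maps"]), cv=payload["cv"], gev=payload["gev"],
        level=payload["level"],
        letters=tuple(payload["letters"]) if payload["letters"] else None,
        letter_corrs=np.array(payload["letter_corrs"])
        if payload["letter_corrs"] is not None else None,
        montage=montage,
    )


def write_label_sequence(labels: LabelSequence, path) -> None:
    pd.DataFrame({
        "sample": np.arange(len(labels)),
        "label": labels.labels,
        "abs_corr": labels.abs_corr,
    }).to_csv(path, index=False)


def read_label_sequence(path, fs: float) -> LabelSequence:
    df = pd.read_csv(path)
    return LabelSequence(labels=df["label"].to_numpy(np.int64),
                         abs_corr=df["abs_corr"].to_numpy(float), fs=fs)
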