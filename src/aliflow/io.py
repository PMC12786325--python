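"""Format readers/writers and seed plumbing.

Recordings travel as HDF5 (dataset ``/data`` of shape electrodes x samples,
float32, with ``fs``, ``t0``, ``condition`` and ``electrode_ids`` attributes)
or as a CSV fallback (one column per electrode, header row of electrode ids;
the sampling rate must then be supplied by the caller). Abundance tables are
TSV (first column ``protein_id``, one column per sample) with a companion
two-column TSV mapping sample id to condition; missing values are empty
cells.

All randomness in a run flows from one top-level seed through named
sub-streams (``derive_seed``), so any stage can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .classify import ClassificationReport
from .ephys import PowerSpectrogram, Recording, SpikeTrain
from .proteomics import AbundanceTable

__all__ = [
    "derive_seed",
    "read_recording",
    "write_recording",
    "write_spectrogram",
    "read_spectrogram",
    "write_spike_train",
    "read_abundance_table",
    "write_abundance_table",
    "write_report",
]


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed: hash of the top seed + stage name,
    reduced below 2**31 so it is valid for every RNG consumer."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def write_recording(rec: Recording, path: "str | Path") -> None:
    """Write a recording as HDF5 (default) or CSV by file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        frame = pd.DataFrame(rec.data.T, columns=[str(int(e)) for e in rec.electrode_ids])
        frame.to_csv(path, index=False)
        return
    with h5py.File(path, "w") as h5:
        h5.create_dataset("data", data=rec.data.astype(np.float32))
        h5.attrs["fs"] = rec.fs
        h5.attrs["t0"] = rec.t0
        h5.attrs["condition"] = rec.condition if rec.condition is not None else ""
        h5.attrs["electrode_ids"] = np.asarray(rec.electrode_ids, dtype=np.int64)


def read_recording(path: "str | Path", fs: Optional[float] = None) -> Recording:
    """Load and validate a recording from HDF5 or CSV.

    CSV carries no sampling rate, so ``fs`` is required for it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        if fs is None:
            raise ValueError("CSV recordings carry no sampling rate: pass fs explicitly")
        frame = pd.read_csv(path)
        ids = np.array([int(c) for c in frame.columns])
        return Recording(data=frame.to_numpy(dtype=np.float32).T, fs=fs, electrode_ids=ids)
    try:
        with h5py.File(path, "r") as h5:
            if "data" not in h5:
                raise ValueError(f"{path}: missing dataset '/data'")
            for attr in ("fs", "t0", "electrode_ids"):
                if attr not in h5.attrs:
                    raise ValueError(f"{path}: missing attribute {attr!r} on the file")
            condition = h5.attrs.get("condition", "")
            condition = str(condition) if str(condition) else None
            return Recording(
                data=h5["data"][()],
                fs=float(h5.attrs["fs"]),
                t0=float(h5.attrs["t0"]),
                condition=condition,
                electrode_ids=np.asarray(h5.attrs["electrode_ids"]),
            )
    except OSError as exc:
        raise ValueError(f"{path}: not a readable HDF5 recording ({exc})") from exc


def write_spectrogram(spec: PowerSpectrogram, path: "str | Path") -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("power", data=spec.power)
        h5.create_dataset("freqs", data=spec.freqs)
        h5.create_dataset("fragment_starts", data=spec.fragment_starts)
        h5.attrs["electrode_ids"] = np.asarray(spec.electrode_ids, dtype=np.int64)
        h5.attrs["condition"] = spec.condition if spec.condition is not None else ""


def read_spectrogram(path: "str | Path") -> PowerSpectrogram:
    with h5py.File(path, "r") as h5:
        for ds in ("power", "freqs", "fragment_starts"):
            if ds not in h5:
                raise ValueError(f"{path}: missing dataset '/{ds}'")
        condition = str(h5.attrs.get("condition", "")) or None
        return PowerSpectrogram(
            power=h5["power"][()],
            freqs=h5["freqs"][()],
            fragment_starts=h5["fragment_starts"][()],
            electrode_ids=np.asarray(h5.attrs["electrode_ids"]),
            condition=condition,
        )


def write_spike_train(train: SpikeTrain, path: "str | Path") -> None:
    """Spike times as tidy CSV: electrode, time_s."""
    rows = [
        {"electrode": eid, "time_s": t} for eid, times in train.times.items() for t in times
    ]
    pd.DataFrame(rows, columns=["electrode", "time_s"]).to_csv(path, index=False)


def write_abundance_table(tab: AbundanceTable, path: "str | Path") -> None:
    """TSV with empty cells for missing values, plus ``<stem>.conditions.tsv``."""
    path = Path(path)
    tab.values.to_csv(path, sep="\t", na_rep="")
    cond = tab.conditions.rename_axis("sample_id").reset_index()
    cond.to_csv(path.with_suffix(".conditions.tsv"), sep="\t", index=False)


def read_abundance_table(path: "str | Path", conditions_path: Optional["str | Path"] = None) -> AbundanceTable:
    path = Path(path)
    if conditions_path is None:
        conditions_path = path.with_suffix(".conditions.tsv")
    values = pd.read_csv(path, sep="\t", index_col=0)
    cond_frame = pd.read_csv(conditions_path, sep="\t")
    conditions = pd.Series(
        cond_frame["condition"].to_numpy(), index=cond_frame["sample_id"], name="condition"
    )
    return AbundanceTable(values=values, conditions=conditions)


def write_report(report: ClassificationReport, path: "str | Path") -> None:
    Path(path).write_text(report.to_json())
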