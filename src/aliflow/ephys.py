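"""Core LFP analysis for multi-electrode recordings.

Spike detection uses an amplitude threshold of 5.5 standard deviations with a
10-ms rolling merge window; spectral analysis splits the recording into
non-overlapping 10-s fragments and computes one-sided periodogram power
densities on a 0.1-Hz grid between 0.2 and 300 Hz. Band summaries cover the
canonical EEG bands plus high-frequency oscillations (HFO, 80-600 Hz), which
require a second spectral pass beyond the 300-Hz spectrogram cap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "SpikeTrain",
    "PowerSpectrogram",
    "BandSummary",
    "DEFAULT_BANDS",
    "detect_spikes",
    "spike_counts",
    "compute_power_density",
    "band_power",
    "select_active_electrodes",
]

#: Canonical band edges in Hz, half-open [lo, hi).
DEFAULT_BANDS: Dict[str, Tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
    "hfo": (80.0, 600.0),
}


@dataclass
class Recording:
    """A multi-electrode voltage recording.

    data : (electrodes, samples) array, µV (arbitrary calibration)
    fs : sampling rate, Hz
    electrode_ids : unique integer ids, one per row
    condition : optional condition label (e.g. "CTL", "EV")
    t0 : recording start time, s
    fragment_labels : optional per-10-s-fragment ground-truth labels
        (set by the mixture generator; None for pure recordings)
    """

    data: np.ndarray
    fs: float
    electrode_ids: Optional[np.ndarray] = None
    condition: Optional[str] = None
    t0: float = 0.0
    fragment_labels: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (electrodes x samples) array")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaNs")
        if self.electrode_ids is None:
            self.electrode_ids = np.arange(self.data.shape[0])
        self.electrode_ids = np.asarray(self.electrode_ids)
        if len(np.unique(self.electrode_ids)) != len(self.electrode_ids):
            raise ValueError("electrode_ids must be unique")
        if len(self.electrode_ids) != self.data.shape[0]:
            raise ValueError("electrode_ids length must match data rows")

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class SpikeTrain:
    """Detected spike times per electrode, with the detection parameters."""

    times: Dict[int, np.ndarray]  # electrode id -> spike times (s)
    window_ms: float
    threshold_sd: float
    sd_estimate: Dict[int, float]  # electrode id -> full-trace SD

    def __post_init__(self) -> None:
        for eid, t in self.times.items():
            t = np.asarray(t, dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"spike times must be strictly increasing (electrode {eid})")
            self.times[eid] = t


@dataclass
class PowerSpectrogram:
    """Fragment-wise one-sided power densities per electrode.

    power : (electrodes, fragments, frequency bins), units²/Hz, >= 0
    freqs : bin centres, Hz
    fragment_starts : s, one per fragment
    """

    power: np.ndarray
    freqs: np.ndarray
    fragment_starts: np.ndarray
    electrode_ids: np.ndarray
    condition: Optional[str] = None
    fragment_labels: Optional[List[str]] = None


@dataclass
class BandSummary:
    """Mean power density per named band, (electrodes, fragments) each."""

    bands: Dict[str, Tuple[float, float]]
    power: Dict[str, np.ndarray]
    electrode_ids: np.ndarray


def detect_spikes(rec: Recording, window_ms: float = 10.0, threshold_sd: float = 5.5) -> SpikeTrain:
    """Threshold spike detection on |v| with a rolling merge window.

    Per electrode the SD is estimated on the full trace; samples whose
    absolute value exceeds ``threshold_sd * SD`` are candidate events, and
    candidates within one ``window_ms`` of a previously accepted event are
    merged into it (event time = first threshold crossing).
    """
    window_samples = max(1, round(window_ms * 1e-3 * rec.fs))
    if rec.data.shape[1] < window_samples:
        raise ValueError("recording must be at least one detection window long")
    times: Dict[int, np.ndarray] = {}
    sds: Dict[int, float] = {}
    for row, eid in enumerate(rec.electrode_ids):
        trace = rec.data[row]
        sd = float(np.std(trace))
        sds[int(eid)] = sd
        if sd == 0.0:
            warnings.warn(
                f"electrode {eid}: zero-variance trace, no spikes detectable",
                RuntimeWarning,
                stacklevel=2,
            )
            times[int(eid)] = np.empty(0)
            continue
        candidates = np.flatnonzero(np.abs(trace) > threshold_sd * sd)
        accepted = []
        last = -window_samples - 1
        for idx in candidates:
            if idx - last >= window_samples:
                accepted.append(idx)
                last = idx
        times[int(eid)] = np.asarray(accepted, dtype=float) / rec.fs + rec.t0
    return SpikeTrain(times=times, window_ms=window_ms, threshold_sd=threshold_sd, sd_estimate=sds)


def spike_counts(train: SpikeTrain) -> Dict[str, object]:
    """Per-electrode spike counts plus total, mean and SD across electrodes."""
    counts = {eid: len(t) for eid, t in train.times.items()}
    values = np.array(list(counts.values()), dtype=float)
    return {
        "per_electrode": counts,
        "total": int(values.sum()) if len(values) else 0,
        "mean": float(values.mean()) if len(values) else 0.0,
        "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
    }


def compute_power_density(
    rec: Recording,
    fragment_s: float = 10.0,
    fmin: float = 0.2,
    fmax: float = 300.0,
    df: float = 0.1,
) -> PowerSpectrogram:
    """Fragment-wise one-sided periodogram on the requested frequency grid.

    The recording is split into non-overlapping ``fragment_s`` windows
    (incomplete tails discarded); per fragment the mean is removed and a
    rectangular-window periodogram is computed, normalized by ``fs*N`` so
    that the density integrates to the fragment variance (Parseval). The
    native resolution of a 10-s fragment is exactly 0.1 Hz, so the requested
    grid must coincide with the native one.
    """
    frag_len = round(fragment_s * rec.fs)
    if abs(frag_len - fragment_s * rec.fs) > 1e-6:
        raise ValueError("fs * fragment_s must be an integer number of samples")
    if rec.data.shape[1] < frag_len:
        raise ValueError("recording is shorter than one fragment")
    if fmax > rec.fs / 2:
        raise ValueError("fmax exceeds the Nyquist frequency")
    native_df = rec.fs / frag_len
    if not np.isclose(df, native_df, rtol=1e-9):
        raise ValueError(
            f"requested df={df} Hz does not match the native fragment "
            f"resolution {native_df} Hz"
        )
    n_frag = rec.data.shape[1] // frag_len
    freqs_all = np.fft.rfftfreq(frag_len, 1.0 / rec.fs)
    i0 = int(round(fmin / native_df))
    i1 = int(round(fmax / native_df))
    freqs = freqs_all[i0 : i1 + 1]
    n_el = rec.n_electrodes
    power = np.empty((n_el, n_frag, len(freqs)))
    scale = 1.0 / (rec.fs * frag_len)
    for row in range(n_el):
        segs = rec.data[row, : n_frag * frag_len].reshape(n_frag, frag_len).astype(np.float64)
        segs -= segs.mean(axis=1, keepdims=True)
        spec = np.fft.rfft(segs, axis=1)
        psd = (spec.real**2 + spec.imag**2) * scale
        psd[:, 1:-1] *= 2.0  # one-sided: double all but DC and Nyquist
        power[row] = psd[:, i0 : i1 + 1]
    starts = rec.t0 + np.arange(n_frag) * fragment_s
    return PowerSpectrogram(
        power=power,
        freqs=freqs,
        fragment_starts=starts,
        electrode_ids=np.asarray(rec.electrode_ids),
        condition=rec.condition,
        fragment_labels=list(rec.fragment_labels) if rec.fragment_labels else None,
    )


def band_power(
    source: "PowerSpectrogram | Recording",
    bands: Optional[Mapping[str, Tuple[float, float]]] = None,
    fragment_s: float = 10.0,
) -> BandSummary:
    """Mean power density per band, per fragment and electrode.

    Band membership is half-open [lo, hi). When a band reaches beyond the
    spectrogram's frequency range (the HFO band extends to 600 Hz while the
    standard spectrogram stops at 300 Hz), pass a Recording: a second
    spectral pass up to the highest band edge is computed internally.
    """
    if bands is None:
        bands = DEFAULT_BANDS
    top = max(hi for _, hi in bands.values())
    if isinstance(source, Recording):
        if top > source.fs / 2:
            raise ValueError("band edge exceeds the Nyquist frequency")
        native_df = 1.0 / fragment_s
        spec = compute_power_density(source, fragment_s=fragment_s, fmin=native_df, fmax=top, df=native_df)
    else:
        spec = source
        if top > spec.freqs[-1] + 1e-9:
            raise ValueError(
                "band edge exceeds the spectrogram range; pass the Recording "
                "so a wider spectral pass can be computed"
            )
    power: Dict[str, np.ndarray] = {}
    for name, (lo, hi) in bands.items():
        sel = (spec.freqs >= lo) & (spec.freqs < hi)
        if not sel.any():
            raise ValueError(f"band {name} [{lo}, {hi}) contains no frequency bins")
        power[name] = spec.power[:, :, sel].mean(axis=2)
    return BandSummary(bands=dict(bands), power=power, electrode_ids=spec.electrode_ids)


def select_active_electrodes(rec: Recording, n: int = 20) -> List[int]:
    """Ids of the ``n`` most active electrodes (highest full-trace SD).

    Returned in descending SD order; ties broken by the lower electrode id.
    """
    if n > rec.n_electrodes:
        raise ValueError("cannot select more electrodes than the recording has")
    sds = rec.data.std(axis=1)
    order = np.lexsort((rec.electrode_ids, -sds))
    return [int(rec.electrode_ids[i]) for i in order[:n]]
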