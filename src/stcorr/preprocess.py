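"""Deterministic preprocessing from continuous EEG to epoched tensors.

The pipeline mirrors a conventional ERP/EEG workflow: zero-phase filtering of
the continuous recording (high-pass against DC drift, notches against line
noise), average re-referencing, epoching around stimulus events, and
amplitude baseline removal.  Ocular-artifact removal and automatic trial
rejection are exposed as pluggable hooks whose default is the identity, so
the stage order of a full pipeline is preserved even when those steps are
supplied externally.

Conventions
-----------
Epoch sample selection is half-open in time: an epoch window ``(t0, t1)`` in
ms keeps the samples ``k`` (relative to the event onset) with
``t0 <= 1000*k/fs < t1``.  At 512 Hz the default window (−700, 1000) ms thus
contains 870 samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "RawRecording",
    "EpochTensor",
    "EventTable",
    "filter_raw",
    "epoch",
    "baseline_correct",
    "rereference_average",
    "preprocess_pipeline",
    "read_raw_edf",
    "read_raw_brainvision",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class RawRecording:
    """Continuous multichannel recording: ``values`` is (n_channels, n_samples)."""

    values: np.ndarray
    sampling_rate: float
    ch_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raw values must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.ch_names:
            self.ch_names = [f"ch{i:03d}" for i in range(self.values.shape[0])]
        if len(self.ch_names) != self.values.shape[0]:
            raise ValueError("ch_names length must match channel axis")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class EpochTensor:
    """Epoched EEG: ``values`` is (n_channels, n_latencies, n_trials).

    ``tmin_ms`` is the latency of the first sample relative to the event
    onset; the latency axis advances in steps of ``1000 / sampling_rate``.
    """

    values: np.ndarray
    sampling_rate: float
    tmin_ms: float
    ch_names: list[str] = field(default_factory=list)
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("epoch values must be 3-D (channels x latency x trials)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("epoch values must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.ch_names:
            self.ch_names = [f"ch{i:03d}" for i in range(self.values.shape[0])]
        if len(self.ch_names) != self.values.shape[0]:
            raise ValueError("ch_names length must match channel axis")
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.values.shape[2])
        self.trial_ids = np.asarray(self.trial_ids)
        if self.trial_ids.shape[0] != self.values.shape[2]:
            raise ValueError("trial_ids length must match trial axis")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_latencies(self) -> int:
        return self.values.shape[1]

    @property
    def n_trials(self) -> int:
        return self.values.shape[2]

    @property
    def latencies_ms(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate
        return self.tmin_ms + step * np.arange(self.n_latencies)


class EventTable:
    """Per-event metadata: onset sample, condition, response (RT in ms), stimulus type.

    Backed by a :class:`pandas.DataFrame` with columns
    ``onset_sample, condition, rt_ms, stim_type``.  Onsets must be strictly
    increasing and response values positive where present.
    """

    COLUMNS = ("onset_sample", "condition", "rt_ms", "stim_type")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        onsets = frame["onset_sample"].to_numpy()
        if len(onsets) and np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        rt = frame["rt_ms"].to_numpy(dtype=float)
        if np.any(rt[np.isfinite(rt)] <= 0):
            raise ValueError("response values must be positive where present")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def onsets(self) -> np.ndarray:
        return self.frame["onset_sample"].to_numpy(dtype=int)

    @property
    def rt_ms(self) -> np.ndarray:
        return self.frame["rt_ms"].to_numpy(dtype=float)

    @classmethod
    def from_arrays(cls, onset_sample, rt_ms, condition="task", stim_type="target"):
        n = len(onset_sample)
        frame = pd.DataFrame(
            {
                "onset_sample": np.asarray(onset_sample, dtype=int),
                "condition": np.broadcast_to(np.asarray(condition, dtype=object), (n,)).copy(),
                "rt_ms": np.asarray(rt_ms, dtype=float),
                "stim_type": np.broadcast_to(np.asarray(stim_type, dtype=object), (n,)).copy(),
            }
        )
        return cls(frame)

    @classmethod
    def read_tsv(cls, path) -> "EventTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# raw readers (thin delegations to MNE)


def read_raw_edf(path) -> RawRecording:
    """Read an EDF(+) file into a :class:`RawRecording`."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return RawRecording(raw.get_data(), raw.info["sfreq"], list(raw.ch_names))


def read_raw_brainvision(path) -> RawRecording:
    """Read a BrainVision header (.vhdr) into a :class:`RawRecording`."""
    import mne

    raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    return RawRecording(raw.get_data(), raw.info["sfreq"], list(raw.ch_names))


# ---------------------------------------------------------------------------
# operations


def filter_raw(
    raw: RawRecording,
    highpass_hz: float = 1.5,
    notch_hz_list: tuple[float, ...] = (50.0, 100.0),
    order: int = 4,
    notch_q: float = 30.0,
) -> RawRecording:
    """Zero-phase high-pass plus notch filtering of a continuous recording.

    The high-pass is a Butterworth SOS applied forward-backward
    (``sosfiltfilt``); each notch is an IIR notch (``iirnotch``) applied
    forward-backward, so the cascade is zero-phase overall.
    """
    nyq = raw.sampling_rate / 2.0
    if highpass_hz is not None and highpass_hz >= nyq:
        raise ValueError(f"high-pass cutoff {highpass_hz} Hz >= Nyquist {nyq} Hz")
    for f0 in notch_hz_list or ():
        if f0 >= nyq:
            raise ValueError(f"notch frequency {f0} Hz >= Nyquist {nyq} Hz")

    data = raw.values
    if highpass_hz is not None and highpass_hz > 0:
        sos = signal.butter(order, highpass_hz, btype="highpass", fs=raw.sampling_rate, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=1)
    for f0 in notch_hz_list or ():
        b, a = signal.iirnotch(f0, Q=notch_q, fs=raw.sampling_rate)
        data = signal.filtfilt(b, a, data, axis=1)
    logger.info("filter_raw: highpass=%s Hz, notches=%s", highpass_hz, list(notch_hz_list or ()))
    return RawRecording(data, raw.sampling_rate, list(raw.ch_names))


def _window_sample_range(window_ms: tuple[float, float], fs: float) -> tuple[int, int]:
    """Relative sample indices [k0, k1) for a half-open ms window."""
    t0, t1 = window_ms
    if t1 <= t0:
        raise ValueError("epoch window must have t1 > t0")
    k0 = math.ceil(t0 * fs / 1000.0 - 1e-9)
    k1 = math.ceil(t1 * fs / 1000.0 - 1e-9)
    return k0, k1


def epoch(
    raw: RawRecording,
    events: EventTable,
    window_ms: tuple[float, float] = (-700.0, 1000.0),
) -> tuple[EpochTensor, EventTable]:
    """Cut trials around event onsets.

    Events whose window falls outside the recording are dropped with a
    logged count.  Returns the epoch tensor together with the event table
    restricted to the retained trials (so response values stay aligned).
    """
    fs = raw.sampling_rate
    k0, k1 = _window_sample_range(window_ms, fs)
    n_lat = k1 - k0
    onsets = events.onsets
    keep = (onsets + k0 >= 0) & (onsets + k1 <= raw.n_samples)
    n_drop = int(np.sum(~keep))
    if n_drop:
        logger.warning("epoch: dropped %d events with out-of-bounds windows", n_drop)
    kept = np.flatnonzero(keep)
    out = np.empty((raw.n_channels, n_lat, len(kept)))
    for j, ev in enumerate(kept):
        s = onsets[ev] + k0
        out[:, :, j] = raw.values[:, s : s + n_lat]
    tmin_ms = 1000.0 * k0 / fs
    tensor = EpochTensor(out, fs, tmin_ms, list(raw.ch_names), trial_ids=kept)
    kept_events = EventTable(events.frame.iloc[kept].reset_index(drop=True))
    return tensor, kept_events


def _latency_mask(epochs: EpochTensor, window_ms: tuple[float, float]) -> np.ndarray:
    lat = epochs.latencies_ms
    t0, t1 = window_ms
    return (lat >= t0 - 1e-9) & (lat < t1 - 1e-9)


def baseline_correct(
    epochs: EpochTensor, baseline_ms: tuple[float, float] = (-300.0, -100.0)
) -> EpochTensor:
    """Subtract the mean amplitude over the baseline interval per channel/trial."""
    mask = _latency_mask(epochs, baseline_ms)
    if not mask.any():
        raise ValueError(f"baseline window {baseline_ms} ms lies outside the epoch")
    base = epochs.values[:, mask, :].mean(axis=1, keepdims=True)
    return EpochTensor(
        epochs.values - base,
        epochs.sampling_rate,
        epochs.tmin_ms,
        list(epochs.ch_names),
        trial_ids=epochs.trial_ids,
    )


def rereference_average(data):
    """Subtract the instantaneous channel mean (common-average reference).

    Accepts either a :class:`RawRecording` (applied per sample) or an
    :class:`EpochTensor` (applied per latency/trial).  Idempotent; requires
    at least two channels.
    """
    if isinstance(data, RawRecording):
        if data.n_channels < 2:
            raise ValueError("average re-reference requires >= 2 channels")
        return RawRecording(
            data.values - data.values.mean(axis=0, keepdims=True),
            data.sampling_rate,
            list(data.ch_names),
        )
    if isinstance(data, EpochTensor):
        if data.n_channels < 2:
            raise ValueError("average re-reference requires >= 2 channels")
        return EpochTensor(
            data.values - data.values.mean(axis=0, keepdims=True),
            data.sampling_rate,
            data.tmin_ms,
            list(data.ch_names),
            trial_ids=data.trial_ids,
        )
    raise TypeError("expected RawRecording or EpochTensor")


def preprocess_pipeline(
    raw: RawRecording,
    events: EventTable,
    highpass_hz: float = 1.5,
    notch_hz_list: tuple[float, ...] = (50.0, 100.0),
    window_ms: tuple[float, float] = (-700.0, 1000.0),
    baseline_ms: tuple[float, float] = (-300.0, -100.0),
    ocular_hook=None,
    trial_reject_hook=None,
) -> tuple[EpochTensor, EventTable]:
    """Run the full stage order: filter → ocular hook → re-reference → epoch → baseline.

    ``ocular_hook`` (RawRecording → RawRecording) and ``trial_reject_hook``
    (EpochTensor, EventTable → EpochTensor, EventTable) default to identity;
    they exist so externally supplied artifact handling slots into the
    canonical position without reordering the pipeline.
    """
    logger.info("pipeline stage 1: filtering")
    raw = filter_raw(raw, highpass_hz, notch_hz_list)
    if ocular_hook is not None:
        logger.info("pipeline stage 2: ocular artifact hook")
        raw = ocular_hook(raw)
    else:
        logger.info("pipeline stage 2: ocular artifact hook (identity)")
    logger.info("pipeline stage 3: average re-reference")
    raw = rereference_average(raw)
    logger.info("pipeline stage 4: epoching %s ms", window_ms)
    epochs, kept = epoch(raw, events, window_ms)
    if trial_reject_hook is not None:
        logger.info("pipeline stage 5: trial rejection hook")
        epochs, kept = trial_reject_hook(epochs, kept)
    logger.info("pipeline stage 6: baseline correction %s ms", baseline_ms)
    epochs = baseline_correct(epochs, baseline_ms)
    return epochs, kept
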