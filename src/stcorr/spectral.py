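"""Morlet time-frequency decomposition and band-power dataset construction.

Each epoch channel is convolved with complex Morlet kernels

    phi_f(t) = alpha * exp(2*pi*i*f*t) * exp(-t^2 / (2*sigma^2)),

with ``sigma = cycles / (2*pi*f)`` and ``alpha`` fixed so each kernel has
unit L2 norm (making power comparable across frequencies).  Instantaneous
power is the squared magnitude of the complex coefficient.  A band-power
dataset collapses the frequency axis by taking, per channel/latency/trial,
the maximum power over the grid frequencies inside a named band, then
subtracting the mean of that collapsed power over a baseline trial set.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
from scipy import fft as spfft

from .preprocess import EpochTensor

__all__ = [
    "MorletSpec",
    "PowerTensor",
    "Band",
    "BandPowerDataset",
    "DEFAULT_BANDS",
    "morlet_kernel",
    "morlet_transform",
    "band_collapse",
    "band_power",
    "aggregate_subjects",
    "band_frequencies",
]


DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (5.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta1": (16.0, 22.0),
    "beta2": (23.0, 30.0),
    "gamma": (31.0, 40.0),
}
"""Standard EEG band intervals in Hz (closed intervals)."""


def band_frequencies(band: tuple[float, float]) -> np.ndarray:
    """1 Hz frequency grid covering a closed band interval."""
    lo, hi = band
    if hi < lo:
        raise ValueError("band interval must have hi >= lo")
    return np.arange(np.ceil(lo), np.floor(hi) + 0.5, 1.0)


@dataclass(frozen=True)
class MorletSpec:
    """Kernel family: center ``frequencies`` (Hz), Gaussian envelope width in
    ``cycles``, and the data ``sampling_rate`` (Hz)."""

    frequencies: tuple[float, ...]
    sampling_rate: float
    cycles: float = 3.0

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies)
        object.__setattr__(self, "frequencies", freqs)
        nyq = self.sampling_rate / 2.0
        if any(f <= 0 for f in freqs):
            raise ValueError("frequencies must be strictly positive")
        if any(f >= nyq for f in freqs):
            raise ValueError(f"frequencies must be below the Nyquist rate ({nyq} Hz)")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")

    def sigma_s(self, f: float) -> float:
        """Gaussian envelope standard deviation in seconds at frequency f."""
        return self.cycles / (2.0 * np.pi * f)


def morlet_kernel(f: float, spec: MorletSpec) -> np.ndarray:
    """Complex Morlet kernel at frequency ``f``, unit L2 norm, support ±5 sigma."""
    fs = spec.sampling_rate
    sigma = spec.sigma_s(f)
    half = int(np.ceil(5.0 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    kern = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2.0 * sigma**2))
    kern /= np.linalg.norm(kern)
    return kern


@dataclass
class PowerTensor:
    """Instantaneous power indexed (channel, latency, frequency, trial).

    ``edge_flags[t, f]`` marks latencies within ±2 sigma of the epoch edges
    for each kernel, where boundary zero-padding contaminates the estimate.
    """

    values: np.ndarray
    latencies_ms: np.ndarray
    frequencies: np.ndarray
    ch_names: list[str]
    trial_ids: np.ndarray
    edge_flags: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("power values must be 4-D (channel, latency, frequency, trial)")
        if np.any(self.values < 0):
            raise ValueError("power values must be nonnegative")
        c, t, f, n = self.values.shape
        if (
            len(self.ch_names) != c
            or len(self.latencies_ms) != t
            or len(self.frequencies) != f
            or len(self.trial_ids) != n
        ):
            raise ValueError("axis metadata lengths must match the array shape")


@dataclass(frozen=True)
class Band:
    """Named closed frequency interval in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.hi < self.lo:
            raise ValueError("band must have hi >= lo")

    @classmethod
    def named(cls, name: str) -> "Band":
        lo, hi = DEFAULT_BANDS[name]
        return cls(name, lo, hi)


@dataclass
class BandPowerDataset:
    """Band-collapsed, baseline-subtracted power: ``values`` is
    (channel, latency, trial).

    ``baseline_mean`` holds the subtracted per-(channel, latency) mean so the
    collapse is invertible; ``subjects`` records the per-trial subject of
    origin (used by :func:`aggregate_subjects`)."""

    values: np.ndarray
    band: Band
    latencies_ms: np.ndarray
    ch_names: list[str]
    baseline_mean: np.ndarray
    sampling_rate: float
    trial_ids: np.ndarray | None = None
    subjects: np.ndarray | None = None
    condition: str = ""
    edge_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("band power values must be 3-D (channel, latency, trial)")
        c, t, n = self.values.shape
        if len(self.ch_names) != c or len(self.latencies_ms) != t:
            raise ValueError("axis metadata lengths must match the array shape")
        if self.baseline_mean.shape != (c, t):
            raise ValueError("baseline_mean must be (channel, latency)")
        if self.trial_ids is None:
            self.trial_ids = np.arange(n)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.subjects is None:
            self.subjects = np.zeros(n, dtype=int)
        self.subjects = np.asarray(self.subjects)
        if len(self.trial_ids) != n or len(self.subjects) != n:
            raise ValueError("per-trial metadata lengths must match the trial axis")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[2]

    def subset_trials(self, idx: np.ndarray) -> "BandPowerDataset":
        """Dataset restricted to the given trial indices (order preserved)."""
        idx = np.asarray(idx)
        return BandPowerDataset(
            self.values[:, :, idx],
            self.band,
            self.latencies_ms,
            list(self.ch_names),
            self.baseline_mean,
            self.sampling_rate,
            trial_ids=self.trial_ids[idx],
            subjects=self.subjects[idx],
            condition=self.condition,
            edge_flags=self.edge_flags,
        )


def _power_iter(values: np.ndarray, spec: MorletSpec):
    """Yield (frequency, |Morlet coefficient|^2) per kernel frequency.

    Same-length output with zero-padded edges.  The convolution runs in the
    frequency domain; the forward FFT of the epochs is computed once and
    shared across kernels.
    """
    n_t = values.shape[1]
    kernels = [morlet_kernel(f, spec) for f in spec.frequencies]
    for f, kern in zip(spec.frequencies, kernels):
        if len(kern) > n_t:
            raise ValueError(
                f"epoch ({n_t} samples) shorter than kernel support at {f} Hz ({len(kern)} samples)"
            )
    n_fft = spfft.next_fast_len(n_t + max(len(k) for k in kernels) - 1, real=False)
    # time axis last for contiguous FFTs; trials chunked to bound the working set
    vt = np.ascontiguousarray(values.transpose(0, 2, 1))  # (C, N, T)
    chunk = max(1, int(2**22 // (vt.shape[0] * n_fft)))
    n_trials = vt.shape[1]
    fds = [
        spfft.fft(vt[:, s : s + chunk, :], n=n_fft, axis=-1)
        for s in range(0, n_trials, chunk)
    ]
    for f, kern in zip(spec.frequencies, kernels):
        fk = spfft.fft(kern, n=n_fft)
        half = (len(kern) - 1) // 2
        out = np.empty((values.shape[0], n_t, n_trials))
        for j, s in enumerate(range(0, n_trials, chunk)):
            conv = spfft.ifft(fds[j] * fk[None, None, :], axis=-1)
            blk = conv[:, :, half : half + n_t]
            out[:, :, s : s + blk.shape[1]] = np.abs(blk.transpose(0, 2, 1)) ** 2
        yield f, out


def _power_one_frequency(values: np.ndarray, f: float, spec: MorletSpec) -> np.ndarray:
    one = MorletSpec((f,), spec.sampling_rate, spec.cycles)
    return next(_power_iter(values, one))[1]


def morlet_transform(epochs: EpochTensor, spec: MorletSpec) -> PowerTensor:
    """Instantaneous power |F(c, t, f, n)|^2 for every channel/latency/frequency/trial."""
    if abs(spec.sampling_rate - epochs.sampling_rate) > 1e-9:
        raise ValueError("MorletSpec sampling_rate must match the epochs")
    c, t, n = epochs.values.shape
    freqs = np.asarray(spec.frequencies, dtype=float)
    out = np.empty((c, t, len(freqs), n))
    edge = np.zeros((t, len(freqs)), dtype=bool)
    lat_idx = np.arange(t)
    for j, (f, pw) in enumerate(_power_iter(epochs.values, spec)):
        out[:, :, j, :] = pw
        guard = int(np.ceil(2.0 * spec.sigma_s(f) * epochs.sampling_rate))
        edge[:, j] = (lat_idx < guard) | (lat_idx >= t - guard)
    return PowerTensor(
        out,
        epochs.latencies_ms,
        freqs,
        list(epochs.ch_names),
        epochs.trial_ids,
        edge,
        epochs.sampling_rate,
    )


def _resolve_baseline(n_trials: int, baseline) -> np.ndarray:
    if baseline is None:
        return np.arange(n_trials)
    idx = np.asarray(baseline)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if idx.size == 0:
        raise ValueError("baseline trial set must be nonempty")
    return idx


def band_collapse(
    power: PowerTensor,
    band: Band,
    baseline: np.ndarray | None = None,
    subjects: np.ndarray | None = None,
    condition: str = "",
) -> BandPowerDataset:
    """Collapse the frequency axis over a band and subtract the baseline mean.

    For each (channel, latency, trial) the collapsed value is the maximum of
    instantaneous power over the grid frequencies inside the closed band,
    minus the mean of that collapsed power over the ``baseline`` trial set
    (default: all trials).
    """
    sel = np.flatnonzero((power.frequencies >= band.lo - 1e-9) & (power.frequencies <= band.hi + 1e-9))
    if sel.size == 0:
        raise ValueError(f"band {band.name} [{band.lo}, {band.hi}] Hz contains no grid frequency")
    collapsed = power.values[:, :, sel, :].max(axis=2)
    base_idx = _resolve_baseline(power.values.shape[3], baseline)
    m = collapsed[:, :, base_idx].mean(axis=2)
    return BandPowerDataset(
        collapsed - m[:, :, None],
        band,
        power.latencies_ms,
        list(power.ch_names),
        m,
        power.sampling_rate,
        trial_ids=power.trial_ids,
        subjects=subjects,
        condition=condition,
        edge_flags=power.edge_flags[:, sel].any(axis=1),
    )


def band_power(
    epochs: EpochTensor,
    band: Band,
    cycles: float = 3.0,
    baseline: np.ndarray | None = None,
    subjects: np.ndarray | None = None,
    condition: str = "",
) -> BandPowerDataset:
    """Epochs → band-power dataset in one step, without materializing the full
    four-way power tensor (the frequency maximum is accumulated per kernel).
    """
    freqs = band_frequencies((band.lo, band.hi))
    spec = MorletSpec(tuple(freqs), epochs.sampling_rate, cycles)
    c, t, n = epochs.values.shape
    collapsed = np.full((c, t, n), -np.inf)
    edge = np.zeros(t, dtype=bool)
    lat_idx = np.arange(t)
    for f, pw in _power_iter(epochs.values, spec):
        np.maximum(collapsed, pw, out=collapsed)
        guard = int(np.ceil(2.0 * spec.sigma_s(f) * epochs.sampling_rate))
        edge |= (lat_idx < guard) | (lat_idx >= t - guard)
    base_idx = _resolve_baseline(n, baseline)
    m = collapsed[:, :, base_idx].mean(axis=2)
    return BandPowerDataset(
        collapsed - m[:, :, None],
        band,
        epochs.latencies_ms,
        list(epochs.ch_names),
        m,
        epochs.sampling_rate,
        trial_ids=epochs.trial_ids,
        subjects=subjects,
        condition=condition,
        edge_flags=edge,
    )


def aggregate_subjects(datasets: list[BandPowerDataset]) -> BandPowerDataset:
    """Concatenate band-power datasets along the trial axis.

    Channel and latency axes must match exactly; the per-trial subject of
    origin is recorded so any trial is retrievable by provenance.  A single
    dataset aggregates to itself.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    first = datasets[0]
    for d in datasets[1:]:
        if d.ch_names != first.ch_names:
            raise ValueError("channel axes differ between datasets")
        if len(d.latencies_ms) != len(first.latencies_ms) or not np.allclose(
            d.latencies_ms, first.latencies_ms
        ):
            raise ValueError("latency axes differ between datasets")
        if d.band != first.band:
            raise ValueError("bands differ between datasets")
    values = np.concatenate([d.values for d in datasets], axis=2)
    subjects = np.concatenate(
        [np.full(d.n_trials, j) if len(datasets) > 1 else d.subjects for j, d in enumerate(datasets)]
    )
    trial_ids = np.concatenate([d.trial_ids for d in datasets])
    base = np.mean([d.baseline_mean for d in datasets], axis=0)
    return BandPowerDataset(
        values,
        first.band,
        first.latencies_ms,
        list(first.ch_names),
        base,
        first.sampling_rate,
        trial_ids=trial_ids,
        subjects=subjects,
        condition=first.condition,
        edge_flags=first.edge_flags,
    )
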