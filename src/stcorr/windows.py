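"""Latency windows and the sliding-window grid.

A :class:`Window` is a half-open latency interval ``[start_ms, stop_ms)``;
a :class:`WindowSpec` describes the grid of equal-duration windows slid in
fixed increments across an epoch range (the training-window search space).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Window", "WindowSpec", "window_grid", "window_samples"]


@dataclass(frozen=True)
class Window:
    """Half-open latency interval in ms: [start_ms, stop_ms)."""

    start_ms: float
    stop_ms: float

    def __post_init__(self) -> None:
        if not self.stop_ms > self.start_ms:
            raise ValueError("window must have stop_ms > start_ms")

    @property
    def duration_ms(self) -> float:
        return self.stop_ms - self.start_ms

    @property
    def center_ms(self) -> float:
        return 0.5 * (self.start_ms + self.stop_ms)


@dataclass(frozen=True)
class WindowSpec:
    """Grid of sliding windows: ``duration_ms`` long, advancing by ``step_ms``
    inside ``[epoch_start_ms, epoch_stop_ms]``."""

    epoch_start_ms: float
    epoch_stop_ms: float
    duration_ms: float = 60.0
    step_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.step_ms <= 0:
            raise ValueError("step_ms must be positive")
        if self.epoch_stop_ms - self.epoch_start_ms < self.duration_ms:
            raise ValueError("epoch range shorter than window duration")


def window_grid(spec: WindowSpec) -> list[Window]:
    """All maximal windows of the stated duration/step inside the epoch range.

    Window starts are ``epoch_start, epoch_start + step, ...`` while
    ``start + duration <= epoch_stop`` (a 0–1000 ms range with 60 ms windows
    in 10 ms increments yields 95 windows starting at 0, 10, …, 940 ms).
    """
    span = spec.epoch_stop_ms - spec.epoch_start_ms - spec.duration_ms
    n = int(np.floor(span / spec.step_ms + 1e-9)) + 1
    starts = spec.epoch_start_ms + spec.step_ms * np.arange(max(n, 0))
    return [Window(float(s), float(s + spec.duration_ms)) for s in starts]


def window_samples(window: Window, latencies_ms: np.ndarray) -> np.ndarray:
    """Indices of latency samples falling in the half-open window.

    Raises if the window extends beyond the latency axis or contains no
    sample.
    """
    latencies_ms = np.asarray(latencies_ms, dtype=float)
    step = np.median(np.diff(latencies_ms)) if latencies_ms.size > 1 else np.inf
    if window.start_ms < latencies_ms[0] - 1e-9 or window.stop_ms > latencies_ms[-1] + step + 1e-9:
        raise ValueError(
            f"window [{window.start_ms}, {window.stop_ms}) ms outside latency axis "
            f"[{latencies_ms[0]}, {latencies_ms[-1]}] ms"
        )
    idx = np.flatnonzero((latencies_ms >= window.start_ms - 1e-9) & (latencies_ms < window.stop_ms - 1e-9))
    if idx.size == 0:
        raise ValueError("window contains no latency sample")
    return idx
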