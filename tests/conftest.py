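import numpy as np
import pytest

from stcorr import (
    Band,
    BandPowerDataset,
    ResponseVector,
    SyntheticSpec,
    Window,
    band_power,
    generate,
)


def make_band_dataset(values: np.ndarray, latencies_ms=None, band=None) -> BandPowerDataset:
    """Wrap a (channels, latency, trials) array as a BandPowerDataset."""
    values = np.asarray(values, dtype=float)
    c, t, _ = values.shape
    if latencies_ms is None:
        latencies_ms = 10.0 * np.arange(t)
    return BandPowerDataset(
        values,
        band or Band("alpha", 8.0, 12.0),
        np.asarray(latencies_ms, dtype=float),
        [f"ch{i:03d}" for i in range(c)],
        np.zeros((c, t)),
        100.0,
    )


def single_latency_design(rng: np.random.Generator, d: int, n: int):
    """Random one-latency dataset + response (Δt = 1 design)."""
    x = rng.standard_normal((d, 1, n))
    y = rng.standard_normal(n)
    data = make_band_dataset(x, latencies_ms=[0.0])
    return data, ResponseVector(y), Window(0.0, 10.0)


@pytest.fixture(scope="session")
def small_synthetic():
    """One small planted dataset shared across tests (8 ch, 120 trials)."""
    spec = SyntheticSpec(
        n_channels=8,
        n_trials=120,
        sampling_rate=64.0,
        epoch_ms=(-300.0, 700.0),
        source_window_ms=(240.0, 300.0),
        rho=0.6,
        seed=11,
    )
    epochs, events, truth = generate(spec)
    return spec, epochs, events, truth


@pytest.fixture(scope="session")
def small_band_data(small_synthetic):
    _, epochs, events, truth = small_synthetic
    data = band_power(epochs, Band.named("alpha"))
    return data, ResponseVector(events.rt_ms), truth
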