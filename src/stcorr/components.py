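"""Derived quantities from a fitted spatial filter.

* SCC — the single-trial correlated component z_n(t) = w' x_n(t), one
  amplitude time course per trial.
* CCT — the component correlation trace c(t): the across-trial Pearson
  correlation between z(t) and the behavioral response, per latency.
* Forward model — the per-channel coupling a = X z / (z'z) of the component,
  the quantity that is topographically interpretable (unlike w itself).
* Component map — the trials × latency SCC image with trials sorted by the
  response value.

Undefined correlations (zero projection variance at a latency) are recorded
as NaN, never silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimator import ResponseVector, SpatialFilter, UndefinedCorrelationError
from .spectral import BandPowerDataset
from .windows import Window, window_samples

__all__ = [
    "ComponentTimeSeries",
    "CorrelationTrace",
    "ForwardModel",
    "ComponentMap",
    "scc",
    "cct",
    "forward_model",
    "component_map",
]


@dataclass
class ComponentTimeSeries:
    """SCC amplitudes: ``values`` is (trials, latency); carries the filter's
    provenance (training window τ, band, λ)."""

    values: np.ndarray
    latencies_ms: np.ndarray
    tau: Window | None
    band: str
    lam: float
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("component values must be 2-D (trials x latency)")
        if self.values.shape[1] != len(self.latencies_ms):
            raise ValueError("latency axis must match the source dataset")
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.values.shape[0])


@dataclass
class CorrelationTrace:
    """Per-latency correlation c(t) between component amplitude and response.

    ``source`` labels the provenance of the trace ("train-cv" or "test").
    Values lie in [−1, 1] or are NaN where the correlation is undefined.
    """

    values: np.ndarray
    latencies_ms: np.ndarray
    source: str = "train-cv"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlation values must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"latency_ms": self.latencies_ms, "r": self.values})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ForwardModel:
    """Per-channel coupling of the component at an evaluation latency."""

    coupling: np.ndarray
    latency_ms: float
    ch_names: list[str] = field(default_factory=list)
    per_sample: np.ndarray | None = None  # (D, n_window_samples) when averaged

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float).ravel()
        if not np.all(np.isfinite(self.coupling)):
            raise ValueError("forward-model coupling must be finite")

    def to_frame(self) -> pd.DataFrame:
        names = self.ch_names or [f"ch{i:03d}" for i in range(len(self.coupling))]
        return pd.DataFrame({"channel": names, "coupling": self.coupling})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ComponentMap:
    """SCC image (trials × latency) with the trial axis sorted by ascending
    response value; ``order`` maps sorted rows back to original trials."""

    values: np.ndarray
    latencies_ms: np.ndarray
    response_sorted: np.ndarray
    order: np.ndarray
    tau: Window | None = None

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.response_sorted):
            raise ValueError("row count must match the response length")


def _check_channels(filt: SpatialFilter, band_data: BandPowerDataset) -> None:
    if len(filt.weights) != band_data.n_channels:
        raise ValueError("filter and dataset channel counts differ")
    if filt.ch_names and filt.ch_names != list(band_data.ch_names):
        raise ValueError("filter and dataset channel names differ")


def scc(filt: SpatialFilter, band_data: BandPowerDataset) -> ComponentTimeSeries:
    """Project every trial and latency through the filter: z_n(t) = w' x_n(t)."""
    _check_channels(filt, band_data)
    z = np.einsum("c,ctn->nt", filt.weights, band_data.values)
    return ComponentTimeSeries(
        z,
        band_data.latencies_ms,
        filt.tau,
        filt.band,
        filt.lam,
        trial_ids=band_data.trial_ids,
    )


def cct(
    filt: SpatialFilter,
    band_data: BandPowerDataset,
    response: ResponseVector,
    source: str = "train-cv",
) -> CorrelationTrace:
    """Across-trial Pearson correlation between z(t) and the response, per latency.

    Latencies with zero projection variance yield NaN.  A constant response
    makes every latency undefined and raises instead.
    """
    _check_channels(filt, band_data)
    if len(response) != band_data.n_trials:
        raise ValueError("response length must equal the trial count")
    yc = response.centered
    y_norm = np.linalg.norm(yc)
    if y_norm == 0:
        raise UndefinedCorrelationError("response has zero variance")
    z = np.einsum("c,ctn->tn", filt.weights, band_data.values)
    zc = z - z.mean(axis=1, keepdims=True)
    z_norm = np.linalg.norm(zc, axis=1)
    scale = np.max(z_norm) if z_norm.size else 0.0
    ok = z_norm > max(scale, 1.0) * 1e-12
    r = np.full(z.shape[0], np.nan)
    r[ok] = (zc[ok] @ yc) / (z_norm[ok] * y_norm)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationTrace(r, band_data.latencies_ms, source=source)


def forward_model(
    band_data: BandPowerDataset,
    component: ComponentTimeSeries,
    latency_ms: float | None = None,
    average_window: bool = True,
) -> ForwardModel:
    """Recover the per-channel coupling a = X z / (z'z).

    With ``latency_ms`` given, the model is evaluated at the single nearest
    latency sample.  Otherwise it is evaluated at every sample of the
    filter's training window τ and, when ``average_window`` is true, the
    per-sample couplings are averaged (the per-sample matrix is retained in
    ``per_sample``).
    """
    if component.values.shape[0] != band_data.n_trials:
        raise ValueError("component and dataset trial counts differ")
    lat = band_data.latencies_ms
    if latency_ms is not None:
        idx = np.array([int(np.argmin(np.abs(lat - latency_ms)))])
    else:
        if component.tau is None:
            raise ValueError("component has no training window; pass latency_ms")
        idx = window_samples(component.tau, lat)

    couplings = np.empty((band_data.n_channels, len(idx)))
    for j, t in enumerate(idx):
        z = component.values[:, t]
        denom = float(z @ z)
        if denom <= 0:
            raise ValueError(f"component has zero norm at latency {lat[t]:.1f} ms")
        couplings[:, j] = (band_data.values[:, t, :] @ z) / denom

    eval_latency = float(np.mean(lat[idx]))
    if len(idx) == 1 or not average_window:
        return ForwardModel(
            couplings[:, 0] if len(idx) == 1 else couplings.mean(axis=1),
            eval_latency,
            list(band_data.ch_names),
            per_sample=couplings,
        )
    return ForwardModel(
        couplings.mean(axis=1), eval_latency, list(band_data.ch_names), per_sample=couplings
    )


def component_map(component: ComponentTimeSeries, response: ResponseVector) -> ComponentMap:
    """Sort trials by ascending response value (ties keep original order)."""
    if component.values.shape[0] != len(response):
        raise ValueError("component and response lengths differ")
    order = np.argsort(response.values, kind="stable")
    return ComponentMap(
        component.values[order],
        component.latencies_ms,
        response.values[order],
        order,
        tau=component.tau,
    )


def plot_component_map(cmap: ComponentMap, path=None, ax=None):
    """Heatmap of a component map; the τ window is marked by vertical lines."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 4))
    else:
        fig = ax.figure
    lat = cmap.latencies_ms
    ax.imshow(
        cmap.values,
        aspect="auto",
        origin="upper",
        extent=(lat[0], lat[-1], cmap.values.shape[0], 0),
        cmap="RdBu_r",
    )
    if cmap.tau is not None:
        ax.axvline(cmap.tau.start_ms, color="b", lw=1.5)
        ax.axvline(cmap.tau.stop_ms, color="b", lw=1.5)
    ax.set_xlabel("latency (ms)")
    ax.set_ylabel("trials (sorted by response)")
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return ax
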