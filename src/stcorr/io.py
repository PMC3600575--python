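"""HDF5 persistence for epoch/power containers and YAML analysis configs."""

from __future__ import annotations

import numpy as np
import yaml

from .preprocess import EpochTensor
from .spectral import Band, BandPowerDataset, PowerTensor
from .windows import WindowSpec

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_band_power",
    "load_band_power",
    "save_power_tensor",
    "load_power_tensor",
    "load_config",
]


def _write_strings(group, name, items) -> None:
    import h5py

    group.create_dataset(name, data=np.asarray(list(items), dtype=h5py.string_dtype()))


def _read_strings(group, name) -> list[str]:
    return [s.decode() if isinstance(s, bytes) else str(s) for s in group[name][()]]


def save_epochs(path, epochs: EpochTensor) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        g = fh.create_group("epochs")
        g.create_dataset("values", data=epochs.values)
        g.attrs["sampling_rate"] = epochs.sampling_rate
        g.attrs["tmin_ms"] = epochs.tmin_ms
        _write_strings(g, "ch_names", epochs.ch_names)
        g.create_dataset("trial_ids", data=np.asarray(epochs.trial_ids))


def load_epochs(path) -> EpochTensor:
    import h5py

    with h5py.File(path, "r") as fh:
        g = fh["epochs"]
        return EpochTensor(
            g["values"][()],
            float(g.attrs["sampling_rate"]),
            float(g.attrs["tmin_ms"]),
            _read_strings(g, "ch_names"),
            trial_ids=g["trial_ids"][()],
        )


def save_power_tensor(path, power: PowerTensor) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        g = fh.create_group("power")
        g.create_dataset("values", data=power.values)
        g.create_dataset("latencies_ms", data=power.latencies_ms)
        g.create_dataset("frequencies", data=power.frequencies)
        g.create_dataset("trial_ids", data=np.asarray(power.trial_ids))
        g.create_dataset("edge_flags", data=power.edge_flags)
        g.attrs["sampling_rate"] = power.sampling_rate
        _write_strings(g, "ch_names", power.ch_names)


def load_power_tensor(path) -> PowerTensor:
    import h5py

    with h5py.File(path, "r") as fh:
        g = fh["power"]
        return PowerTensor(
            g["values"][()],
            g["latencies_ms"][()],
            g["frequencies"][()],
            _read_strings(g, "ch_names"),
            g["trial_ids"][()],
            g["edge_flags"][()],
            float(g.attrs["sampling_rate"]),
        )


def save_band_power(path, data: BandPowerDataset) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        g = fh.create_group("band_power")
        g.create_dataset("values", data=data.values)
        g.create_dataset("latencies_ms", data=data.latencies_ms)
        g.create_dataset("baseline_mean", data=data.baseline_mean)
        g.create_dataset("trial_ids", data=np.asarray(data.trial_ids))
        g.create_dataset("subjects", data=np.asarray(data.subjects))
        if data.edge_flags is not None:
            g.create_dataset("edge_flags", data=data.edge_flags)
        g.attrs["sampling_rate"] = data.sampling_rate
        g.attrs["band_name"] = data.band.name
        g.attrs["band_lo"] = data.band.lo
        g.attrs["band_hi"] = data.band.hi
        g.attrs["condition"] = data.condition
        _write_strings(g, "ch_names", data.ch_names)


def load_band_power(path) -> BandPowerDataset:
    import h5py

    with h5py.File(path, "r") as fh:
        g = fh["band_power"]
        return BandPowerDataset(
            g["values"][()],
            Band(str(g.attrs["band_name"]), float(g.attrs["band_lo"]), float(g.attrs["band_hi"])),
            g["latencies_ms"][()],
            _read_strings(g, "ch_names"),
            g["baseline_mean"][()],
            float(g.attrs["sampling_rate"]),
            trial_ids=g["trial_ids"][()],
            subjects=g["subjects"][()],
            condition=str(g.attrs["condition"]),
            edge_flags=g["edge_flags"][()] if "edge_flags" in g else None,
        )


def load_config(path) -> dict:
    """Load a YAML analysis config.

    Recognized sections: ``bands`` (name → [lo, hi] Hz), ``window`` (epoch
    start/stop, duration, step in ms), ``cv`` (k_folds, inner_folds,
    lambda_grid), ``permutation`` (n_perm, q, reselect_lambda), ``seed``.
    Returns a plain dict with a parsed ``WindowSpec`` under "window_spec"
    and Band objects under "bands" when those sections are present.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = dict(raw)
    if "bands" in raw:
        out["bands"] = {name: Band(name, float(lo), float(hi)) for name, (lo, hi) in raw["bands"].items()}
    if "window" in raw:
        w = raw["window"]
        out["window_spec"] = WindowSpec(
            float(w["epoch_start_ms"]),
            float(w["epoch_stop_ms"]),
            float(w.get("duration_ms", 60.0)),
            float(w.get("step_ms", 10.0)),
        )
    return out
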