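"""Spike raster and voltage trace containers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SpikeRaster:
    """Spike times for a set of trials.

    ``trial``, ``neuron`` and ``time`` are parallel arrays, sorted by
    (trial, neuron, time).  Times are ms relative to trial start;
    ``record_window`` is the (start, stop) of the recorded period within
    a trial and every stored spike lies inside it.
    """

    trial: np.ndarray
    neuron: np.ndarray
    time: np.ndarray
    n_trials: int
    n_neurons: int
    record_window: tuple[float, float]

    def __post_init__(self) -> None:
        order = np.lexsort((self.time, self.neuron, self.trial))
        self.trial = np.asarray(self.trial, dtype=np.int64)[order]
        self.neuron = np.asarray(self.neuron, dtype=np.int64)[order]
        self.time = np.asarray(self.time, dtype=np.float64)[order]

    @property
    def n_spikes(self) -> int:
        return self.time.size

    @property
    def record_duration(self) -> float:
        return self.record_window[1] - self.record_window[0]

    def spike_times(self, trial: int, neuron: int) -> np.ndarray:
        mask = (self.trial == trial) & (self.neuron == neuron)
        return self.time[mask]

    def counts(self) -> np.ndarray:
        """(n_trials, n_neurons) spike-count matrix."""
        out = np.zeros((self.n_trials, self.n_neurons), dtype=np.int64)
        np.add.at(out, (self.trial, self.neuron), 1)
        return out

    def total_counts(self) -> np.ndarray:
        return self.counts().sum(axis=0)

    def active_neurons(self) -> np.ndarray:
        """Indices of neurons with at least one spike."""
        return np.unique(self.neuron)

    def binned(self, bin_ms: float) -> np.ndarray:
        """(n_trials, n_neurons, n_bins) spike counts in fixed bins."""
        t0, t1 = self.record_window
        n_bins = int(round((t1 - t0) / bin_ms))
        idx = np.floor((self.time - t0) / bin_ms).astype(np.int64)
        idx = np.clip(idx, 0, n_bins - 1)
        out = np.zeros((self.n_trials, self.n_neurons, n_bins),
                       dtype=np.int64)
        np.add.at(out, (self.trial, self.neuron, idx), 1)
        return out

    def subset_neurons(self, neurons: np.ndarray) -> "SpikeRaster":
        """Raster restricted (and re-indexed) to the given neuron ids."""
        neurons = np.asarray(neurons)
        lookup = -np.ones(self.n_neurons, dtype=np.int64)
        lookup[neurons] = np.arange(neurons.size)
        keep = lookup[self.neuron] >= 0
        return SpikeRaster(self.trial[keep], lookup[self.neuron[keep]],
                           self.time[keep], self.n_trials, neurons.size,
                           self.record_window)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"trial": self.trial, "neuron": self.neuron,
                             "time_ms": self.time})

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_arrays(cls, trial, neuron, time, n_trials, n_neurons,
                    record_window) -> "SpikeRaster":
        return cls(np.asarray(trial), np.asarray(neuron), np.asarray(time),
                   n_trials, n_neurons, record_window)


def load_raster_csv(path, n_trials, n_neurons, record_window) -> SpikeRaster:
    import pandas as pd

    df = pd.read_csv(path)
    return SpikeRaster(df["trial"].to_numpy(), df["neuron"].to_numpy(),
                       df["time_ms"].to_numpy(), n_trials, n_neurons,
                       record_window)


@dataclass
class VoltageTraces:
    """Membrane-potential samples for the excitatory population.

    ``V`` has shape (n_trials, n_samples, n_neurons) and holds the
    potential at the end of each sampling interval during the recorded
    window, in mV.  Samples taken while a neuron is in its post-spike
    reset/refractory state carry the reset value.
    """

    V: np.ndarray
    sample_interval: float
    record_window: tuple[float, float]

    @property
    def n_trials(self) -> int:
        return self.V.shape[0]

    @property
    def n_samples(self) -> int:
        return self.V.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.V.shape[2]

    def sample_times(self) -> np.ndarray:
        """Times (ms, relative to trial start) of each voltage sample."""
        t0 = self.record_window[0]
        return t0 + self.sample_interval * (1 + np.arange(self.n_samples))
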