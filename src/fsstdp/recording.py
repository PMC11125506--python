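"""Run records, HDF5 persistence, and deterministic random streams."""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import __version__
from .plasticity import SynapsePopulation

__all__ = ["SimulationRecord", "save_record", "load_record", "new_rng"]


@dataclass
class SimulationRecord:
    """Snapshots of a network simulation.

    ``times`` are evenly spaced recording instants (seconds, starting at 0);
    ``w`` and ``mu`` hold one row per instant.  ``config`` echoes the
    configuration that produced the run, so every persisted artifact is
    self-describing.
    """

    times: np.ndarray
    w: np.ndarray
    mu: np.ndarray
    post_spike_times: np.ndarray
    config: dict = field(default_factory=dict)
    version: str = __version__
    final_pop: Optional[SynapsePopulation] = None

    @property
    def n_synapses(self) -> int:
        return self.w.shape[1]

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def final_w(self) -> np.ndarray:
        return self.w[-1]

    def final_mu(self) -> np.ndarray:
        return self.mu[-1]

    def mean_post_rate(self, t_from: float = 0.0, t_to: Optional[float] = None) -> float:
        """Average postsynaptic firing rate (Hz) over [t_from, t_to)."""
        t_to = self.duration if t_to is None else t_to
        if t_to <= t_from:
            raise ValueError("need t_to > t_from")
        n = np.count_nonzero(
            (self.post_spike_times >= t_from) & (self.post_spike_times < t_to)
        )
        return n / (t_to - t_from)

    def post_spikes_to_text(self, path) -> None:
        np.savetxt(path, self.post_spike_times, fmt="%.10g", header="spike_time_s")

    def trajectories_to_csv(self, path, which: str = "w") -> None:
        """Export the weight ("w") or spineness ("mu") trajectory as CSV,
        one row per recording instant, one column per synapse."""
        import pandas as pd

        data = {"w": self.w, "mu": self.mu}[which]
        df = pd.DataFrame(data, columns=[f"syn{i}" for i in range(data.shape[1])])
        df.insert(0, "time_s", self.times)
        df.to_csv(path, index=False)

    def __eq__(self, other) -> bool:  # stream state / final_pop excluded
        if not isinstance(other, SimulationRecord):
            return NotImplemented
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.w, other.w)
            and np.array_equal(self.mu, other.mu)
            and np.array_equal(self.post_spike_times, other.post_spike_times)
            and self.config == other.config
        )


def save_record(record: SimulationRecord, path) -> None:
    """Persist a record to HDF5 (layout: /synapses/{w,mu}, /neuron/spikes)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(record.config, sort_keys=True)
        f.attrs["version"] = record.version
        f.create_dataset("times", data=record.times)
        syn = f.create_group("synapses")
        syn.create_dataset("w", data=record.w)
        syn.create_dataset("mu", data=record.mu)
        f.create_group("neuron").create_dataset(
            "spikes", data=record.post_spike_times
        )


def load_record(path) -> SimulationRecord:
    import h5py

    with h5py.File(path, "r") as f:
        return SimulationRecord(
            times=f["times"][...],
            w=f["synapses/w"][...],
            mu=f["synapses/mu"][...],
            post_spike_times=f["neuron/spikes"][...],
            config=json.loads(f.attrs["config"]),
            version=str(f.attrs["version"]),
        )


def new_rng(seed: int, stream: str = "") -> np.random.Generator:
    """Independent, reproducible random stream per (seed, stream label).

    Distinct labels under the same seed yield statistically independent
    generators (distinct SeedSequence spawn keys); the same pair always
    reproduces the same draws.
    """
    label_key = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), label_key]))
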