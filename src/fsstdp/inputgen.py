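"""Correlation structures and correlated Poisson spike rasters.

A *correlation structure* assigns each excitatory presynaptic neuron a
correlation strength ``c_i`` in [0, 1].  Spike trains are generated by the
reference-train construction: a homogeneous Bernoulli reference train is
drawn at the target rate, and each neuron copies reference bins with mixing
probability ``c_i``:

    P(spike | ref bin)    = r*dt + c_i * (1 - r*dt)
    P(spike | no ref bin) = r*dt * (1 - c_i)

This leaves every marginal rate exactly ``r`` while imposing zero-lag
pairwise bin correlations ``corr(X_i, X_j) = c_i * c_j`` (rank-1 family).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationStructure",
    "SpikeRaster",
    "make_von_mises",
    "make_squared_pulse",
    "make_gaussian",
    "rotate",
    "sample_spikes",
]


@dataclass(frozen=True)
class CorrelationStructure:
    """Per-neuron correlation strengths with generating metadata.

    Attributes
    ----------
    c : ndarray
        Correlation strengths, one per excitatory presynaptic neuron,
        each in [0, 1].
    kind : str
        One of ``von_mises``, ``squared_pulse``, ``gaussian``.
    theta_pref : float or None
        Preferred angle in radians (angle-indexed kinds only).
    kappa : float or None
        von Mises concentration.
    c_tot : float
        Total correlation, ``sum(c)``.
    n_tot : int or None
        Number of correlated neurons (squared-pulse only).
    """

    c: np.ndarray
    kind: str
    theta_pref: Optional[float] = None
    kappa: Optional[float] = None
    c_tot: float = 0.0
    n_tot: Optional[int] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "c", c)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("c must be a non-empty 1-D vector")
        if np.any(c < 0) or np.any(c > 1):
            raise ValueError("all correlation strengths must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.c.size

    @property
    def angles(self) -> np.ndarray:
        """Evenly spaced neuron angles on [0, 2*pi)."""
        return 2.0 * np.pi * np.arange(self.n) / self.n

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"index": np.arange(self.n), "angle": self.angles, "c": self.c}
        ).to_csv(path, index=False)


def make_von_mises(
    n: int, theta_pref: float, kappa: float, c_tot: float
) -> CorrelationStructure:
    """Von Mises shaped correlation structure.

    Neurons receive evenly spaced angles on [0, 2*pi); each gets
    ``c_i`` proportional to the von Mises density at its angle, rescaled so
    that ``sum(c_i) = c_tot``.
    """
    if n < 2:
        raise ValueError("need at least two neurons")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if c_tot <= 0:
        raise ValueError("c_tot must be positive")
    theta = 2.0 * np.pi * np.arange(n) / n
    density = stats.vonmises.pdf(theta, kappa, loc=theta_pref)
    c = density * (c_tot / density.sum())
    if np.any(c > 1.0 + 1e-12):
        raise ValueError(
            f"c_tot={c_tot} too large for kappa={kappa}, n={n}: "
            f"max c_i would be {c.max():.4f} > 1"
        )
    c = np.clip(c, 0.0, 1.0)
    return CorrelationStructure(
        c=c, kind="von_mises", theta_pref=float(theta_pref), kappa=float(kappa),
        c_tot=float(c_tot),
    )


def make_squared_pulse(
    n: int, n_tot: int, c_tot: float, offset: int = 0
) -> CorrelationStructure:
    """Squared-pulse structure: ``n_tot`` neurons share ``c_tot/n_tot``, rest 0.

    The correlated block is contiguous, starting at ``offset`` (wraps around).
    """
    if not 0 < n_tot <= n:
        raise ValueError("need 0 < n_tot <= n")
    ci = c_tot / n_tot
    if ci > 1.0 + 1e-12:
        raise ValueError(f"c_tot/n_tot = {ci:.4f} exceeds 1")
    c = np.zeros(n)
    idx = (np.arange(n_tot) + offset) % n
    c[idx] = min(ci, 1.0)
    return CorrelationStructure(
        c=c, kind="squared_pulse", c_tot=float(c_tot), n_tot=int(n_tot)
    )


def make_gaussian(
    n: int, mean: float, sd: float, c_tot: float, seed: int
) -> CorrelationStructure:
    """Gaussian-sampled structure: clip negatives at 0, then rescale to c_tot."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    raw = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, float(mean))
    raw = np.clip(raw, 0.0, None)
    total = raw.sum()
    if total <= 0:
        raise ValueError("all sampled correlations clipped to zero; cannot normalize")
    c = raw * (c_tot / total)
    if np.any(c > 1.0 + 1e-12):
        raise ValueError("rescaled correlation strengths exceed 1")
    c = np.clip(c, 0.0, 1.0)
    return CorrelationStructure(c=c, kind="gaussian", c_tot=float(c_tot))


def rotate(structure: CorrelationStructure, delta_theta: float) -> CorrelationStructure:
    """Rotate an angle-indexed structure by ``delta_theta`` radians.

    Implemented as a circular shift by the nearest whole number of grid
    positions; the total correlation is preserved exactly.
    """
    if structure.kind != "von_mises":
        raise ValueError("rotation is defined for angle-indexed (von_mises) structures")
    n = structure.n
    shift = int(np.round(delta_theta * n / (2.0 * np.pi))) % n
    new_pref = (structure.theta_pref + 2.0 * np.pi * shift / n) % (2.0 * np.pi)
    return replace(structure, c=np.roll(structure.c, shift), theta_pref=new_pref)


@dataclass
class SpikeRaster:
    """Binned spike occupancy for a population of Poisson neurons.

    Bins are half-open ``[k*dt, (k+1)*dt)``; the spike time of bin ``k`` is
    ``k*dt``.  At most one spike per neuron per bin (Bernoulli construction).
    """

    bins: np.ndarray  # (n_bins, n_neurons) bool
    dt: float
    rate_target: float

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=bool)
        if self.bins.ndim != 2:
            raise ValueError("bins must be 2-D (n_bins, n_neurons)")

    @property
    def n_neurons(self) -> int:
        return self.bins.shape[1]

    @property
    def n_bins(self) -> int:
        return self.bins.shape[0]

    @property
    def duration(self) -> float:
        return self.n_bins * self.dt

    def spike_times(self, neuron: int) -> np.ndarray:
        return np.nonzero(self.bins[:, neuron])[0] * self.dt

    def empirical_rates(self) -> np.ndarray:
        return self.bins.sum(axis=0) / self.duration

    # -- plain-text and HDF5 export -------------------------------------
    def to_text(self, path) -> None:
        """Two-column plain text: neuron_id, spike_time_s."""
        rows, cols = np.nonzero(self.bins)
        out = np.column_stack([cols.astype(float), rows * self.dt])
        order = np.lexsort((out[:, 1], out[:, 0]))
        np.savetxt(path, out[order], fmt=["%d", "%.10g"], header="neuron_id spike_time_s")

    @classmethod
    def from_text(cls, path, n_neurons: int, dt: float, duration: float,
                  rate_target: float = 0.0) -> "SpikeRaster":
        data = np.loadtxt(path, ndmin=2)
        n_bins = int(round(duration / dt))
        bins = np.zeros((n_bins, n_neurons), dtype=bool)
        if data.size:
            neuron = data[:, 0].astype(int)
            k = np.round(data[:, 1] / dt).astype(int)
            bins[k, neuron] = True
        return cls(bins=bins, dt=dt, rate_target=rate_target)

    def to_hdf5(self, h5group) -> None:
        h5group.create_dataset("bins", data=self.bins, compression=None)
        h5group.attrs["dt"] = self.dt
        h5group.attrs["duration"] = self.duration
        h5group.attrs["rate_target"] = self.rate_target

    @classmethod
    def from_hdf5(cls, h5group) -> "SpikeRaster":
        return cls(
            bins=h5group["bins"][...],
            dt=float(h5group.attrs["dt"]),
            rate_target=float(h5group.attrs["rate_target"]),
        )


def sample_spikes(
    structure: CorrelationStructure,
    rate: float,
    dt: float,
    duration: float,
    seed,
) -> SpikeRaster:
    """Sample a correlated Poisson raster for one structure.

    ``seed`` may be an int or a ``numpy.random.Generator``.  A fresh
    reference train is drawn and every neuron fires conditionally on it,
    independently across neurons given the reference.
    """
    m = rate * dt
    if m >= 1.0:
        raise ValueError("rate*dt must be < 1 for the Bernoulli construction")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_bins = int(round(duration / dt))
    bins = sample_spike_bins(structure.c, m, n_bins, rng)
    return SpikeRaster(bins=bins, dt=dt, rate_target=rate)


def sample_spike_bins(
    c: np.ndarray, m: float, n_bins: int, rng: np.random.Generator
) -> np.ndarray:
    """Low-level sampler returning a (n_bins, n) boolean array.

    Used both by :func:`sample_spikes` and by the chunked simulation loop.
    """
    ref = rng.random(n_bins) < m
    u = rng.random((n_bins, c.size))
    spikes = u < m * (1.0 - c)
    spikes[ref] = u[ref] < m + c * (1.0 - m)
    return spikes
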