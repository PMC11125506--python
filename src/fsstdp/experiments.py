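"""Stimulation protocols: receptive-field formation, consolidation,
discrimination testing, and parameter sweeps.

All protocols wire the input generator, the LIF neuron and the plasticity
rule through :func:`fsstdp.simulate.run_network` and summarize the outcome
with the metrics module.  Every entry point is deterministic given its
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .inputgen import CorrelationStructure, make_von_mises, rotate
from .metrics import (
    classify_regime,
    discrimination_index,
    label_synapses,
    memory_overlap,
    pearson_r,
)
from .neuron import NeuronParams
from .plasticity import PlasticityParams, SynapsePopulation
from .recording import SimulationRecord, new_rng
from .simulate import Phase, SimParams, run_network

__all__ = [
    "ProtocolSpec",
    "RFSummary",
    "run_rf_formation",
    "run_consolidation",
    "run_di_protocol",
    "run_sweep",
    "mean_spine_mu",
]

TRAIN_RATE = 30.0  # presynaptic rate during training, Hz
TEST_RATE = 10.0   # presynaptic rate during discrimination testing, Hz


@dataclass(frozen=True)
class ProtocolSpec:
    """An ordered list of stimulation phases plus rule and bookkeeping."""

    phases: Tuple[Phase, ...]
    pparams: PlasticityParams = PlasticityParams()
    nparams: NeuronParams = NeuronParams()
    sim: SimParams = SimParams()
    seed: int = 0
    label_window: float = 10.0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("need at least one phase")
        object.__setattr__(self, "phases", tuple(self.phases))


@dataclass
class RFSummary:
    """Summary measures of a formed receptive field."""

    labels: Optional[np.ndarray] = None  # True = spine
    r: Optional[float] = None
    di: Optional[float] = None
    overlap_a: Optional[float] = None
    overlap_b: Optional[float] = None
    regime: Optional[str] = None


def formation_spec(
    structure: CorrelationStructure,
    duration: float = 200.0,
    pparams: Optional[PlasticityParams] = None,
    seed: int = 0,
    **kwargs,
) -> ProtocolSpec:
    """Single-phase training protocol at the default training rate."""
    return ProtocolSpec(
        phases=(Phase(structure, TRAIN_RATE, duration, plastic=True),),
        pparams=pparams or PlasticityParams(),
        seed=seed,
        **kwargs,
    )


def run_rf_formation(spec: ProtocolSpec) -> Tuple[SimulationRecord, RFSummary]:
    """Train the network on the protocol and summarize the formed RF.

    The Pearson correlation ``r`` is computed over spine-labeled synapses
    (final-window mean weight at or above the lower soft bound); it is left
    as None when fewer than three spines formed or the spine weights are
    degenerate.
    """
    record = run_network(
        spec.phases, spec.pparams, spec.nparams, spec.sim, spec.seed
    )
    labels = label_synapses(
        record.w, record.times, spec.pparams.w0_minus, spec.label_window
    )
    summary = RFSummary(labels=labels)
    c = spec.phases[-1].structure.c
    w_final = record.final_w()
    if labels.sum() >= 3:
        try:
            summary.r = pearson_r(w_final[labels], c[labels])
        except ValueError:
            summary.r = None
    return record, summary


def mean_spine_mu(record: SimulationRecord, pparams: PlasticityParams,
                  window: float = 10.0) -> float:
    """Average final spineness over spine-labeled synapses."""
    labels = label_synapses(record.w, record.times, pparams.w0_minus, window)
    if not labels.any():
        raise ValueError("no spines formed; mean spine mu undefined")
    return float(record.final_mu()[labels].mean())


def run_consolidation(
    structure_a: CorrelationStructure,
    structure_b: CorrelationStructure,
    pparams: Optional[PlasticityParams] = None,
    nparams: Optional[NeuronParams] = None,
    sim: Optional[SimParams] = None,
    duration_a: float = 200.0,
    duration_b: float = 400.0,
    seed: int = 0,
    threshold: float = 0.5,
) -> RFSummary:
    """Pattern A -> pattern B protocol with A-alone and B-alone references.

    Trains on A for ``duration_a`` seconds and continues on B for
    ``duration_b`` seconds.  The A-alone reference RF is the state of that
    same run at the end of phase A (training on A alone for ``duration_a``
    is exactly the protocol prefix); the B-alone reference is formed in a
    separate run from the homogeneous initial state.  The overlaps of the
    A-then-B weight vector with each reference classify the run as
    total/partial/no overwriting (or unformed).
    """
    pparams = pparams or PlasticityParams()
    nparams = nparams or NeuronParams()
    sim = sim or SimParams()
    phases_ab = (
        Phase(structure_a, TRAIN_RATE, duration_a),
        Phase(structure_b, TRAIN_RATE, duration_b),
    )
    rec_ab = run_network(phases_ab, pparams, nparams, sim, new_rng(seed, "ab"))
    rec_b = run_network(
        (Phase(structure_b, TRAIN_RATE, duration_b),),
        pparams, nparams, sim, new_rng(seed, "b"),
    )
    i_a = int(np.argmin(np.abs(rec_ab.times - duration_a)))
    w_ab, w_a, w_b = rec_ab.final_w(), rec_ab.w[i_a], rec_b.final_w()
    summary = RFSummary(
        labels=label_synapses(rec_ab.w, rec_ab.times, pparams.w0_minus)
    )
    try:
        summary.overlap_a = memory_overlap(w_ab, w_a)
        summary.overlap_b = memory_overlap(w_ab, w_b)
        summary.regime = classify_regime(summary.overlap_a, summary.overlap_b, threshold)
    except ValueError:
        summary.regime = "unformed"
    return summary


def run_di_protocol(
    pop: SynapsePopulation,
    structure: CorrelationStructure,
    pparams: Optional[PlasticityParams] = None,
    nparams: Optional[NeuronParams] = None,
    sim: Optional[SimParams] = None,
    n_angles: int = 16,
    t_pref: float = 100.0,
    t_test: float = 1.0,
    rate: float = TEST_RATE,
    seed: int = 0,
) -> RFSummary:
    """Measure the discrimination index of a trained weight state.

    Plasticity is frozen.  The output rate is measured for ``t_pref``
    seconds under the training structure (the preferred pattern) and for
    ``t_test`` seconds under each of ``n_angles`` evenly spaced rotations
    of it, all at the reduced testing rate.
    """
    pparams = pparams or PlasticityParams()
    nparams = nparams or NeuronParams()
    sim = sim or SimParams()
    rng = new_rng(seed, "di")

    def measure(struct: CorrelationStructure, duration: float) -> float:
        rec = run_network(
            (Phase(struct, rate, duration, plastic=False),),
            pparams, nparams, sim, rng, pop=pop,
        )
        return rec.mean_post_rate()

    y_pref = measure(structure, t_pref)
    if y_pref == 0:
        raise ValueError("neuron silent at the preferred pattern; DI undefined")
    angles = 2.0 * np.pi * np.arange(n_angles) / n_angles
    y_theta = np.array(
        [measure(rotate(structure, d), t_test) for d in angles]
    )
    _, di = discrimination_index(y_pref, y_theta)
    return RFSummary(di=di)


def run_sweep(
    alphas: Sequence[float],
    c_tots: Sequence[float],
    seeds: Sequence[int],
    kind: str = "formation",
    rule: str = "fs",
    make_structure=None,
    pparams: Optional[PlasticityParams] = None,
    duration: float = 200.0,
    duration_b: float = 400.0,
    n: int = 1000,
    with_di: bool = False,
    **protocol_kwargs,
) -> pd.DataFrame:
    """Run a protocol over an (alpha, c_tot) grid and tabulate results.

    ``kind`` selects ``formation`` (columns: r, n_spines, optionally di)
    or ``consolidation`` (columns: overlap_a, overlap_b, regime).
    ``make_structure(c_tot)`` builds the input structure per cell; default
    is the von Mises structure at the table concentration.  Failures in a
    cell are recorded (column ``error``) and the sweep continues.
    """
    if not len(alphas) or not len(c_tots):
        raise ValueError("grid must be nonempty")
    base = pparams or PlasticityParams()
    base = replace(base, rule=rule)
    if make_structure is None:
        make_structure = lambda c_tot: make_von_mises(n, np.pi, 8.0, c_tot)
    rows = []
    for alpha in alphas:
        for c_tot in c_tots:
            structure = make_structure(c_tot)
            p = replace(base, alpha=float(alpha))
            for seed in seeds:
                row = {"alpha": float(alpha), "c_tot": float(c_tot),
                       "seed": int(seed), "rule": rule, "error": ""}
                try:
                    if kind == "formation":
                        spec = formation_spec(structure, duration, p, seed=seed)
                        rec, summ = run_rf_formation(spec)
                        row["r"] = summ.r
                        row["n_spines"] = int(summ.labels.sum())
                        if with_di:
                            di = run_di_protocol(
                                rec.final_pop, structure, p, seed=seed,
                                **protocol_kwargs,
                            )
                            row["di"] = di.di
                    elif kind == "consolidation":
                        structure_b = rotate(structure, np.pi)
                        summ = run_consolidation(
                            structure, structure_b, p,
                            duration_a=duration, duration_b=duration_b,
                            seed=seed, **protocol_kwargs,
                        )
                        row["overlap_a"] = summ.overlap_a
                        row["overlap_b"] = summ.overlap_b
                        row["regime"] = summ.regime
                    else:
                        raise ValueError(f"unknown sweep kind {kind!r}")
                except ValueError as exc:
                    row["error"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows)
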