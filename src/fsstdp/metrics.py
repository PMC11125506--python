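"""Receptive-field metrics: labeling, correlation, discrimination, overlap."""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
from scipy import stats

__all__ = [
    "label_synapses",
    "pearson_r",
    "discrimination_index",
    "memory_overlap",
    "classify_regime",
    "REGIMES",
]

REGIMES = ("total_overwriting", "partial_overwriting", "no_overwriting", "unformed")


def label_synapses(
    w_trace: np.ndarray,
    times: np.ndarray,
    w0_minus: float = 0.5,
    window: float = 10.0,
) -> np.ndarray:
    """Label synapses filopodium/spine from the trailing mean weight.

    A synapse is a *spine* if its mean weight over the final ``window``
    seconds of the trace is at or above the lower soft bound ``w0_minus``,
    a *filopodium* otherwise.  Returns a boolean array, True for spines.
    """
    w_trace = np.atleast_2d(np.asarray(w_trace, dtype=float))
    times = np.asarray(times, dtype=float)
    if w_trace.shape[0] == 0:
        raise ValueError("empty weight trace")
    if times.size != w_trace.shape[0]:
        raise ValueError("times and trace rows must match")
    t_end = times[-1]
    mask = times >= t_end - window + 1e-12
    mean_w = w_trace[mask].mean(axis=0)
    return mean_w >= w0_minus


def pearson_r(weights: np.ndarray, c: np.ndarray) -> float:
    """Pearson correlation between converged efficacies and their c_i."""
    weights = np.asarray(weights, dtype=float)
    c = np.asarray(c, dtype=float)
    if weights.size < 3:
        raise ValueError("need at least 3 synapses for a correlation")
    if np.ptp(weights) == 0 or np.ptp(c) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(weights, c).statistic)


def discrimination_index(
    y_pref: float, y_theta: np.ndarray
) -> Tuple[np.ndarray, float]:
    """Discrimination index DI(theta) per tested angle and its mean.

    ``DI(theta) = (y_pref - y_theta) / (y_pref + y_theta)``; angles where
    both rates vanish are undefined and excluded with a warning.
    """
    y_theta = np.asarray(y_theta, dtype=float)
    denom = y_pref + y_theta
    valid = denom > 0
    if not valid.all():
        warnings.warn(
            f"{np.count_nonzero(~valid)} angle(s) with zero rate at both the "
            "preferred and tested structure excluded from the DI average",
            stacklevel=2,
        )
    if not valid.any():
        raise ValueError("DI undefined: neuron silent at every tested angle")
    di_curve = np.full(y_theta.shape, np.nan)
    di_curve[valid] = (y_pref - y_theta[valid]) / denom[valid]
    return di_curve, float(np.nanmean(di_curve))


def memory_overlap(w_x: np.ndarray, w_y: np.ndarray) -> float:
    """Cosine similarity between two converged weight vectors."""
    w_x = np.asarray(w_x, dtype=float)
    w_y = np.asarray(w_y, dtype=float)
    nx = np.linalg.norm(w_x)
    ny = np.linalg.norm(w_y)
    if nx == 0 or ny == 0:
        raise ValueError("memory overlap undefined for a zero weight vector")
    return float(w_x @ w_y / (nx * ny))


def classify_regime(overlap_a: float, overlap_b: float, threshold: float = 0.5) -> str:
    """Overwriting regime from the two memory overlaps.

    A memory counts as present when its overlap reaches ``threshold``.
    Both present -> partial overwriting; only the new pattern B ->
    total overwriting; only the old pattern A -> no overwriting;
    neither -> unformed.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    a_present = overlap_a >= threshold
    b_present = overlap_b >= threshold
    if a_present and b_present:
        return "partial_overwriting"
    if b_present:
        return "total_overwriting"
    if a_present:
        return "no_overwriting"
    return "unformed"
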