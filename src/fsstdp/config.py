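"""Run configuration: table defaults, strict validation, YAML/JSON loading.

The schema is flat and namespaced: sections ``neuron``, ``plasticity`` and
``sim`` map one-to-one onto the corresponding parameter dataclasses (and
default to the published table values when unspecified); ``protocol``
selects what to run; top-level ``seed`` and ``out`` complete the run.
Unknown sections or keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import numpy as np
import yaml

from .inputgen import (
    CorrelationStructure,
    make_gaussian,
    make_squared_pulse,
    make_von_mises,
)
from .neuron import NeuronParams
from .plasticity import PlasticityParams
from .simulate import SimParams

__all__ = ["RunConfig", "load_config", "build_structure"]

_SECTIONS = ("neuron", "plasticity", "sim", "protocol")
_TOP_KEYS = set(_SECTIONS) | {"seed", "out"}

_PROTOCOL_KEYS = {
    "kind", "structure", "duration", "duration_a", "duration_b",
    "alphas", "c_tots", "seeds", "n_angles", "t_pref", "t_test",
    "rule", "threshold", "with_di",
}
_STRUCTURE_KEYS = {
    "kind", "n", "theta_pref", "kappa", "c_tot", "n_tot", "mean", "sd",
    "seed", "offset",
}


@dataclass(frozen=True)
class RunConfig:
    """Fully validated configuration for one run."""

    neuron: NeuronParams = NeuronParams()
    plasticity: PlasticityParams = PlasticityParams()
    sim: SimParams = SimParams()
    protocol: dict = field(default_factory=dict)
    seed: int = 0
    out: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "neuron": dataclasses.asdict(self.neuron),
            "plasticity": dataclasses.asdict(self.plasticity),
            "sim": dataclasses.asdict(self.sim),
            "protocol": dict(self.protocol),
            "seed": self.seed,
            "out": self.out,
        }


def _build_section(cls, mapping: Mapping[str, Any], section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}; "
            f"expected a subset of {sorted(known)}"
        )
    return cls(**mapping)


def _check_protocol(protocol: Mapping[str, Any]) -> dict:
    unknown = set(protocol) - _PROTOCOL_KEYS
    if unknown:
        raise ValueError(f"unknown protocol key(s) {sorted(unknown)}")
    structure = protocol.get("structure", {})
    if not isinstance(structure, Mapping):
        raise ValueError("protocol.structure must be a mapping")
    unknown = set(structure) - _STRUCTURE_KEYS
    if unknown:
        raise ValueError(f"unknown structure key(s) {sorted(unknown)}")
    return {**protocol, "structure": dict(structure)}


def load_config(source: Union[str, Path, Mapping, None] = None) -> RunConfig:
    """Build a RunConfig from a mapping or a YAML/JSON file path.

    Values merge over the table defaults; anything not recognized raises a
    descriptive ValueError.
    """
    if source is None:
        data: Mapping[str, Any] = {}
    elif isinstance(source, Mapping):
        data = source
    else:
        text = Path(source).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"config file {source} must contain a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(
            f"unknown top-level key(s) {sorted(unknown)}; "
            f"expected a subset of {sorted(_TOP_KEYS)}"
        )
    return RunConfig(
        neuron=_build_section(NeuronParams, data.get("neuron", {}), "neuron"),
        plasticity=_build_section(
            PlasticityParams, data.get("plasticity", {}), "plasticity"
        ),
        sim=_build_section(SimParams, data.get("sim", {}), "sim"),
        protocol=_check_protocol(data.get("protocol", {})),
        seed=int(data.get("seed", 0)),
        out=data.get("out"),
    )


def build_structure(spec: Mapping[str, Any], default_seed: int = 0) -> CorrelationStructure:
    """Construct a correlation structure from its config mapping."""
    kind = spec.get("kind", "von_mises")
    n = int(spec.get("n", 1000))
    c_tot = float(spec.get("c_tot", 60.0))
    if kind == "von_mises":
        return make_von_mises(
            n,
            float(spec.get("theta_pref", np.pi)),
            float(spec.get("kappa", 8.0)),
            c_tot,
        )
    if kind == "squared_pulse":
        return make_squared_pulse(
            n, int(spec.get("n_tot", 200)), c_tot, int(spec.get("offset", 0))
        )
    if kind == "gaussian":
        return make_gaussian(
            n,
            float(spec.get("mean", 0.3)),
            float(spec.get("sd", 0.1)),
            c_tot,
            int(spec.get("seed", default_seed)),
        )
    raise ValueError(f"unknown structure kind {kind!r}")
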