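"""Serialization: declarative model YAML, dataset CSV, scenario bundles.

The YAML schema covers models whose rate laws come from the declarative
registry (Michaelis–Menten with optional summed vmax terms and
multiplicative gains, mass action, zero order).  Models carrying
arbitrary Python callables without a ``rate_specs`` entry cannot be
round-tripped and are rejected with a clear message.

Schema::

    states:
      - {name: S0, initial: 10.0, status: known}   # or unknown
    parameters: {vmax_1: 1.2, km_1: 0.9}
    rates:
      r1: {law: michaelis_menten, substrate: S0, vmax: [vmax_1], km: km_1, gains: []}
      r2: {law: mass_action, substrate: S1, k: k_2}
    stoichiometry:
      r1: {S0: -1, S1: 1}
    dilution_rate: 0.0
    extracellular: []
    outputs: [S0, S1]
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable

import yaml

from .data import Dataset, ErrorModel
from .model import KineticModel

__all__ = ["load_model", "save_model", "load_dataset", "save_dataset", "save_scenario"]


def _law_from_spec(spec: dict) -> Callable:
    law = spec.get("law")
    if law == "michaelis_menten":
        sub = spec["substrate"]
        vnames = tuple(spec["vmax"]) if isinstance(spec["vmax"], list) else (spec["vmax"],)
        kname = spec["km"]
        gains = tuple(spec.get("gains", ()))

        def mm(c, p):
            v = sum(p[n] for n in vnames)
            for g in gains:
                v *= p[g]
            s = c[sub]
            return v * s / (p[kname] + s)

        return mm
    if law == "mass_action":
        sub, kname = spec["substrate"], spec["k"]
        return lambda c, p: p[kname] * c[sub]
    if law == "constant":
        vname = spec["vmax"] if isinstance(spec["vmax"], str) else spec["vmax"][0]
        return lambda c, p: p[vname]
    raise ValueError(f"unknown rate law {law!r}")


def load_model(path) -> KineticModel:
    """Read a model specification file (YAML)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    states = doc["states"]
    state_names = [s["name"] for s in states]
    ics = {s["name"]: float(s["initial"]) for s in states}
    unknown = frozenset(
        s["name"] for s in states if s.get("status", "known") == "unknown"
    )
    rate_specs = dict(doc["rates"])
    rate_laws = {name: _law_from_spec(spec) for name, spec in rate_specs.items()}
    stoich = {
        rate: {s: float(c) for s, c in coeffs.items()}
        for rate, coeffs in doc["stoichiometry"].items()
    }
    return KineticModel(
        state_names=tuple(state_names),
        parameters={k: float(v) for k, v in doc.get("parameters", {}).items()},
        rate_laws=rate_laws,
        stoichiometry=stoich,
        initial_conditions=ics,
        unknown_ics=unknown,
        dilution_rate=float(doc.get("dilution_rate", 0.0)),
        extracellular=frozenset(doc.get("extracellular", ())),
        output_map=tuple(doc.get("outputs", ())),
        rate_specs=rate_specs,
    )


def save_model(model: KineticModel, path) -> None:
    """Write a model specification file; requires declarative rate specs."""
    missing = set(model.stoichiometry) - set(model.rate_specs)
    if missing:
        raise ValueError(
            f"rates {sorted(missing)} have no declarative spec; models built "
            "from raw callables cannot be serialized"
        )
    doc = {
        "states": [
            {
                "name": s,
                "initial": float(model.initial_conditions[s]),
                "status": "unknown" if s in model.unknown_ics else "known",
            }
            for s in model.state_names
        ],
        "parameters": {k: float(v) for k, v in model.parameters.items()},
        "rates": {
            name: {k: (list(v) if isinstance(v, tuple) else v) for k, v in spec.items()}
            for name, spec in model.rate_specs.items()
        },
        "stoichiometry": {
            rate: {s: float(c) for s, c in coeffs.items()}
            for rate, coeffs in model.stoichiometry.items()
        },
        "dilution_rate": float(model.dilution_rate),
        "extracellular": sorted(model.extracellular),
        "outputs": list(model.output_map),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_dataset(path, error_model: ErrorModel | None = None) -> Dataset:
    """Read a long-format CSV (columns time, variable, value)."""
    return Dataset.from_csv(path, error_model)


def save_dataset(dataset: Dataset, path) -> None:
    dataset.to_csv(path)


def save_scenario(scenario, model_path, data_path) -> None:
    """Write a synthetic scenario as the model YAML + data CSV the CLI
    consumes, so generated problems exercise the user-facing path."""
    save_model(scenario.model, model_path)
    save_dataset(scenario.dataset, data_path)
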