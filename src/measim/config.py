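"""Flat key-value configuration files.

The format is deliberately minimal: one ``section.key = value`` pair per
line, ``#`` comments, blank lines ignored.  Sections map onto the parameter
dataclasses (``simulation``, ``neuron``, ``synapse``, ``layout``,
``condition``, ``condition.modifier``); every field defaults to the control
model, so an empty file is a valid control configuration.

Example::

    simulation.duration = 170
    simulation.transient_discard = 50
    simulation.seed = 42
    neuron.sigma = 4.1
    condition.name = sAHP_half
"""

from __future__ import annotations

from dataclasses import fields, replace
from pathlib import Path

from .engine import ConditionSpec, SimulationConfig
from .params import LayoutParams, NeuronParams, RateModifier, SynapseParams

_SIM_KEYS = {
    "duration",
    "transient_discard",
    "dt",
    "record_rate",
    "n_networks",
    "seed",
}


def _coerce(raw: str):
    raw = raw.strip()
    low = raw.lower()
    if low in ("true", "false"):
        return low == "true"
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        pass
    return raw


def parse_config_text(text: str) -> dict[str, object]:
    """Parse ``section.key = value`` lines into a flat dict."""
    out: dict[str, object] = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {ln}: expected 'section.key = value', got {line!r}")
        key, raw = (part.strip() for part in line.split("=", 1))
        out[key] = _coerce(raw)
    return out


def config_from_mapping(mapping: dict[str, object]) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from flat dotted keys.

    Unknown keys raise a single error listing every offender.
    """
    sim: dict = {}
    block_updates: dict[str, dict] = {
        "neuron": {},
        "synapse": {},
        "layout": {},
        "condition": {},
        "condition.modifier": {},
    }
    known = {
        "neuron": {f.name for f in fields(NeuronParams)},
        "synapse": {f.name for f in fields(SynapseParams)},
        "layout": {f.name for f in fields(LayoutParams)},
        "condition": {f.name for f in fields(ConditionSpec)} - {"modifier"},
        "condition.modifier": {f.name for f in fields(RateModifier)},
    }
    bad = []
    for key, value in mapping.items():
        if "." not in key:
            bad.append(key)
            continue
        section, field = key.rsplit(".", 1)
        if section == "simulation" and field in _SIM_KEYS:
            sim[field] = value
        elif section in block_updates and field in known[section]:
            block_updates[section][field] = value
        else:
            bad.append(key)
    if bad:
        raise ValueError("unknown configuration keys: " + ", ".join(sorted(bad)))

    neuron = replace(NeuronParams(), **block_updates["neuron"])
    synapse = replace(SynapseParams(), **block_updates["synapse"])
    layout = replace(LayoutParams(), **block_updates["layout"])
    cond_kw = block_updates["condition"]
    name = cond_kw.pop("name", "control")
    mod = RateModifier(**block_updates["condition.modifier"])
    if cond_kw or not mod.is_identity:
        condition = ConditionSpec(name=name, modifier=mod, **cond_kw)
    else:
        condition = ConditionSpec.from_name(name)
    return SimulationConfig(
        neuron=neuron, synapse=synapse, layout=layout, condition=condition, **sim
    )


def load_config(path) -> SimulationConfig:
    """Read a key-value configuration file."""
    return config_from_mapping(parse_config_text(Path(path).read_text()))
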