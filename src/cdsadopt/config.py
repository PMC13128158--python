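"""Configuration loading: flat YAML/JSON key-value files over defaults."""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import yaml

from cdsadopt.model import ModelParameters, default_params

__all__ = ["load_config"]

log = logging.getLogger("cdsadopt")

_PARAM_NAMES = {f.name for f in dataclasses.fields(ModelParameters)}


def load_config(path: str | Path | None) -> ModelParameters:
    """Parameters from a flat YAML (or JSON) mapping overlaid on defaults.

    Keys must be exactly the ``ModelParameters`` field names; an unknown
    key is rejected by name, as is any value violating the parameter
    invariants. The overridden keys are logged for provenance. ``None``
    or an empty file yields the defaults.
    """
    if path is None:
        return default_params()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        log.info("config %s empty; using defaults", path)
        return default_params()
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat mapping, got {type(data).__name__}")
    unknown = set(data) - _PARAM_NAMES
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; valid keys are "
            f"{sorted(_PARAM_NAMES)}"
        )
    overrides = {k: float(v) for k, v in data.items()}
    params = default_params().replace(**overrides)
    log.info("config %s overrides: %s", path, sorted(overrides))
    return params
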