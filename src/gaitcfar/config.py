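"""Structured configuration: YAML file -> DetectorParams, with overrides.

Layout mirrors the parameter dataclasses::

    windows: {asc_size: 38, asc_limit: 35, desc_size: 40, desc_limit: 36}
    cfar:    {pf_value: 20.5, pf_mode: inverse_gain,
              min_unstable_samples: 20, trim_tail: 38}
    filter:  {cutoff_hz: 200, order: 2, mode: causal}
    rule_mode: discussion_consistent

Unknown keys are rejected.  CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import asdict, replace
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .cfar import CfarParams
from .detector import DetectorParams
from .errors import ConfigError
from .filters import FilterConfig
from .windows import WindowParams

__all__ = ["params_from_dict", "params_to_dict", "load_params", "save_params"]

_SECTIONS = {"windows": WindowParams, "cfar": CfarParams, "filter": FilterConfig}


def params_from_dict(data: Mapping[str, Any]) -> DetectorParams:
    """Build :class:`DetectorParams` from a nested mapping."""
    unknown = set(data) - set(_SECTIONS) - {"rule_mode"}
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for section, cls in _SECTIONS.items():
        sub = data.get(section, {})
        if not isinstance(sub, Mapping):
            raise ConfigError(f"section {section!r} must be a mapping")
        bad = set(sub) - set(cls.__dataclass_fields__)  # type: ignore[attr-defined]
        if bad:
            raise ConfigError(f"unknown keys in section {section!r}: {sorted(bad)}")
        try:
            kwargs[section] = cls(**sub)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid {section} configuration: {exc}") from exc
    if "rule_mode" in data:
        kwargs["rule_mode"] = data["rule_mode"]
    return DetectorParams(**kwargs)


def params_to_dict(params: DetectorParams) -> dict[str, Any]:
    """Fully-resolved nested mapping of *params* (for logging/round-trip)."""
    out = asdict(params)
    out["cfar"]["pf_mode"] = params.cfar.pf_mode.value
    out["filter"]["mode"] = params.filter.mode.value
    out["rule_mode"] = params.rule_mode.value
    return out


def load_params(path, **overrides: Any) -> DetectorParams:
    """Load detector parameters from a YAML file, applying flat overrides.

    Overrides use the dataclass field names: ``pf_value``, ``pf_mode``
    (cfar), ``rule_mode``, window and filter fields.  ``path=None`` starts
    from defaults.
    """
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = loaded
    params = params_from_dict(data)
    for key, value in overrides.items():
        if value is None:
            continue
        if key == "rule_mode":
            params = replace(params, rule_mode=value)
        elif key in CfarParams.__dataclass_fields__:
            params = replace(params, cfar=replace(params.cfar, **{key: value}))
        elif key in WindowParams.__dataclass_fields__:
            params = replace(params, windows=replace(params.windows, **{key: value}))
        elif key in FilterConfig.__dataclass_fields__:
            params = replace(params, filter=replace(params.filter, **{key: value}))
        else:
            raise ConfigError(f"unknown parameter override {key!r}")
    return params


def save_params(path, params: DetectorParams) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(params), sort_keys=False))
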