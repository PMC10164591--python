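"""Flat ``key: value`` configuration files with include support.

The format is deliberately minimal: one ``key: value`` pair per line,
``#`` comments, and ``include: relative/path`` lines that splice in another
file (keys defined later override included ones).  Values are parsed as
int, float, bool or string.  Kinetic-parameter keys are named exactly as
the :class:`~tailkin.types.KineticParams` fields, so a ground-truth
parameter set round-trips bit-exactly through ``repr`` serialization.
"""

from __future__ import annotations

from pathlib import Path

from .types import ConfigError, KineticParams

__all__ = [
    "parse_config",
    "parse_config_text",
    "dump_config",
    "params_to_config",
    "params_from_config",
    "validate_params_mapping",
]


def _parse_value(raw: str):
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


def parse_config_text(text: str, base_dir: Path | None = None) -> dict:
    out: dict = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ConfigError(f"line {lineno}: expected 'key: value', got {line!r}")
        key, raw = (part.strip() for part in line.split(":", 1))
        if not key:
            raise ConfigError(f"line {lineno}: empty key")
        if key == "include":
            if base_dir is None:
                raise ConfigError("include requires a file-based config")
            out.update(parse_config(base_dir / raw))
        else:
            out[key] = _parse_value(raw)
    return out


def parse_config(path) -> dict:
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    return parse_config_text(path.read_text(), base_dir=path.parent)


def dump_config(mapping: dict) -> str:
    lines = []
    for key, value in mapping.items():
        if isinstance(value, float):
            lines.append(f"{key}: {value!r}")
        else:
            lines.append(f"{key}: {value}")
    return "\n".join(lines) + "\n"


def params_to_config(params: KineticParams) -> dict:
    return {name: getattr(params, name) for name in KineticParams.field_names()}


def validate_params_mapping(mapping: dict) -> dict:
    """Check kinetic-parameter overrides, reporting the offending field."""
    known = set(KineticParams.field_names())
    overrides = {k: v for k, v in mapping.items() if k in known}
    for key, value in overrides.items():
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ConfigError(f"{key}: expected a number, got {value!r}")
    non_negative = ("k_on", "k_off", "k_cat_ccr4", "k_cat_caf1", "handoff_rate")
    positive = ("tether_off_scale", "cup_on_scale", "pabpc_end_block",
                "pabpc_stim", "pabpc_recruit_block", "pabpc_footprint")
    for key in non_negative:
        if key in overrides and overrides[key] < 0:
            raise ConfigError(f"{key}: must be >= 0, got {overrides[key]}")
    for key in positive:
        if key in overrides and overrides[key] <= 0:
            raise ConfigError(f"{key}: must be > 0, got {overrides[key]}")
    if "theta_dead" in overrides and not 0 <= overrides["theta_dead"] <= 1:
        raise ConfigError(f"theta_dead: must be in [0, 1], got {overrides['theta_dead']}")
    return overrides


def params_from_config(mapping: dict, base: KineticParams | None = None) -> KineticParams:
    base = base or KineticParams()
    overrides = validate_params_mapping(mapping)
    values = params_to_config(base)
    values.update(overrides)
    if "pabpc_footprint" in values:
        values["pabpc_footprint"] = int(values["pabpc_footprint"])
    return KineticParams(**values)
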