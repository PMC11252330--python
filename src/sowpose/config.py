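"""Flat key-value configuration files and the shipped gait presets."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any, Union

import yaml

from .errors import ParseError

__all__ = ["parse_flat_config", "load_config", "load_gait_presets"]


def _coerce(text: str) -> Any:
    low = text.lower()
    if low in ("true", "yes", "on"):
        return True
    if low in ("false", "no", "off"):
        return False
    if low in ("none", "null", ""):
        return None
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def parse_flat_config(text: str) -> dict[str, Any]:
    """Parse ``key = value`` lines; '#' starts a comment; values are coerced."""
    out: dict[str, Any] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if not key:
            raise ParseError(f"line {lineno}: empty key")
        if key in out:
            raise ParseError(f"line {lineno}: duplicate key {key!r}")
        out[key] = _coerce(value)
    return out


def load_config(path: Union[str, Path]) -> dict[str, Any]:
    """Load a config file: flat key=value by default, YAML for .yaml/.yml."""
    path = Path(path)
    text = path.read_text("utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(text) or {}
        if not isinstance(doc, dict):
            raise ParseError(f"{path}: YAML config must be a mapping")
        return doc
    return parse_flat_config(text)


def load_gait_presets() -> dict[int, dict[str, Any]]:
    """Per-score gait parameter presets from the shipped config file.

    Returns a mapping score -> flat parameter dict, with the ``common.*``
    entries merged into each score's dict.
    """
    text = resources.files("sowpose").joinpath("data/gait_presets.cfg").read_text("utf-8")
    flat = parse_flat_config(text)
    common = {k.split(".", 1)[1]: v for k, v in flat.items() if k.startswith("common.")}
    presets: dict[int, dict[str, Any]] = {}
    for score in range(4):
        prefix = f"score{score}."
        overrides = {k[len(prefix):]: v for k, v in flat.items() if k.startswith(prefix)}
        merged = dict(common)
        merged.update(overrides)
        merged["score"] = score
        presets[score] = merged
    return presets
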