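"""Flat key-value run configuration: defaults < config file < command flags.

Grammar: one ``key = value`` pair per line (``=`` or whitespace separated),
``#`` starts a comment, blank lines ignored.  Keys are validated against the
schema of the subcommand being run; unknown keys are errors, not warnings.
Every run echoes its effective configuration verbatim into the output
directory so it can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any, Dict, Mapping, Optional

from .model_core import SimParams

__all__ = ["ConfigError", "parse_config_file", "build_sim_params", "echo_config", "setup_logging"]

logger = logging.getLogger("svload")


class ConfigError(ValueError):
    """A configuration problem, named after the offending key."""


def _parse_scalar(text: str) -> Any:
    t = text.strip()
    low = t.lower()
    if low in ("true", "yes", "on"):
        return True
    if low in ("false", "no", "off"):
        return False
    for caster in (int, float):
        try:
            return caster(t)
        except ValueError:
            pass
    return t


def parse_config_file(path) -> Dict[str, Any]:
    """Parse a flat key-value config file into a dict of typed scalars."""
    out: Dict[str, Any] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" in line:
                key, _, value = line.partition("=")
            else:
                parts = line.split(None, 1)
                if len(parts) != 2:
                    raise ConfigError(f"{path}:{lineno}: cannot parse {raw.strip()!r}")
                key, value = parts
            key = key.strip()
            if not key:
                raise ConfigError(f"{path}:{lineno}: empty key")
            if key in out:
                raise ConfigError(f"{path}:{lineno}: duplicate key {key!r}")
            out[key] = _parse_scalar(value)
    return out


_SIM_KEYS = {f.name for f in dataclasses.fields(SimParams)}


def build_sim_params(
    file_settings: Mapping[str, Any],
    overrides: Mapping[str, Any],
    allowed_extra: frozenset = frozenset(),
) -> SimParams:
    """Merge config-file settings and CLI overrides into SimParams.

    Keys that are neither SimParams fields nor in ``allowed_extra`` raise
    :class:`ConfigError` naming the key.
    """
    merged: Dict[str, Any] = {}
    for source in (file_settings, overrides):
        for key, value in source.items():
            if value is None:
                continue
            if key not in _SIM_KEYS and key not in allowed_extra:
                raise ConfigError(f"unknown configuration key: {key!r}")
            merged[key] = value
    sim_kwargs = {k: v for k, v in merged.items() if k in _SIM_KEYS}
    try:
        return SimParams(**sim_kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def echo_config(settings: Mapping[str, Any], outdir: Path, name: str = "config_used.txt") -> Path:
    """Write the effective configuration, one key = value per line."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / name
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(settings):
            fh.write(f"{key} = {settings[key]}\n")
    return path


def setup_logging(outdir: Optional[Path], level: str = "INFO") -> None:
    """Log to console and, when an output directory is given, to run.log."""
    handlers: list = [logging.StreamHandler()]
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(outdir / "run.log", encoding="utf-8"))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )
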