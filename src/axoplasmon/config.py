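"""Flat key-value configuration dialect and run manifests.

One ``key = value`` pair per line, ``#`` comments, blank lines ignored.
Keys are dotted paths whose last component carries an explicit unit suffix
(``_m``, ``_per_s``, ``_k``, ...) for every dimensional quantity.  JSON
files (detected by a ``.json`` extension or a leading ``{``) are accepted
as an alternative representation of the same flat mapping.
"""

from __future__ import annotations

import json
from pathlib import Path


class ConfigError(ValueError):
    pass


def parse_config(text: str) -> dict:
    """Parse flat key-value text (or a flat JSON object) into a dict of strings."""
    stripped = text.lstrip()
    if stripped.startswith("{"):
        obj = json.loads(text)
        if not isinstance(obj, dict):
            raise ConfigError("JSON config must be a flat object")
        return {str(k): str(v) for k, v in obj.items()}
    out: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if not key:
            raise ConfigError(f"line {lineno}: empty key")
        out[key] = value
    return out


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return {str(k): str(v) for k, v in json.loads(text).items()}
    return parse_config(text)


def dump_config(cfg: dict) -> str:
    """Serialize back to the flat dialect (round-trips with parse_config)."""
    return "".join(f"{k} = {v}\n" for k, v in cfg.items())


def write_manifest(path, params: dict, extra: dict | None = None) -> dict:
    """Write a run manifest JSON recording all resolved parameters."""
    from . import __version__

    manifest = {"package": "axoplasmon", "version": __version__,
                "params": {k: params[k] for k in sorted(params)}}
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
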