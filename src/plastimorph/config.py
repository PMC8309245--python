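"""Run configuration: defaults < config file < CLI flags, resolved once.

The config file is flat key-value text with dotted namespaces::

    pixel_size_nm = 100
    canny.sigma = 2.0
    pores.min_area_px = 10

Every run writes its fully resolved configuration next to its outputs, so
any metric file can be regenerated from the sidecar plus the input image —
comparability across a series depends on parameters being fixed once and
recorded.
"""

from __future__ import annotations

import json
import os

__all__ = ["DEFAULTS", "load_config", "resolve_config", "write_sidecar"]

DEFAULTS: dict[str, object] = {
    "pixel_size_nm": None,  # mandatory: every physical metric needs it
    "denoise.sigma": 0.0,
    "canny.sigma": 2.0,
    "canny.low_frac": 0.1,
    "canny.high_frac": 0.2,
    "threshold": "otsu",
    "particles.min_area_px": 10,
    "pores.threshold": "triangle",
    "pores.min_area_px": 10,
    "pores.max_area_px": None,  # None -> 10% of ROI
    "texture.min_period_px": 2,
    "seed": 0,
}


def _coerce(text: str) -> object:
    t = text.strip()
    low = t.lower()
    if low in ("none", "null"):
        return None
    if low == "true":
        return True
    if low == "false":
        return False
    for cast in (int, float):
        try:
            return cast(t)
        except ValueError:
            pass
    return t


def load_config(path: str | os.PathLike) -> dict[str, object]:
    """Parse a flat ``key = value`` file; ``#`` starts a comment."""
    values: dict[str, object] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, val = line.split("=", 1)
            values[key.strip()] = _coerce(val)
    return values


def resolve_config(
    config_file: str | os.PathLike | None = None,
    overrides: dict[str, object] | None = None,
) -> dict[str, object]:
    """Merge defaults, file values, and CLI overrides (None overrides skipped)."""
    resolved = dict(DEFAULTS)
    if config_file is not None:
        for k, v in load_config(config_file).items():
            resolved[k] = v
    if overrides:
        for k, v in overrides.items():
            if v is not None:
                resolved[k] = v
    return resolved


def write_sidecar(config: dict[str, object], path: str | os.PathLike, extra: dict | None = None) -> None:
    """Record the resolved configuration (plus run inputs) as JSON."""
    payload = dict(config)
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
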