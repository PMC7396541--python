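"""YAML configuration for the command-line tools.

A single file with ``simulator`` / ``detector`` / ``evaluation`` sections;
command-line flags override file values, which override the built-in
defaults below.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml

from .errors import FormatError

DEFAULTS: dict = {
    "simulator": {
        "subjects": 20,
        "patients": 6,
        "strides": 50,
        "freqs": [0.25, 0.3, 0.4],
        "noise": 1.0,
    },
    "detector": {
        "preset": None,  # default: the trial's own group
        "prominence_deg": 5.0,
        "refractory_frac": 0.4,
        "clamp_eps_deg": 0.5,
        "confirm_margin_deg": 1.0,
        "omega_star": None,  # None: use the preset value
        "theta_star": None,
        "a_star": None,
        "alpha": None,
    },
    "evaluation": {
        "ratio": "7:3",
    },
}


def load_config(path: Optional[str] = None) -> dict:
    """Built-in defaults, overlaid with the sections of a YAML file."""
    merged = {k: dict(v) for k, v in DEFAULTS.items()}
    if path is None:
        return merged
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"config {path} must be a mapping of sections")
    for section, values in raw.items():
        if section not in merged:
            raise FormatError(f"unknown config section {section!r}")
        if values is None:
            continue
        for key, value in values.items():
            if key not in merged[section]:
                raise FormatError(f"unknown config key {section}.{key}")
            merged[section][key] = value
    return merged


def hs_config_from(cfg: dict):
    from .hs import HsConfig

    d = cfg["detector"]
    return HsConfig(
        prominence_deg=float(d["prominence_deg"]),
        refractory_frac=float(d["refractory_frac"]),
        clamp_eps_deg=float(d["clamp_eps_deg"]),
        confirm_margin_deg=float(d["confirm_margin_deg"]),
    )


def to_thresholds_from(cfg: dict, population: str):
    from .to import ToThresholds

    d = cfg["detector"]
    overrides = {
        k: float(d[k])
        for k in ("omega_star", "theta_star", "a_star", "alpha")
        if d[k] is not None
    }
    return ToThresholds.preset(population, **overrides)
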