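"""Bundled condition profiles and their loaders.

Profiles are shipped as editable YAML under ``bpdph/data`` and describe
the per-group structure the phantom generators emulate: diameter-binned
vessel abundances, Doppler timings, agonist concentration-response
parameters, qPCR group means, histology collagen fractions, and
angiogram branching counts.  Users may point the loaders at their own
files to change the study conditions.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "load_yaml_profile",
    "microct_conditions",
    "doppler_profiles",
    "pcls_agonists",
    "heart_qpcr",
    "histology_collagen",
    "angiogram_trees",
]

_DATA = resources.files("bpdph") / "data"


def load_yaml_profile(name_or_path: str | Path) -> dict[str, Any]:
    """Load a bundled profile by name (e.g. ``"doppler_profiles"``) or an
    arbitrary YAML file by path."""
    p = Path(name_or_path)
    if p.suffix in {".yaml", ".yml"} and p.exists():
        text = p.read_text()
    else:
        text = (_DATA / f"{name_or_path}.yaml").read_text()
    return yaml.safe_load(text)


def microct_conditions() -> dict[str, Any]:
    return load_yaml_profile("microct_conditions")


def doppler_profiles() -> dict[str, Any]:
    return load_yaml_profile("doppler_profiles")


def pcls_agonists() -> dict[str, Any]:
    return load_yaml_profile("pcls_agonists")


def heart_qpcr() -> dict[str, Any]:
    return load_yaml_profile("heart_qpcr")


def histology_collagen() -> dict[str, Any]:
    return load_yaml_profile("histology_collagen")


def angiogram_trees() -> dict[str, Any]:
    return load_yaml_profile("angiogram_trees")
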