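"""YAML configuration for head model, source grid and interpolation defaults.

A config file is a flat mapping of sections, all optional; every value
defaults to the standard settings::

    head_model:
      r_brain: 0.87
      r_skull_outer: 0.92
      r_scalp: 1.0
      sigma_brain: 1.0
      sigma_skull: 0.0125
      sigma_scalp: 1.0
    source_grid:
      n_cap: 2600
      n_plane: 400
      cap_radius: 0.869
      plane_z: -0.076
    interpolation:
      pinv_rtol: 1.0e-8
      ssi_order: 4
      ssi_n_legendre: 50
      ni_neighbors: 4
"""

from __future__ import annotations

import yaml

from .forward_model import ConcentricSphereHeadModel, SourceGrid, build_source_grid

__all__ = [
    "load_config",
    "head_model_from_config",
    "source_grid_from_config",
    "interpolation_defaults",
]

_INTERP_DEFAULTS = {
    "pinv_rtol": 1e-8,
    "ssi_order": 4,
    "ssi_n_legendre": 50,
    "ni_neighbors": 4,
}


def load_config(path) -> dict:
    """Load a YAML config file into a plain dict (empty file -> {})."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root in {path} must be a mapping")
    return cfg


def _section(cfg: dict | None, name: str) -> dict:
    sec = (cfg or {}).get(name, {}) or {}
    if not isinstance(sec, dict):
        raise ValueError(f"config section {name!r} must be a mapping")
    return sec


def head_model_from_config(cfg: dict | None = None) -> ConcentricSphereHeadModel:
    return ConcentricSphereHeadModel(**_section(cfg, "head_model"))


def source_grid_from_config(cfg: dict | None = None) -> SourceGrid:
    return build_source_grid(**_section(cfg, "source_grid"))


def interpolation_defaults(cfg: dict | None = None) -> dict:
    out = dict(_INTERP_DEFAULTS)
    sec = _section(cfg, "interpolation")
    unknown = set(sec) - set(out)
    if unknown:
        raise ValueError(f"unknown interpolation options {sorted(unknown)}")
    out.update(sec)
    return out
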