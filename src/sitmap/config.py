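"""Layered YAML configuration for the command-line interface.

One file with one section per stage; every section is validated by the
corresponding module's dataclass, and omitted sections fall back to the
canonical defaults (template geometry, optimized values v2=2/v3=5/k=-0.3/
WeakenCoef=2.8, 0.45 threshold, 3x3 Gaussian).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .classify import SVMConfig
from .localize import LocalizerParams
from .optimize import ParamGrid
from .preprocess import PreprocessConfig
from .synth import SceneConfig
from .templates import DEFAULT_ANGLES, GeometryParams, TemplateValues

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    template_values: TemplateValues = field(default_factory=TemplateValues)
    localizer: LocalizerParams = field(default_factory=LocalizerParams)
    param_grid: ParamGrid = field(default_factory=ParamGrid)
    svm: SVMConfig = field(default_factory=SVMConfig)
    angles: tuple[float, ...] = DEFAULT_ANGLES
    seed: int = 0

    def to_dict(self) -> dict:
        out: dict = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if hasattr(v, "__dataclass_fields__"):
                out[f.name] = {g.name: _plain(getattr(v, g.name)) for g in fields(v)}
            else:
                out[f.name] = _plain(v)
        return out


def _plain(v):
    if isinstance(v, tuple):
        return list(v)
    return v


_SECTIONS = {
    "scene": SceneConfig,
    "preprocess": PreprocessConfig,
    "geometry": GeometryParams,
    "template_values": TemplateValues,
    "localizer": LocalizerParams,
    "param_grid": ParamGrid,
    "svm": SVMConfig,
}

_TUPLE_FIELDS = {
    "rotation_range_deg", "translation_range_px", "weight_scale_range",
    "v_medium_values", "v_strong_values", "k_values", "weaken_coef_values",
}


def load_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config; unknown sections or fields raise a named error."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        for sect, vals in overrides.items():
            raw.setdefault(sect, {}).update(vals)

    kwargs: dict = {}
    for sect, payload in raw.items():
        if sect in ("seed",):
            kwargs["seed"] = int(payload)
            continue
        if sect == "angles":
            kwargs["angles"] = tuple(float(a) for a in payload)
            continue
        cls = _SECTIONS.get(sect)
        if cls is None:
            raise ValueError(f"unknown config section: {sect!r}")
        valid = {f.name for f in fields(cls)}
        unknown = set(payload) - valid
        if unknown:
            raise ValueError(f"invalid {sect} config: unknown fields {sorted(unknown)}")
        payload = {k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
                   for k, v in payload.items()}
        try:
            kwargs[sect] = cls(**payload)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid {sect} config: {exc}") from None
    return RunConfig(**kwargs)
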