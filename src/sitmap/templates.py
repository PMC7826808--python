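"""Hip templates: signed reward/penalty grids for correlation localization.

A template encodes the expected seated-pressure footprint: two hip discs of
radius ``r1`` separated by ``d``, a caudal disc of radius ``r2`` offset ``h``
toward the seat rear, forward thigh rectangles of length ``l``, and — since
there is no pressure behind a seated body — a negative "half-runway" penalty
band of thickness ``c`` wrapped around the rear of the discs, its magnitude
growing linearly with distance from the disc boundary (slope ``k``).

Reward pixels are tiered weak/medium/strong.  The three candidate
high-pressure sites (left-hip core, right-hip core, caudal disc, all of
radius ``r2``) rarely peak simultaneously, so four variants distribute the
strong tier differently:

* variant 1 — strong at both hip cores and the caudal disc (the baseline);
* variant 2 — strong at the left-hip core only;
* variant 3 — strong at the right-hip core only;
* variant 4 — strong at the caudal disc only;

with the remaining candidate sites at the medium tier and the rest of the
reward area weak.  Variants 2–4 have their reward pixels rescaled by one
scalar each so all four reward sums match variant 1's, giving every variant
the same weight in the correlation.  Each variant is rotated through a set
of angles (default −40°…40° in 10° steps → 36 templates) by re-rasterizing
the rotated analytic geometry, which keeps the reward/penalty/neutral sign
partition crisp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "GeometryParams",
    "TemplateValues",
    "HipTemplate",
    "TemplateBank",
    "DEFAULT_ANGLES",
    "build_variant",
    "equalize_reward_sums",
    "rotate_template",
    "build_bank",
]

#: Default rotation angles of the bank (degrees).
DEFAULT_ANGLES = (-40.0, -30.0, -20.0, -10.0, 0.0, 10.0, 20.0, 30.0, 40.0)


@dataclass(frozen=True)
class GeometryParams:
    """Template geometry in pixels, sized for an average adult."""

    r1: int = 7   # hip disc radius
    r2: int = 3   # strong-site (core / caudal) radius
    d: int = 12   # hip-center separation
    c: int = 4    # penalty band thickness
    h: int = 3    # caudal disc offset behind the hip line
    l: int = 9    # forward thigh-rectangle length

    def __post_init__(self) -> None:
        if not (0 < self.r2 < self.r1):
            raise ValueError("need 0 < r2 < r1")
        if min(self.d, self.c, self.h, self.l) <= 0:
            raise ValueError("geometry parameters must be positive")


@dataclass(frozen=True)
class TemplateValues:
    """Reward-tier values and penalty slope.

    ``v_weak`` is the fixed reference (1): scaling all values together only
    rescales every correlation response, so it carries no information.
    ``k`` is the (nonpositive) per-pixel slope of the penalty band.
    """

    v_weak: float = 1.0
    v_medium: float = 2.0
    v_strong: float = 5.0
    k: float = -0.3

    def __post_init__(self) -> None:
        if not (self.v_weak <= self.v_medium <= self.v_strong):
            raise ValueError("need v_weak <= v_medium <= v_strong")
        if self.k > 0:
            raise ValueError("penalty slope k must be <= 0")


@dataclass
class HipTemplate:
    values: np.ndarray                    # signed grid: >0 reward, <0 penalty, 0 neutral
    variant_id: int
    angle_deg: float
    anchor: tuple[int, int]               # rotation center within the grid
    left_hip_offset: tuple[float, float]  # (row, col) relative to anchor
    right_hip_offset: tuple[float, float]
    caudal_offset: tuple[float, float]
    reward_scale: float = 1.0
    geom: GeometryParams | None = None
    vals: TemplateValues | None = None

    def reward_sum(self) -> float:
        return float(self.values[self.values > 0].sum())


@dataclass
class TemplateBank:
    templates: list[HipTemplate]
    angles: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.templates)


def _rotate_offset(dr: float, dc: float, angle_deg: float) -> tuple[float, float]:
    th = math.radians(angle_deg)
    return (dr * math.cos(th) - dc * math.sin(th), dr * math.sin(th) + dc * math.cos(th))


@lru_cache(maxsize=512)
def _rasterize(geom: GeometryParams, angle_deg: float) -> dict:
    """Rasterize the rotated analytic geometry into region masks.

    Masks depend only on geometry and angle, not on tier values, so they are
    cached: a value grid for any (variant, TemplateValues) combination is a
    cheap linear assembly of these masks.  A pixel belongs to a region iff
    its center lies inside the analytic region; boundary ties go to the
    higher-priority region (cores > reward > penalty).
    """
    r1, r2, d, c, h, ell = geom.r1, geom.r2, geom.d, geom.c, geom.h, geom.l
    half_d = d / 2.0

    # Canonical centers (row, col) relative to the anchor (hip midpoint).
    sites = {"left": (0.0, -half_d), "right": (0.0, +half_d), "caudal": (float(h), 0.0)}

    # Bounding box of the rotated geometry: disc centers +- (radius + c) and
    # the rotated thigh-rectangle corners, plus a 1 px margin.
    pts = []
    for (sr, sc), rad in (((0.0, -half_d), r1 + c), ((0.0, half_d), r1 + c), ((float(h), 0.0), r2 + c)):
        rr, rc = _rotate_offset(sr, sc, angle_deg)
        pts += [(rr - rad, rc - rad), (rr + rad, rc + rad)]
    for sign in (-1.0, 1.0):
        for corner in ((-(r1 + ell), sign * half_d - r1), (-(r1 + ell), sign * half_d + r1),
                       (0.0, sign * half_d - r1), (0.0, sign * half_d + r1)):
            pts.append(_rotate_offset(*corner, angle_deg))
    rows = [p[0] for p in pts]
    cols = [p[1] for p in pts]
    r_lo, r_hi = math.floor(min(rows)) - 1, math.ceil(max(rows)) + 1
    c_lo, c_hi = math.floor(min(cols)) - 1, math.ceil(max(cols)) + 1
    anchor = (-r_lo, -c_lo)

    gr, gc = np.meshgrid(np.arange(r_lo, r_hi + 1, dtype=float),
                         np.arange(c_lo, c_hi + 1, dtype=float), indexing="ij")
    # Inverse-rotate pixel offsets into the canonical frame.
    th = math.radians(angle_deg)
    cr = gr * math.cos(th) + gc * math.sin(th)
    cc = -gr * math.sin(th) + gc * math.cos(th)

    def disc(center: tuple[float, float], radius: float) -> np.ndarray:
        return (cr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2

    cores = {
        "left": disc(sites["left"], r2),
        "right": disc(sites["right"], r2),
        "caudal": disc(sites["caudal"], r2),
    }
    hip_discs = disc(sites["left"], r1) | disc(sites["right"], r1)
    thighs = np.zeros_like(hip_discs)
    for sign in (-1.0, 1.0):
        thighs |= (cr <= 0) & (cr >= -(r1 + ell)) & (np.abs(cc - sign * half_d) <= r1)
    reward = hip_discs | thighs | cores["caudal"]

    # Penalty: within distance c outside the union of the three discs, rear
    # half-plane only (no penalty across the forward thigh rectangles).
    dist_out = np.minimum.reduce([
        np.hypot(cr - sites["left"][0], cc - sites["left"][1]) - r1,
        np.hypot(cr - sites["right"][0], cc - sites["right"][1]) - r1,
        np.hypot(cr - sites["caudal"][0], cc - sites["caudal"][1]) - r2,
    ])
    penalty = (~reward) & (cr >= 0) & (dist_out > 0) & (dist_out <= c)

    offsets = {name: _rotate_offset(*pos, angle_deg) for name, pos in sites.items()}
    return {
        "anchor": anchor,
        "cores": cores,
        "reward": reward,
        "penalty": penalty,
        "penalty_dist": np.where(penalty, dist_out, 0.0),
        "offsets": offsets,
    }


_STRONG_SITES = {1: ("left", "right", "caudal"), 2: ("left",), 3: ("right",), 4: ("caudal",)}


def build_variant(geom: GeometryParams, vals: TemplateValues, variant_id: int,
                  angle_deg: float = 0.0) -> HipTemplate:
    """Rasterize one template variant at the given rotation angle."""
    if variant_id not in _STRONG_SITES:
        raise ValueError(f"unknown variant: {variant_id}")
    if abs(angle_deg) > 45:
        raise ValueError("rotation angle must be within [-45, 45] degrees")
    reg = _rasterize(geom, float(angle_deg))

    strong = np.zeros_like(reg["reward"])
    for site in _STRONG_SITES[variant_id]:
        strong |= reg["cores"][site]
    medium = np.zeros_like(strong)
    for site in ("left", "right", "caudal"):
        if site not in _STRONG_SITES[variant_id]:
            medium |= reg["cores"][site]
    medium &= ~strong
    weak = reg["reward"] & ~strong & ~medium

    values = (vals.v_strong * strong + vals.v_medium * medium + vals.v_weak * weak
              + vals.k * reg["penalty_dist"])
    return HipTemplate(
        values=values,
        variant_id=variant_id,
        angle_deg=float(angle_deg),
        anchor=reg["anchor"],
        left_hip_offset=reg["offsets"]["left"],
        right_hip_offset=reg["offsets"]["right"],
        caudal_offset=reg["offsets"]["caudal"],
        geom=geom,
        vals=vals,
    )


def equalize_reward_sums(templates: list[HipTemplate]) -> list[HipTemplate]:
    """Scale reward pixels of templates 2..n so all reward sums equal the
    first template's; penalty pixels are untouched."""
    if not templates:
        raise ValueError("no templates")
    ref = templates[0].reward_sum()
    out = []
    for i, tpl in enumerate(templates):
        s = tpl.reward_sum()
        if s <= 0:
            raise ValueError("degenerate template: zero reward sum")
        scale = 1.0 if i == 0 else ref / s
        values = np.where(tpl.values > 0, tpl.values * scale, tpl.values)
        out.append(HipTemplate(values, tpl.variant_id, tpl.angle_deg, tpl.anchor,
                               tpl.left_hip_offset, tpl.right_hip_offset, tpl.caudal_offset,
                               reward_scale=tpl.reward_scale * scale, geom=tpl.geom, vals=tpl.vals))
    return out


def rotate_template(tpl: HipTemplate, angle_deg: float) -> HipTemplate:
    """Rotate rigidly about the anchor by re-rasterizing the rotated analytic
    geometry (not by resampling pixels); the reward-equalization scale is
    re-applied, so reward sums drift only by re-rasterization (< 1 %)."""
    if tpl.geom is None or tpl.vals is None:
        raise ValueError("template lacks analytic geometry; cannot rotate")
    fresh = build_variant(tpl.geom, tpl.vals, tpl.variant_id, angle_deg)
    values = np.where(fresh.values > 0, fresh.values * tpl.reward_scale, fresh.values)
    return HipTemplate(values, fresh.variant_id, fresh.angle_deg, fresh.anchor,
                       fresh.left_hip_offset, fresh.right_hip_offset, fresh.caudal_offset,
                       reward_scale=tpl.reward_scale, geom=tpl.geom, vals=tpl.vals)


def build_bank(geom: GeometryParams | None = None, vals: TemplateValues | None = None,
               angles: tuple[float, ...] = DEFAULT_ANGLES) -> TemplateBank:
    """Build the rotated template bank: 4 variants x |angles| templates,
    ordered variant-major, angle-minor."""
    geom = geom or GeometryParams()
    vals = vals or TemplateValues()
    if len(angles) == 0:
        raise ValueError("no angles")
    base = [build_variant(geom, vals, v) for v in (1, 2, 3, 4)]
    base = equalize_reward_sums(base)
    templates = [rotate_template(tpl, a) for tpl in base for a in angles]
    # Re-rasterization at different angles changes reward pixel counts by a
    # few percent (axis-aligned boundaries at 0° pass exactly through pixel
    # centers), which would bias the argmax toward angles with larger sums.
    # Equal correlation weight is the point of equalization, so it is
    # enforced across the whole bank, not just across variants.
    ref = base[0].reward_sum()
    for i, tpl in enumerate(templates):
        templates[i] = _scale_reward(tpl, ref / tpl.reward_sum())
    return TemplateBank(templates=templates, angles=tuple(float(a) for a in angles))


def _scale_reward(tpl: HipTemplate, scale: float) -> HipTemplate:
    values = np.where(tpl.values > 0, tpl.values * scale, tpl.values)
    return HipTemplate(values, tpl.variant_id, tpl.angle_deg, tpl.anchor,
                       tpl.left_hip_offset, tpl.right_hip_offset, tpl.caudal_offset,
                       reward_scale=tpl.reward_scale * scale, geom=tpl.geom, vals=tpl.vals)
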