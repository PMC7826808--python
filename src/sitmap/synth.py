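"""Synthetic seat pressure scenes with ground-truth hip annotations.

The generator paints the qualitative structure of a seated adult on a 32x32
sensor grid: two high-pressure ischial ("hip") blobs about 12 px apart, a
smaller coccyx ("caudal") blob 3 px behind their midpoint, a forward thigh
ridge, and nothing behind the body support — plus sensor noise and isolated
spike pixels off the body for the preprocessing mask to remove.  The whole
body is rotated rigidly (±40°, matching how far a person can turn on an
armchair) and translated, and per-subject weight scaling multiplies the
image globally.

Blobs are truncated Gaussians: smooth, unimodal, and analytically
controlled, so regional mass orderings per posture hold exactly in the
noise-free limit.  Posture drives the left/right/caudal mass balance
(lean_left boosts the left hip, lean_back the caudal region, upright is
balanced); leg-crossed variations unbalance the thigh ridge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .io import POSTURES, VARIATIONS, AnnotatedSample, PressureImage

__all__ = ["SceneConfig", "generate_scene", "generate_dataset", "study_dataset"]

# Peak amplitudes of the canonical (unit-weight, upright) body, arbitrary
# sensor units.  The caudal peak depends on which region is high-pressure in
# the given frame: coccyx and ischial high-pressure states generally do not
# co-occur.
_HIP_AMP = 1.0
_CAUDAL_AMP = {"hips": 0.45, "caudal": 1.25}
_THIGH_AMP = 0.25
# Probability the caudal region is the high-pressure one under "mixed" mode:
# leaning back tilts the pelvis posteriorly and loads the coccyx.
_P_CAUDAL_HIGH = {"upright": 0.10, "lean_left": 0.10, "lean_right": 0.10, "lean_back": 0.85}
# Posture multipliers on (left hip, right hip, caudal, thigh) masses.
_POSTURE_MULT = {
    "upright": (1.0, 1.0, 1.0, 1.0),
    "lean_left": (1.5, 0.6, 0.9, 1.0),
    "lean_right": (0.6, 1.5, 0.9, 1.0),
    "lean_back": (0.85, 0.85, 1.7, 0.7),
}
# Thigh multipliers (left leg, right leg) per variation; a crossed leg lifts
# that thigh off the seat.
_VARIATION_THIGH = {
    "normal": (1.0, 1.0),
    "left_leg_crossed": (0.45, 1.25),
    "right_leg_crossed": (1.25, 0.45),
}


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, intensity and randomness settings for one synthetic scene.

    Defaults mirror the template geometry (hip separation 12 px, hip radius
    7 px, caudal offset 3 px, thigh length 9 px) and the acquisition ranges
    (rotation −40°…40°).  Degenerate ranges (lo == hi) pin a value, which is
    how tests request exact rotations or zero translation.
    """

    grid_size: int = 32
    hip_separation_px: float = 12.0
    hip_blob_radius_px: float = 7.0
    caudal_blob_radius_px: float = 3.0
    caudal_offset_px: float = 3.0
    thigh_length_px: float = 9.0
    rotation_range_deg: tuple[float, float] = (-40.0, 40.0)
    translation_range_px: tuple[float, float] = (-2.0, 2.0)
    weight_scale_range: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 0.02
    spike_rate: float = 1.5
    high_pressure_mode: str = "mixed"
    posture: str = "upright"
    variation: str = "normal"
    pixel_pitch_mm: float = 11.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0 < self.weight_scale_range[0] <= self.weight_scale_range[1]):
            raise ValueError("weight_scale_range must be positive")
        if self.high_pressure_mode not in ("hips", "caudal", "mixed"):
            raise ValueError(f"unknown high_pressure_mode: {self.high_pressure_mode!r}")
        if self.posture not in POSTURES:
            raise ValueError(f"unknown class: {self.posture!r}")
        if self.variation not in VARIATIONS:
            raise ValueError(f"unknown variation: {self.variation!r}")


def _rot(dr: float, dc: float, angle_deg: float) -> tuple[float, float]:
    th = math.radians(angle_deg)
    return (dr * math.cos(th) - dc * math.sin(th), dr * math.sin(th) + dc * math.cos(th))


def _check_fit(cfg: SceneConfig, center: tuple[float, float]) -> None:
    # The annotated structures (hip discs + caudal disc) must fit the grid at
    # any rotation; the thigh ridge may clip at the seat-front edge, as real
    # knees extend past the sensor.
    reach = max(cfg.hip_separation_px / 2 + cfg.hip_blob_radius_px,
                cfg.caudal_offset_px + cfg.caudal_blob_radius_px)
    r, c = center
    n = cfg.grid_size
    if r - reach < 0 or r + reach > n - 1 or c - reach < 0 or c + reach > n - 1:
        raise ValueError("scene out of bounds")


def _paint_body(cfg: SceneConfig, center: tuple[float, float], angle_deg: float,
                caudal_high: bool, amp_jitter: tuple[float, float, float] = (1.0, 1.0, 1.0),
                ) -> tuple[np.ndarray, tuple[float, float], tuple[float, float]]:
    """Rasterize the noise-free body; returns (grid, left hip, right hip)."""
    n = cfg.grid_size
    half_d = cfg.hip_separation_px / 2.0
    mult_l, mult_r, mult_c, mult_t = _POSTURE_MULT[cfg.posture]
    thigh_l, thigh_r = _VARIATION_THIGH[cfg.variation]
    jl, jr, jc = amp_jitter

    rows, cols = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float), indexing="ij")
    # Inverse-rotate pixel offsets into the canonical (unrotated) body frame.
    dr, dc = rows - center[0], cols - center[1]
    th = math.radians(angle_deg)
    cr = dr * math.cos(th) + dc * math.sin(th)
    cc = -dr * math.sin(th) + dc * math.cos(th)

    out = np.zeros((n, n))

    def blob(center_rc: tuple[float, float], radius: float, amp: float,
             core: bool = False) -> None:
        # Broad soft-tissue base; hip blobs add a sharp central peak from the
        # ischial bone (the steep spike the localizer's weakening step clips).
        d2 = (cr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2
        sigma = radius / 2.5
        p = 0.6 * np.exp(-d2 / (2 * sigma**2))
        if core:
            p += 0.8 * np.exp(-d2 / (2 * (radius / 4.5) ** 2))
        p /= 1.4 if core else 0.6  # peak value at the center equals amp
        out[d2 <= radius**2] += amp * p[d2 <= radius**2]

    caudal_amp = _CAUDAL_AMP["caudal" if caudal_high else "hips"]
    blob((0.0, -half_d), cfg.hip_blob_radius_px, _HIP_AMP * mult_l * jl, core=True)
    blob((0.0, +half_d), cfg.hip_blob_radius_px, _HIP_AMP * mult_r * jr, core=True)
    blob((cfg.caudal_offset_px, 0.0), cfg.caudal_blob_radius_px, caudal_amp * mult_c * jc)

    # Thigh ridge: forward rectangles with a smooth lateral (cosine) profile
    # and linear decay toward the knees.
    r1, ell = cfg.hip_blob_radius_px, cfg.thigh_length_px
    for sign, leg_mult in ((-1.0, thigh_l), (+1.0, thigh_r)):
        lat = np.abs(cc - sign * half_d)
        ahead = (cr <= 0) & (cr >= -(r1 + ell)) & (lat <= r1)
        profile = np.cos(0.5 * np.pi * lat / r1) * (1.0 - 0.5 * np.abs(cr) / (r1 + ell))
        out[ahead] += _THIGH_AMP * mult_t * leg_mult * profile[ahead]

    lh = (center[0] + _rot(0.0, -half_d, angle_deg)[0], center[1] + _rot(0.0, -half_d, angle_deg)[1])
    rh = (center[0] + _rot(0.0, +half_d, angle_deg)[0], center[1] + _rot(0.0, +half_d, angle_deg)[1])
    return out, lh, rh


def generate_scene(cfg: SceneConfig, rng: np.random.Generator | None = None,
                   weight_scale: float | None = None) -> AnnotatedSample:
    """Generate one annotated scene.

    Rotation, translation and (unless given) weight scale are drawn uniformly
    from the configured ranges.  The hip annotation equals the blob centers
    used to paint the image.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    angle = float(rng.uniform(*cfg.rotation_range_deg))
    t_r = float(rng.uniform(*cfg.translation_range_px))
    t_c = float(rng.uniform(*cfg.translation_range_px))
    if weight_scale is None:
        weight_scale = float(rng.uniform(*cfg.weight_scale_range))

    if cfg.high_pressure_mode == "mixed":
        caudal_high = bool(rng.random() < _P_CAUDAL_HIGH[cfg.posture])
    else:
        caudal_high = cfg.high_pressure_mode == "caudal"

    variation = cfg.variation
    eff_cfg = cfg
    jitter = (1.0, 1.0, 1.0)
    if variation == "free":
        # Unconstrained pose: one of the three concrete variations plus mild
        # amplitude jitter.
        eff_cfg = replace(cfg, variation=str(rng.choice(["normal", "left_leg_crossed", "right_leg_crossed"])))
        jitter = tuple(rng.uniform(0.9, 1.1, size=3))

    center = ((cfg.grid_size - 1) / 2 + 0.5 + t_r, (cfg.grid_size - 1) / 2 + 0.5 + t_c)
    _check_fit(cfg, center)

    body, lh, rh = _paint_body(eff_cfg, center, angle, caudal_high, jitter)
    img = body * weight_scale

    if cfg.noise_sd > 0:
        img = img + np.clip(rng.normal(0.0, cfg.noise_sd * weight_scale, img.shape), 0.0, None)
        # Isolated spike pixels off the body (external interference).
        n_spikes = rng.poisson(cfg.spike_rate)
        empty = np.argwhere(body == 0)
        if n_spikes > 0 and len(empty) > 0:
            idx = rng.choice(len(empty), size=min(n_spikes, len(empty)), replace=False)
            for r, c in empty[idx]:
                img[r, c] += rng.uniform(0.3, 0.8) * weight_scale

    return AnnotatedSample(
        image=PressureImage(img, cfg.pixel_pitch_mm),
        left_hip=lh,
        right_hip=rh,
        posture=cfg.posture,
        variation=variation,
        subject_id="S00",
        rotation_deg=angle,
    )


def generate_dataset(n_per_cell: int, cfg: SceneConfig | None = None, subjects: int = 1,
                     seed: int = 0, variations: tuple[str, ...] = VARIATIONS,
                     postures: tuple[str, ...] = POSTURES) -> list[AnnotatedSample]:
    """Generate a balanced dataset: ``n_per_cell`` scenes per
    (subject, posture, variation) cell, with one weight scale per subject.
    """
    if n_per_cell < 1 or subjects < 1:
        raise ValueError("n_per_cell and subjects must be >= 1")
    base = cfg if cfg is not None else SceneConfig()
    rng = np.random.default_rng(seed)
    out: list[AnnotatedSample] = []
    for s in range(subjects):
        weight = float(rng.uniform(*base.weight_scale_range))
        sid = f"S{s:02d}"
        for posture in postures:
            for variation in variations:
                for _ in range(n_per_cell):
                    scene_cfg = replace(base, posture=posture, variation=variation)
                    sample = generate_scene(scene_cfg, rng, weight_scale=weight)
                    sample.subject_id = sid
                    out.append(sample)
    return out


def study_dataset(seed: int = 0, cfg: SceneConfig | None = None) -> list[AnnotatedSample]:
    """The full acquisition design: 10 subjects x 4 postures x 20 images
    (5 normal + 5 left-leg-crossed + 5 right-leg-crossed + 5 free) = 800.
    """
    return generate_dataset(n_per_cell=5, cfg=cfg, subjects=10, seed=seed)
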