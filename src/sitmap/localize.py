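"""Hip localization by template correlation.

Steps: (1) weaken the preprocessed image by clamping it at a multiple of the
mean pressure of the pressure area, which flattens bony pressure spikes;
(2) cross-correlate with every template in the bank (zero padding: off the
sensor there is no pressure); (3) take the global argmax over all
(template, position) pairs; (4) read the left/right hip and caudal positions
off the winning template's rotated offsets.

Ties in the argmax are broken deterministically: smaller |angle| first
(biased toward the commonest, unrotated sitting case), then ascending signed
angle, then lower variant id, then row-major position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import PressureImage
from .templates import HipTemplate, TemplateBank

__all__ = ["LocalizerParams", "HipLocalization", "weaken", "response_map", "locate_hips"]


@dataclass(frozen=True)
class LocalizerParams:
    weaken_coef: float = 2.8

    def __post_init__(self) -> None:
        if not self.weaken_coef > 0:
            raise ValueError("weaken_coef must be positive")


@dataclass
class HipLocalization:
    left_hip: tuple[float, float]
    right_hip: tuple[float, float]
    caudal: tuple[float, float]
    angle_deg: float
    variant_id: int
    score: float
    anchor_pos: tuple[int, int] = (0, 0)


def weaken(img: PressureImage, weaken_coef: float = 2.8) -> PressureImage:
    """Clamp every pixel at ``weaken_coef`` x the mean of the pressure area
    (strictly positive pixels).  Zeros stay zero."""
    v = img.values
    positive = v[v > 0]
    if positive.size == 0:
        raise ValueError("empty pressure image")
    cap = positive.mean() * weaken_coef
    return PressureImage(np.minimum(v, cap), img.pixel_pitch_mm)


def response_map(img: PressureImage, tpl: HipTemplate) -> np.ndarray:
    """Cross-correlation response, same size as the image, zero-padded.

    ``response[i, j] = sum_{u,v} img[i + u - a_r, j + v - a_c] * tpl[u, v]``
    where ``(a_r, a_c)`` is the template anchor: the response at a position
    is the template's score when its anchor sits on that pixel.
    """
    full = signal.correlate(img.values, tpl.values, mode="full", method="fft")
    tr, tc = tpl.values.shape
    ar, ac = tpl.anchor
    h, w = img.values.shape
    return full[tr - 1 - ar: tr - 1 - ar + h, tc - 1 - ac: tc - 1 - ac + w]


def locate_hips(img: PressureImage, bank: TemplateBank,
                params: LocalizerParams | None = None) -> HipLocalization:
    """Weaken the image, then find the (template, position) pair with the
    maximal correlation response over the whole bank."""
    params = params or LocalizerParams()
    weakened = weaken(img, params.weaken_coef)

    order = sorted(range(len(bank.templates)),
                   key=lambda i: (abs(bank.templates[i].angle_deg),
                                  bank.templates[i].angle_deg,
                                  bank.templates[i].variant_id))
    best_score = -np.inf
    best: tuple[HipTemplate, int, int] | None = None
    for i in order:
        tpl = bank.templates[i]
        resp = response_map(weakened, tpl)
        flat = int(np.argmax(resp))           # row-major first occurrence
        score = float(resp.flat[flat])
        if score > best_score:
            best_score = score
            best = (tpl, *np.unravel_index(flat, resp.shape))
    assert best is not None
    tpl, r, c = best
    return HipLocalization(
        left_hip=(r + tpl.left_hip_offset[0], c + tpl.left_hip_offset[1]),
        right_hip=(r + tpl.right_hip_offset[0], c + tpl.right_hip_offset[1]),
        caudal=(r + tpl.caudal_offset[0], c + tpl.caudal_offset[1]),
        angle_deg=tpl.angle_deg,
        variant_id=tpl.variant_id,
        score=best_score,
        anchor_pos=(int(r), int(c)),
    )
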