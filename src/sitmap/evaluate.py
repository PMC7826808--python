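"""Localization accuracy statistics.

Per image, the deviation of each hip is the Euclidean pixel distance between
the predicted and marked center, and the *maximum positioning deviation* is
the larger of the two.  The report aggregates: a histogram over unit pixel
intervals with its cumulative curve, per-subject and per-rotation-bucket
proportions of images with maximum deviation below 3 px, and the mean
deviation.  Rotation buckets use |ground-truth angle|: small [0, 15),
medium [15, 30), large [30, 45] degrees.  Pixel deviations convert to
physical distance via the sensor pitch (11.5 mm per pixel by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import AnnotatedSample
from .localize import HipLocalization

__all__ = ["DeviationReport", "deviation_report", "px_to_cm", "ANGLE_BUCKETS"]

ANGLE_BUCKETS = ("0-15", "15-30", "30-45")
_GOOD_PX = 3.0  # "maximum deviation less than three pixels" (strict)


@dataclass
class DeviationReport:
    per_image: list[tuple[float, float, float]]  # (dist_l, dist_r, max_dev) px
    mean_deviation_px: float
    histogram: list[int]                 # counts per [i, i+1) px interval
    cumulative: list[float]              # running proportions, ends at 1
    per_subject: dict[str, float]        # proportion(max_dev < 3 px)
    per_angle_range: dict[str, float]
    proportion_below_3px: float


def _bucket(rotation_deg: float) -> str:
    a = abs(rotation_deg)
    if a < 15:
        return "0-15"
    if a < 30:
        return "15-30"
    return "30-45"


def deviation_report(samples: list[AnnotatedSample],
                     predictions: list[HipLocalization]) -> DeviationReport:
    """Aggregate deviation statistics for aligned (sample, prediction) pairs."""
    if len(samples) != len(predictions):
        raise ValueError("unaligned predictions")
    if not samples:
        raise ValueError("no samples")

    per_image = []
    for s, p in zip(samples, predictions):
        dl = math.dist(p.left_hip, s.left_hip)
        dr = math.dist(p.right_hip, s.right_hip)
        per_image.append((dl, dr, max(dl, dr)))

    n = len(per_image)
    mean_dev = sum(dl + dr for dl, dr, _ in per_image) / (2 * n)
    max_devs = [m for _, _, m in per_image]

    n_bins = int(math.floor(max(max_devs))) + 1
    histogram = [0] * n_bins
    for m in max_devs:
        histogram[int(math.floor(m))] += 1
    cumulative = list(np.cumsum(histogram) / n)

    def proportion(devs: list[float]) -> float:
        return sum(1 for m in devs if m < _GOOD_PX) / len(devs)

    per_subject: dict[str, list[float]] = {}
    per_angle: dict[str, list[float]] = {}
    for s, (_, _, m) in zip(samples, per_image):
        per_subject.setdefault(s.subject_id, []).append(m)
        per_angle.setdefault(_bucket(s.rotation_deg), []).append(m)

    return DeviationReport(
        per_image=per_image,
        mean_deviation_px=mean_dev,
        histogram=histogram,
        cumulative=cumulative,
        per_subject={k: proportion(v) for k, v in sorted(per_subject.items())},
        per_angle_range={k: proportion(v) for k, v in per_angle.items()},
        proportion_below_3px=proportion(max_devs),
    )


def px_to_cm(deviation_px: float, pixel_pitch_mm: float = 11.5) -> float:
    """Convert a pixel deviation to centimetres (3 significant figures)."""
    if not pixel_pitch_mm > 0:
        raise ValueError("pixel pitch must be positive")
    cm = deviation_px * pixel_pitch_mm / 10.0
    if cm == 0:
        return 0.0
    return float(f"{cm:.3g}")
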