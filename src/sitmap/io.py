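"""Reading and writing pressure images and annotation records.

A pressure image is a plain-text delimited matrix (``*.pmat``), one image per
file, comma- or whitespace-separated, no header.  Annotations (``*.ann``) are
JSON records, one per line, referencing the image file by a path relative to
the annotation file.

Coordinate convention used throughout the package: 0-based ``(row, col)``;
row 0 is the seat-front edge (toward the knees), rows increase toward the
seat rear; the subject's left hip lies on the smaller-column side.
Coordinates are stored as reals — manual marks and rotated-template geometry
are naturally sub-pixel even though correlation argmaxes land on pixels.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

__all__ = [
    "POSTURES",
    "VARIATIONS",
    "PressureImage",
    "AnnotatedSample",
    "read_pressure_image",
    "write_pressure_image",
    "read_annotations",
    "write_annotations",
]

#: The four posture classes.
POSTURES = ("upright", "lean_back", "lean_left", "lean_right")

#: Within-posture variations ("free" = unconstrained pose of one of the three).
VARIATIONS = ("normal", "left_leg_crossed", "right_leg_crossed", "free")

#: Physical center-to-center sensor spacing in millimetres.
DEFAULT_PIXEL_PITCH_MM = 11.5


@dataclass
class PressureImage:
    """A nonnegative pressure grid with a physical pixel pitch.

    Raw images carry sensor counts; after preprocessing the grid is unitless
    and L1-normalized (sums to 1).
    """

    values: np.ndarray
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("pressure image must be a 2-D grid")
        if np.any(v < 0):
            raise ValueError("negative pressure")
        if not (self.pixel_pitch_mm > 0):
            raise ValueError("pixel pitch must be positive")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def scaled(self, factor: float) -> "PressureImage":
        """Return a copy with all values multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return PressureImage(self.values * factor, self.pixel_pitch_mm)


@dataclass
class AnnotatedSample:
    """A pressure image with ground-truth hip marks and a posture label."""

    image: PressureImage
    left_hip: tuple[float, float]
    right_hip: tuple[float, float]
    posture: str
    variation: str = "normal"
    subject_id: str = "S00"
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.posture not in POSTURES:
            raise ValueError(f"unknown class: {self.posture!r}")
        if self.variation not in VARIATIONS:
            raise ValueError(f"unknown variation: {self.variation!r}")
        h, w = self.image.shape
        for name, (r, c) in (("left_hip", self.left_hip), ("right_hip", self.right_hip)):
            if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
                raise ValueError(f"annotation out of bounds: {name}=({r}, {c})")
        if abs(self.rotation_deg) < 45.0 and not self.left_hip[1] < self.right_hip[1]:
            raise ValueError("left hip must lie on the smaller-column side")
        self.left_hip = (float(self.left_hip[0]), float(self.left_hip[1]))
        self.right_hip = (float(self.right_hip[0]), float(self.right_hip[1]))


def read_pressure_image(path: str | os.PathLike, pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM) -> PressureImage:
    """Read a plain-text delimited matrix into a :class:`PressureImage`."""
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"malformed value in {path}: {exc}") from None
    if not rows:
        raise ValueError(f"empty image file: {path}")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"ragged matrix in {path}")
    arr = np.asarray(rows, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"negative pressure in {path}")
    return PressureImage(arr, pixel_pitch_mm)


def write_pressure_image(img: PressureImage, path: str | os.PathLike) -> str:
    """Write an image as plain text at full precision; returns the path."""
    np.savetxt(path, img.values, fmt="%.17g")
    return os.fspath(path)


def write_annotations(samples: list[AnnotatedSample], ann_path: str | os.PathLike,
                      image_dir: str | os.PathLike | None = None) -> str:
    """Write samples as one JSON record per line plus one ``.pmat`` per image.

    Image files are named ``img_<index>.pmat`` under ``image_dir`` (default:
    the annotation file's directory) and referenced by relative path.
    """
    ann_path = os.fspath(ann_path)
    base = os.path.dirname(os.path.abspath(ann_path))
    image_dir = base if image_dir is None else os.fspath(image_dir)
    os.makedirs(image_dir, exist_ok=True)
    with open(ann_path, "w") as fh:
        for i, s in enumerate(samples):
            img_path = os.path.join(image_dir, f"img_{i:04d}.pmat")
            write_pressure_image(s.image, img_path)
            rec = {
                "image": os.path.relpath(img_path, base),
                "left_hip": list(s.left_hip),
                "right_hip": list(s.right_hip),
                "posture": s.posture,
                "variation": s.variation,
                "subject_id": s.subject_id,
                "rotation_deg": s.rotation_deg,
            }
            fh.write(json.dumps(rec) + "\n")
    return ann_path


def read_annotations(path: str | os.PathLike) -> list[AnnotatedSample]:
    """Read an annotation file; every record is validated on construction."""
    path = os.fspath(path)
    base = os.path.dirname(os.path.abspath(path))
    samples: list[AnnotatedSample] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from None
            img = read_pressure_image(os.path.join(base, rec["image"]))
            samples.append(
                AnnotatedSample(
                    image=img,
                    left_hip=tuple(rec["left_hip"]),
                    right_hip=tuple(rec["right_hip"]),
                    posture=rec["posture"],
                    variation=rec.get("variation", "normal"),
                    subject_id=rec.get("subject_id", "S00"),
                    rotation_deg=float(rec.get("rotation_deg", 0.0)),
                )
            )
    return samples
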