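"""Template-parameter optimization by exhaustive grid search.

The free parameters are the medium/strong reward values, the penalty slope
``k`` and the weakening coefficient (the weak value is the fixed reference
1).  The objective is the mean localization deviation

    J = sum_i (dist_l_i + dist_r_i) / (2 N)

over an annotated dataset, with ``dist`` the Euclidean pixel distance
between predicted and marked hip, left-to-left and right-to-right.  The
objective is piecewise constant in the parameters (the argmax moves in
jumps), so gradient methods do not apply and every valid grid combination is
evaluated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .io import AnnotatedSample, PressureImage
from .localize import LocalizerParams, locate_hips
from .preprocess import PreprocessConfig, preprocess
from .templates import GeometryParams, TemplateBank, TemplateValues, build_bank

__all__ = ["ObjectiveReport", "ParamGrid", "evaluate_objective", "grid_search"]


@dataclass
class ObjectiveReport:
    mean_deviation_px: float
    per_image: list[tuple[float, float]]  # (dist_l, dist_r) per sample
    n: int


@dataclass(frozen=True)
class ParamGrid:
    """Candidate values per parameter; combinations violating
    ``1 <= v_medium <= v_strong`` are skipped.  Defaults bracket the
    canonical optimum (v2=2, v3=5, k=-0.3, coef=2.8)."""

    v_medium_values: tuple[float, ...] = (1.5, 2.0, 3.0)
    v_strong_values: tuple[float, ...] = (4.0, 5.0, 6.0)
    k_values: tuple[float, ...] = (-0.1, -0.3, -0.5)
    weaken_coef_values: tuple[float, ...] = (2.0, 2.8, 3.6)

    def __post_init__(self) -> None:
        for name in ("v_medium_values", "v_strong_values", "k_values", "weaken_coef_values"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"empty grid: {name}")

    def combinations(self):
        """Yield valid (TemplateValues, LocalizerParams) pairs in grid order."""
        for v2, v3, k, coef in itertools.product(
                self.v_medium_values, self.v_strong_values, self.k_values, self.weaken_coef_values):
            if not (1.0 <= v2 <= v3) or k > 0 or coef <= 0:
                continue
            yield TemplateValues(1.0, v2, v3, k), LocalizerParams(coef)


def _dists(sample: AnnotatedSample, pre: PressureImage, bank: TemplateBank,
           params: LocalizerParams) -> tuple[float, float]:
    loc = locate_hips(pre, bank, params)
    dl = math.dist(loc.left_hip, sample.left_hip)
    dr = math.dist(loc.right_hip, sample.right_hip)
    return dl, dr


def evaluate_objective(samples: list[AnnotatedSample], geom: GeometryParams | None = None,
                       vals: TemplateValues | None = None, params: LocalizerParams | None = None,
                       preprocess_cfg: PreprocessConfig | None = None,
                       _preprocessed: list[PressureImage] | None = None) -> ObjectiveReport:
    """Mean localization deviation of the pipeline on annotated samples."""
    if not samples:
        raise ValueError("no samples")
    geom = geom or GeometryParams()
    vals = vals or TemplateValues()
    params = params or LocalizerParams()
    bank = build_bank(geom, vals)
    if _preprocessed is None:
        _preprocessed = [preprocess(s.image, preprocess_cfg) for s in samples]
    per_image = [_dists(s, p, bank, params) for s, p in zip(samples, _preprocessed)]
    total = sum(dl + dr for dl, dr in per_image)
    return ObjectiveReport(mean_deviation_px=total / (2 * len(samples)),
                           per_image=per_image, n=len(samples))


def grid_search(samples: list[AnnotatedSample], grid: ParamGrid | None = None,
                geom: GeometryParams | None = None,
                preprocess_cfg: PreprocessConfig | None = None,
                ) -> tuple[TemplateValues, LocalizerParams, ObjectiveReport]:
    """Exhaustively evaluate every valid grid combination and return the
    minimizer (ties broken by earliest grid order)."""
    grid = grid or ParamGrid()
    geom = geom or GeometryParams()
    if not samples:
        raise ValueError("no samples")
    # Images are preprocessed once: preprocessing does not depend on the
    # searched parameters.  Template geometry rasterization is cached inside
    # the template module, so per-point bank builds are cheap value fills.
    preprocessed = [preprocess(s.image, preprocess_cfg) for s in samples]
    best: tuple[TemplateValues, LocalizerParams, ObjectiveReport] | None = None
    for vals, params in grid.combinations():
        report = evaluate_objective(samples, geom, vals, params, preprocess_cfg,
                                    _preprocessed=preprocessed)
        if best is None or report.mean_deviation_px < best[2].mean_deviation_px:
            best = (vals, params, report)
    if best is None:
        raise ValueError("empty grid: no valid combination")
    return best
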