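"""Posture classification from three regional pressure sums.

Features are the sums of normalized pressure over discs centered on the
localized left hip (radius 7), right hip (radius 7) and caudal vertebra
(radius 3) — because the image is L1-normalized, each feature is the
fraction of total body weight borne by that region, which is exactly what
shifts when a person leans.  Features are standardized (z-scored with the
population standard deviation) and fed to one-vs-rest support vector
machines with a polynomial, Gaussian (RBF) or sigmoid kernel; prediction is
the class with the largest decision value.  Model selection uses stratified
k-fold cross-validation (default 5 folds) and exhaustive grid search over
kernel parameters.

Standardization note: z-scoring the whole dataset before cross-validation
leaks test-fold statistics into training; by default the standardizer is
fit on each training fold only.  ``dataset_standardize=True`` restores
whole-dataset standardization.
"""

from __future__ import annotations

from dataclasses import dataclass
import itertools

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, GroupKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .io import POSTURES, AnnotatedSample, PressureImage
from .localize import HipLocalization, LocalizerParams, locate_hips
from .preprocess import PreprocessConfig, preprocess
from .templates import GeometryParams, TemplateBank, build_bank

__all__ = [
    "FeatureVector",
    "StandardizationStats",
    "SVMConfig",
    "CVResult",
    "extract_features",
    "features_from_samples",
    "fit_standardizer",
    "apply_standardizer",
    "train_ova_svm",
    "cross_validate",
    "svm_grid_search",
]

_KERNELS = ("polynomial", "gaussian", "sigmoid")


@dataclass
class FeatureVector:
    f_left: float
    f_right: float
    f_caudal: float
    standardized: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.f_left, self.f_right, self.f_caudal])


@dataclass
class StandardizationStats:
    mean: np.ndarray  # per-feature mean
    sd: np.ndarray    # per-feature population standard deviation


@dataclass(frozen=True)
class SVMConfig:
    """Kernel choice and parameters.

    polynomial: ``(beta * <x, x'> + theta) ** degree`` — needs C, beta,
    theta, degree; gaussian: ``exp(-gamma ||x - x'||^2)`` — needs C, gamma;
    sigmoid: ``tanh(beta * <x, x'> + theta)`` — needs C, beta, theta.
    """

    kernel: str = "polynomial"
    C: float = 1.3
    beta: float = 1.4
    theta: float = 0.8
    degree: int = 3
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if self.kernel not in _KERNELS:
            raise ValueError(f"unknown kernel: {self.kernel!r}")
        if not self.C > 0:
            raise ValueError("C must be positive")

    def _svc(self) -> SVC:
        common = dict(C=self.C, tol=1e-4)
        if self.kernel == "polynomial":
            return SVC(kernel="poly", degree=self.degree, gamma=self.beta,
                       coef0=self.theta, **common)
        if self.kernel == "gaussian":
            return SVC(kernel="rbf", gamma=self.gamma, **common)
        return SVC(kernel="sigmoid", gamma=self.beta, coef0=self.theta, **common)


@dataclass
class CVResult:
    fold_accuracies: list[float]
    mean_accuracy: float
    confusion: np.ndarray  # rows = true class, cols = predicted
    labels: tuple[str, ...]


def _disc_sum(values: np.ndarray, center: tuple[float, float], radius: float) -> float:
    """Sum over pixels whose centers lie within ``radius`` of ``center``;
    parts of the disc outside the grid contribute zero."""
    h, w = values.shape
    rows, cols = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    inside = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2
    return float(values[inside].sum())


def extract_features(img: PressureImage, loc: HipLocalization,
                     hip_radius: float = 7.0, caudal_radius: float = 3.0) -> FeatureVector:
    """Regional pressure sums around the localized centers (image should be
    preprocessed, i.e. sum to 1)."""
    v = img.values
    return FeatureVector(
        f_left=_disc_sum(v, loc.left_hip, hip_radius),
        f_right=_disc_sum(v, loc.right_hip, hip_radius),
        f_caudal=_disc_sum(v, loc.caudal, caudal_radius),
    )


def features_from_samples(samples: list[AnnotatedSample], geom: GeometryParams | None = None,
                          bank: TemplateBank | None = None,
                          params: LocalizerParams | None = None,
                          preprocess_cfg: PreprocessConfig | None = None,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """End-to-end feature extraction: preprocess, localize, sum regions.
    Returns (n x 3 feature matrix, label array)."""
    geom = geom or GeometryParams()
    bank = bank or build_bank(geom)
    hip_r, caudal_r = float(geom.r1), float(geom.r2)
    X, y = [], []
    for s in samples:
        pre = preprocess(s.image, preprocess_cfg)
        loc = locate_hips(pre, bank, params)
        X.append(extract_features(pre, loc, hip_r, caudal_r).as_array())
        y.append(s.posture)
    return np.asarray(X), np.asarray(y)


def fit_standardizer(X: np.ndarray) -> StandardizationStats:
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples to standardize")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd
    if np.any(sd <= 0):
        raise ValueError("degenerate feature: zero standard deviation")
    return StandardizationStats(mean=mean, sd=sd)


def apply_standardizer(stats: StandardizationStats, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - stats.mean) / stats.sd


def train_ova_svm(X: np.ndarray, y: np.ndarray, cfg: SVMConfig | None = None,
                  seed: int = 0) -> OneVsRestClassifier:
    """One binary max-margin classifier per class (class vs rest); predicted
    class is the one with the largest decision value."""
    cfg = cfg or SVMConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes")
    model = OneVsRestClassifier(cfg._svc())
    model.fit(np.asarray(X, dtype=float), y)
    return model


def cross_validate(X: np.ndarray, y: np.ndarray, cfg: SVMConfig | None = None,
                   folds: int = 5, seed: int = 0, dataset_standardize: bool = False,
                   groups: np.ndarray | None = None) -> CVResult:
    """Stratified k-fold cross-validation with per-training-fold
    standardization; pass ``groups`` (e.g. subject ids) for subject-wise
    folds instead."""
    cfg = cfg or SVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    uniq = [str(u) for u in np.unique(y)]
    labels = tuple(sorted(uniq, key=list(POSTURES).index) if set(uniq) <= set(POSTURES)
                   else sorted(uniq))
    counts = {lab: int((y == lab).sum()) for lab in labels}
    if groups is None and min(counts.values()) < folds:
        raise ValueError("insufficient samples for stratification")

    if groups is not None:
        splitter = GroupKFold(n_splits=folds)
        split = splitter.split(X, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(X, y)

    global_stats = fit_standardizer(X) if dataset_standardize else None
    fold_acc: list[float] = []
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    for train_idx, test_idx in split:
        stats = global_stats if global_stats is not None else fit_standardizer(X[train_idx])
        Xtr = apply_standardizer(stats, X[train_idx])
        Xte = apply_standardizer(stats, X[test_idx])
        model = train_ova_svm(Xtr, y[train_idx], cfg, seed)
        pred = model.predict(Xte)
        fold_acc.append(float((pred == y[test_idx]).mean()))
        confusion += confusion_matrix(y[test_idx], pred, labels=list(labels))
    return CVResult(fold_accuracies=fold_acc,
                    mean_accuracy=float(np.mean(fold_acc)),
                    confusion=confusion, labels=labels)


def svm_grid_search(X: np.ndarray, y: np.ndarray, kernel: str = "polynomial",
                    param_grid: dict[str, list[float]] | None = None,
                    folds: int = 5, seed: int = 0) -> tuple[SVMConfig, CVResult]:
    """Exhaustive search maximizing mean CV accuracy; ties go to the
    earliest grid-order combination.  Default grids bracket the canonical
    optima of each kernel."""
    defaults = {
        "polynomial": {"C": [0.5, 1.0, 1.3, 2.0], "beta": [0.7, 1.4, 2.8],
                       "theta": [0.4, 0.8, 1.6], "degree": [2, 3, 4]},
        "gaussian": {"C": [0.1, 0.2, 0.5, 1.0], "gamma": [1.0, 2.0, 4.0]},
        "sigmoid": {"C": [0.2, 0.4, 0.8], "beta": [0.1, 0.2, 0.4], "theta": [0.1, 0.2, 0.4]},
    }
    if kernel not in _KERNELS:
        raise ValueError(f"unknown kernel: {kernel!r}")
    grid = param_grid if param_grid is not None else defaults[kernel]
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty grid")
    names = list(grid)
    best: tuple[SVMConfig, CVResult] | None = None
    for combo in itertools.product(*(grid[n] for n in names)):
        cfg = SVMConfig(kernel=kernel, **dict(zip(names, combo)))
        result = cross_validate(X, y, cfg, folds=folds, seed=seed)
        if best is None or result.mean_accuracy > best[1].mean_accuracy:
            best = (cfg, result)
    assert best is not None
    return best
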