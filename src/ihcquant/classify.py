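"""SVM stain-intensity classification of detected cells.

Each cell is summarized by the mean L, a, b values over a square window
of side d_min centered on it; an RBF-kernel SVM maps those three numbers
to a staining category.  Hyper-parameters (regularization lambda and
kernel spread sigma) are tuned by grid search with stratified 4-fold
cross-validation, scored by the Cohen kappa statistic in percent, which
discounts agreement expected by chance.  Features are standardized by the
training mean/sd before the kernel, so the fixed sigma grid is meaningful
regardless of feature scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .model import Cell, Overlay, StainCategory, ValidationError
from .rda import LabImage

CLASS_ORDER = [StainCategory.HIGH, StainCategory.LOW, StainCategory.NONE]


@dataclass(frozen=True)
class CellFeatures:
    mean_L: float
    mean_a: float
    mean_b: float

    def vector(self) -> np.ndarray:
        return np.array([self.mean_L, self.mean_a, self.mean_b])


def extract_features(lab: LabImage, cell: Cell, d_min: float) -> CellFeatures:
    """Mean Lab over a square window of side max(3, round(d_min)).

    The window is centered at the rounded cell position and clipped to the
    image, so corner cells average over the visible part only.
    """
    h, w = lab.L.shape
    cx, cy = int(round(cell.x)), int(round(cell.y))
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValidationError(f"cell ({cell.x}, {cell.y}) outside image")
    s = max(3, int(round(d_min)))
    half = s // 2
    x0, x1 = max(0, cx - half), min(w, cx - half + s)
    y0, y1 = max(0, cy - half), min(h, cy - half + s)
    return CellFeatures(
        float(lab.L[y0:y1, x0:x1].mean()),
        float(lab.a[y0:y1, x0:x1].mean()),
        float(lab.b[y0:y1, x0:x1].mean()),
    )


@dataclass
class TrainingSet:
    features: np.ndarray                 # (n, 3)
    categories: list[StainCategory]      # len n

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.shape[0] != len(self.categories):
            raise ValidationError("features/categories length mismatch")

    @property
    def n(self) -> int:
        return len(self.categories)

    def class_counts(self) -> dict[StainCategory, int]:
        return {c: sum(1 for y in self.categories if y is c) for c in CLASS_ORDER}

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("mean_L,mean_a,mean_b,category\n")
            for (L, a, b), y in zip(self.features, self.categories):
                fh.write(f"{L!r},{a!r},{b!r},{y.value}\n")


def _quotas(avail: Sequence[int], cap: int) -> list[int]:
    """Split `cap` samples over classes: equal quotas, all-of-small classes,
    shortfall redistributed among classes with surplus; remainders go to
    earlier classes."""
    n = len(avail)
    if sum(avail) <= cap:
        return list(avail)
    alloc = [0] * n
    active = list(range(n))
    budget = cap
    while budget > 0 and active:
        base, rem = divmod(budget, len(active))
        prov = {i: base + (1 if rank < rem else 0) for rank, i in enumerate(active)}
        capped = [i for i in active if avail[i] <= prov[i]]
        if not capped:
            for i in active:
                alloc[i] += prov[i]
            budget = 0
        else:
            for i in capped:
                budget -= avail[i] - alloc[i]
                alloc[i] = avail[i]
                active.remove(i)
    return alloc


def build_training_set(samples: Iterable[tuple[CellFeatures, StainCategory]],
                       cap: int = 1000, min_per_class: int = 10,
                       seed: int = 0) -> TrainingSet:
    """Class-balanced subsample of labeled cells, at most `cap` total.

    Classes with fewer than `min_per_class` members are excluded.  Each
    included class gets an equal quota of the cap; classes too small to
    fill their quota contribute everything and the shortfall is split
    among the rest.  Selection within a class is uniform without
    replacement (seeded).
    """
    samples = list(samples)
    by_class: dict[StainCategory, list[int]] = {c: [] for c in CLASS_ORDER}
    for i, (_, y) in enumerate(samples):
        by_class[y].append(i)
    included = [c for c in CLASS_ORDER if len(by_class[c]) >= min_per_class]
    if not included:
        raise ValidationError(
            f"no class has >= {min_per_class} labeled cells; cannot train")
    alloc = _quotas([len(by_class[c]) for c in included], cap)
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for c, take in zip(included, alloc):
        idx = by_class[c]
        if take >= len(idx):
            chosen.extend(idx)
        else:
            picks = rng.choice(len(idx), size=take, replace=False)
            chosen.extend(idx[j] for j in sorted(picks))
    feats = np.array([samples[i][0].vector() for i in chosen])
    cats = [samples[i][1] for i in chosen]
    return TrainingSet(feats, cats)


def collect_labeled_features(lab: LabImage, overlay: Overlay
                             ) -> list[tuple[CellFeatures, StainCategory]]:
    """Features + labels for every categorized cell of one overlay."""
    out = []
    for c in overlay.cells:
        if c.category is not None:
            out.append((extract_features(lab, c, overlay.diameters.d_min),
                        c.category))
    return out


# ---------------------------------------------------------------------------
# agreement statistics

@dataclass
class ConfusionMatrix:
    """Square matrix of true-class (rows) vs predicted-class (columns) mass.

    Entries may be counts or percentages; every derived statistic is
    normalization-invariant.
    """

    matrix: np.ndarray
    labels: list = field(default_factory=lambda: list(CLASS_ORDER))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValidationError("confusion matrix must be square")
        if (self.matrix < 0).any():
            raise ValidationError("confusion matrix entries must be >= 0")

    @property
    def total(self) -> float:
        return float(self.matrix.sum())


def confusion_from_labels(y_true: Sequence, y_pred: Sequence,
                          labels: Optional[Sequence] = None) -> ConfusionMatrix:
    labels = list(labels) if labels is not None else list(CLASS_ORDER)
    index = {c: i for i, c in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)))
    for t, p in zip(y_true, y_pred):
        m[index[t], index[p]] += 1
    return ConfusionMatrix(m, labels)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Cohen kappa in percent: 100 * (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement (trace fraction) and p_e the agreement
    expected by chance from the marginals.  Returns 0 when p_e = 1 (a
    single nonempty row/column pair, where agreement is all chance).
    """
    N = cm.total
    if N <= 0:
        raise ValidationError("empty confusion matrix")
    m = cm.matrix
    p_o = np.trace(m) / N
    p_e = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / (N * N)
    if p_e >= 1.0:
        return 0.0
    return 100.0 * (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# SVM training

@dataclass(frozen=True)
class GridSpec:
    """Hyper-parameter grid: lambda = 2^(2i-7), i=1..10 (2^-5 .. 2^13);
    sigma = 2^(-(i+1)/2), i=-15..0 (2^7 .. 2^-0.5); K=4 folds."""

    lambdas: tuple[float, ...] = tuple(2.0 ** (2 * i - 7) for i in range(1, 11))
    sigmas: tuple[float, ...] = tuple(2.0 ** (-(i + 1) / 2.0)
                                      for i in range(-15, 1))
    folds: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lambdas or not self.sigmas or self.folds < 2:
            raise ValidationError("grid must be nonempty with K >= 2")


@dataclass
class SvmModel:
    svc: SVC
    mean: np.ndarray
    sd: np.ndarray
    lam: float
    sigma: float
    cv_kappa: float                      # best mean CV kappa (percent)
    classes: list[StainCategory]

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    def predict_features(self, X: np.ndarray) -> list[StainCategory]:
        raw = self.svc.predict(self._standardize(np.asarray(X, dtype=np.float64)))
        return [StainCategory(v) for v in raw]

    def save(self, path: str | Path) -> None:
        joblib.dump({
            "format": "ihcquant-svm-1",
            "mean": self.mean, "sd": self.sd,
            "lambda": self.lam, "sigma": self.sigma,
            "cv_kappa": self.cv_kappa,
            "classes": [c.value for c in self.classes],
            "svc": self.svc,
        }, path)

    @classmethod
    def load(cls, path: str | Path) -> "SvmModel":
        d = joblib.load(path)
        if d.get("format") != "ihcquant-svm-1":
            raise ValidationError(f"not an ihcquant SVM model file: {path}")
        return cls(svc=d["svc"], mean=d["mean"], sd=d["sd"], lam=d["lambda"],
                   sigma=d["sigma"], cv_kappa=d["cv_kappa"],
                   classes=[StainCategory(v) for v in d["classes"]])


def _gamma(sigma: float) -> float:
    # RBF K(x,y) = exp(-||x-y||^2 / (2 sigma^2)) => sklearn gamma
    return 1.0 / (2.0 * sigma * sigma)


def grid_search_train(ts: TrainingSet, grid: GridSpec = GridSpec()) -> SvmModel:
    """Tune (lambda, sigma) by stratified K-fold CV kappa, refit on all data.

    Ties in mean kappa resolve to the smaller lambda, then the smaller
    sigma (the less complex model).  Folds are stratified and seeded, so
    the search is reproducible.
    """
    y = np.array([c.value for c in ts.categories])
    present = sorted(set(y))
    if len(present) < 2:
        raise ValidationError("training set must contain >= 2 classes")
    X = ts.features
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd

    n_splits = min(grid.folds, min(np.bincount(np.searchsorted(present, y))))
    n_splits = max(2, n_splits)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=grid.seed)
    folds = list(skf.split(Xs, y))

    best = None  # (kappa, lam, sigma)
    for lam in sorted(grid.lambdas):
        for sigma in sorted(grid.sigmas):
            kappas = []
            for tr, te in folds:
                if len(set(y[tr])) < 2:
                    kappas.append(0.0)
                    continue
                svc = SVC(C=lam, kernel="rbf", gamma=_gamma(sigma))
                svc.fit(Xs[tr], y[tr])
                cm = confusion_from_labels(y[te], svc.predict(Xs[te]),
                                           labels=present)
                kappas.append(cohen_kappa(cm))
            mk = float(np.mean(kappas))
            if best is None or mk > best[0] + 1e-12:
                best = (mk, lam, sigma)
    mk, lam, sigma = best
    svc = SVC(C=lam, kernel="rbf", gamma=_gamma(sigma))
    svc.fit(Xs, y)
    return SvmModel(svc=svc, mean=mean, sd=sd, lam=lam, sigma=sigma,
                    cv_kappa=mk,
                    classes=[StainCategory(v) for v in present])


def predict_cells(model: SvmModel, lab: LabImage, cells: list[Cell],
                  d_min: float) -> list[Cell]:
    """Label each cell with the model's predicted category (order kept)."""
    if model.svc is None or not hasattr(model.svc, "support_"):
        raise ValidationError("model is not fitted")
    if not cells:
        return []
    X = np.array([extract_features(lab, c, d_min).vector() for c in cells])
    preds = model.predict_features(X)
    return [Cell(c.x, c.y, category=p, source=c.source)
            for c, p in zip(cells, preds)]
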