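"""Incremental feature selection with SMOTE-balanced decision trees.

Nested prefixes of the mRMR-ranked feature list (sizes step, 2·step, …,
plus the final partial prefix) are each evaluated by stratified 10-fold
cross-validation of a CART (Gini) decision tree.  Inside every fold the
*training* portion only is rebalanced by SMOTE — synthetic minority rows
interpolated between a minority sample and one of its k nearest minority
neighbors — bringing the minority class to parity with the majority; the
held-out fold is never touched.  Confusion counts are pooled over folds
and summarized as ACC, SN (recall), SP, precision, F1 and MCC.  The best
prefix maximizes F1, ties resolved toward the smaller prefix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier


@dataclass(frozen=True)
class IFSConfig:
    step: int = 5
    folds: int = 10
    smote_k: int = 5
    seed: int = 0
    # CART settings: Gini criterion, unlimited depth, library defaults
    tree_params: dict = field(
        default_factory=lambda: {
            "criterion": "gini",
            "max_depth": None,
            "min_samples_split": 2,
            "min_samples_leaf": 1,
        }
    )

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricRecord:
    acc: float
    sn: float
    sp: float
    precision: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "acc": self.acc,
            "sn": self.sn,
            "sp": self.sp,
            "precision": self.precision,
            "f1": self.f1,
            "mcc": self.mcc,
        }


@dataclass(frozen=True)
class IFSCurve:
    points: tuple[tuple[int, MetricRecord], ...]
    best: tuple[int, MetricRecord]

    def as_rows(self) -> list[dict]:
        return [
            {"n_features": n, **rec.as_dict()} for n, rec in self.points
        ]


def evaluate_metrics(c: ConfusionCounts) -> MetricRecord:
    """ACC, SN, SP, precision, F1 and MCC from pooled confusion counts.

    Any ratio with a zero denominator is defined as 0.
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    acc = ratio(tp + tn, tp + fp + tn + fn)
    sn = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    precision = ratio(tp, tp + fp)
    f1 = ratio(2 * precision * sn, precision + sn)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ratio(tp * tn - fp * fn, mcc_den)
    return MetricRecord(acc=acc, sn=sn, sp=sp, precision=precision, f1=f1, mcc=mcc)


def smote_oversample(
    X_min: np.ndarray,
    n_new: int,
    k: int = 5,
    seed: int | np.random.Generator = 0,
    return_parents: bool = False,
):
    """Generate ``n_new`` synthetic minority rows by kNN interpolation.

    Each synthetic row is ``x_i + u · (x_nn − x_i)`` with ``u ~ U(0, 1)``,
    ``x_i`` a uniformly chosen minority row and ``x_nn`` one of its ``k``
    nearest minority neighbors (Euclidean; k clamped to ``|X_min| − 1``).
    With ``return_parents`` the row indices of ``x_i`` and ``x_nn`` are
    returned alongside, for auditing the interpolation.
    """
    X_min = np.asarray(X_min, dtype=float)
    if X_min.ndim != 2 or X_min.shape[0] < 2:
        raise ValueError("need at least two minority samples to interpolate")
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    if n_new == 0:
        empty = np.empty((0, X_min.shape[1]))
        if return_parents:
            return empty, np.empty(0, dtype=int), np.empty(0, dtype=int)
        return empty
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = min(k, X_min.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    _, idx = nn.kneighbors(X_min)  # idx[:, 0] is the point itself
    base = rng.integers(X_min.shape[0], size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    u = rng.random(n_new)[:, None]
    neigh = idx[base, pick]
    xi = X_min[base]
    xnn = X_min[neigh]
    synth = xi + u * (xnn - xi)
    if return_parents:
        return synth, base, neigh
    return synth


def stratified_folds(y: np.ndarray, folds: int = 10, seed: int = 0) -> np.ndarray:
    """Fold index per sample; per-class counts across folds differ by <= 1."""
    y = np.asarray(y)
    for cls, cnt in zip(*np.unique(y, return_counts=True)):
        if cnt < folds:
            raise ValueError(
                f"class {cls!r} has {cnt} members, fewer than {folds} folds"
            )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(y.shape[0], dtype=int)
    for fold_id, (_, test_idx) in enumerate(skf.split(np.zeros((y.shape[0], 1)), y)):
        assignment[test_idx] = fold_id
    return assignment


def _balance_with_smote(
    X: np.ndarray, y: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Bring the minority class to exact parity with the majority."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    minority = classes[np.argmin(counts)]
    n_new = int(counts.max() - counts.min())
    if n_new == 0:
        return X, y
    X_min = X[y == minority]
    synth = smote_oversample(X_min, n_new, k=k, seed=rng)
    X_bal = np.vstack([X, synth])
    y_bal = np.concatenate([y, np.full(n_new, minority)])
    return X_bal, y_bal


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def cv_evaluate(
    X: np.ndarray, y: np.ndarray, cfg: IFSConfig = IFSConfig()
) -> tuple[MetricRecord, ConfusionCounts]:
    """Pooled cross-validated metrics for one feature subset.

    SMOTE runs strictly inside each training fold; the held-out fold never
    contains synthetic rows, and each real sample is predicted exactly once.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    assignment = stratified_folds(y, cfg.folds, seed=cfg.seed)
    rng = np.random.default_rng((cfg.seed, 17))
    pooled = ConfusionCounts(0, 0, 0, 0)
    for fold_id in range(cfg.folds):
        test = assignment == fold_id
        Xtr, ytr = X[~test], y[~test]
        Xtr, ytr = _balance_with_smote(Xtr, ytr, cfg.smote_k, rng)
        tree = DecisionTreeClassifier(
            **cfg.tree_params, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(Xtr, ytr)
        pooled = pooled + _confusion(y[test], tree.predict(X[test]))
    if pooled.total != y.shape[0]:  # CV accounting invariant
        raise AssertionError("pooled confusion counts do not sum to sample count")
    return evaluate_metrics(pooled), pooled


def prefix_sizes(n_columns: int, step: int) -> list[int]:
    sizes = list(range(step, n_columns + 1, step))
    if not sizes or sizes[-1] != n_columns:
        sizes.append(n_columns)
    return sizes


def ifs_run(
    X_ranked: np.ndarray, y: np.ndarray, cfg: IFSConfig = IFSConfig()
) -> IFSCurve:
    """Sweep nested prefixes of the ranked feature matrix.

    ``X_ranked`` must already have its columns in mRMR order.  Returns the
    full curve (for plotting) and the best point by F1, ties toward the
    smaller prefix.
    """
    X_ranked = np.asarray(X_ranked, dtype=float)
    if X_ranked.shape[1] < 1:
        raise ValueError("need at least one ranked column")
    points = []
    for n in prefix_sizes(X_ranked.shape[1], cfg.step):
        rec, _ = cv_evaluate(X_ranked[:, :n], y, cfg)
        points.append((n, rec))
    best = max(points, key=lambda p: (p[1].f1, -p[0]))
    return IFSCurve(points=tuple(points), best=best)
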