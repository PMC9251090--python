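"""All-relevant feature filtering with shadow features (Boruta).

Each iteration appends a freshly permuted "shadow" copy of every active
feature to the matrix, fits a random forest on the augmented data, and
records a *hit* for every real feature whose importance exceeds a
reference percentile (default: the maximum) of the shadow importances.
A two-sided binomial test on the accumulated hit counts — with Bonferroni
correction over the features still undecided — then confirms features
hitting significantly more often than chance (p = 0.5) and rejects those
hitting significantly less often.  Rejected features are dropped from
subsequent forests; the loop stops when nothing is tentative or at
``max_iter``.  Features still tentative at the end are resolved by
comparing their median importance across iterations with the median of
the best shadow importance: those below it are rejected, those above keep
weak (tentative) support — only the binomial test confirms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier


@dataclass(frozen=True)
class BorutaConfig:
    n_trees: int = 500
    max_iter: int = 100
    alpha: float = 0.05
    percentile: float = 100.0  # shadow-importance reference; 100 = max shadow
    importance: str = "permutation"  # or "impurity"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (0.0 < self.percentile <= 100.0):
            raise ValueError("percentile must be in (0, 100]")
        if self.importance not in ("permutation", "impurity"):
            raise ValueError(f"unknown importance measure {self.importance!r}")


@dataclass(frozen=True)
class BorutaResult:
    confirmed: tuple[str, ...]
    rejected: tuple[str, ...]
    tentative: tuple[str, ...]
    hit_history: dict[str, list[int]] = field(default_factory=dict, repr=False)
    n_iterations: int = 0

    def __post_init__(self) -> None:
        groups = (set(self.confirmed), set(self.rejected), set(self.tentative))
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("confirmed/rejected/tentative must be disjoint")


def add_shadows(
    X: np.ndarray,
    rng: np.random.Generator | None = None,
    min_shadows: int = 1,
) -> np.ndarray:
    """Append independently row-permuted shadow columns, one per feature.

    The originals occupy the first columns, unchanged.  When fewer than
    ``min_shadows`` features remain, source columns are recycled so the
    shadow pool keeps at least ``min_shadows`` independent permutations —
    otherwise the max-shadow reference would collapse as features are
    rejected.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] < 1 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >=2 samples and >=1 feature")
    rng = np.random.default_rng() if rng is None else rng
    n_shadow = max(X.shape[1], min_shadows)
    shadows = np.empty((X.shape[0], n_shadow), dtype=X.dtype)
    for j in range(n_shadow):
        shadows[:, j] = rng.permutation(X[:, j % X.shape[1]])
    return np.hstack([X, shadows])


def _oob_permutation_zscores(
    forest: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-feature z-scores of out-of-bag permutation importance.

    For every tree, balanced accuracy on its out-of-bag samples is
    compared with the balanced accuracy after permuting one column at a
    time; the z-score of a feature is the mean drop across trees over its
    standard error.  Balanced accuracy matches the class-balanced sample
    weights the forest is trained with: under heavy imbalance a plain
    accuracy drop would reward corrupting minority-informative features.
    Because the evaluation is out-of-bag, a feature that is merely
    overfit in-sample scores near zero — unlike impurity-decrease
    importance, which locks onto spurious in-sample associations.
    """
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    y = np.asarray(y)
    n, p = X.shape
    classes = forest.classes_
    drops = np.full((len(forest.estimators_), p), np.nan)

    for t, (est, sampled) in enumerate(
        zip(forest.estimators_, forest.estimators_samples_)
    ):
        oob = np.ones(n, dtype=bool)
        oob[sampled] = False
        if oob.sum() < 2:
            continue
        Xo = X32[oob]
        yo = y[oob]
        class_masks = [yo == c for c in classes if np.any(yo == c)]
        if len(class_masks) < 2:
            continue

        def _acc(A: np.ndarray) -> float:
            votes = est.tree_.predict(A)
            pred = classes[np.argmax(votes.reshape(len(A), -1), axis=1)]
            hit = pred == yo
            return float(np.mean([hit[mk].mean() for mk in class_masks]))

        base = _acc(Xo)
        perm = rng.permutation(len(Xo))
        drops[t, :] = 0.0  # features absent from this tree have exact zero drop
        used = np.unique(est.tree_.feature)
        for j in used[used >= 0]:
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            drops[t, j] = base - _acc(Xp)

    mean = np.nanmean(drops, axis=0)
    sd = np.nanstd(drops, axis=0, ddof=1)
    n_used = np.sum(~np.isnan(drops), axis=0)
    z = np.zeros(p)
    ok = (sd > 0) & (n_used > 1)
    z[ok] = mean[ok] / (sd[ok] / np.sqrt(n_used[ok]))  # Breiman z-score
    return z


def boruta_run(
    X: np.ndarray,
    y: np.ndarray,
    cfg: BorutaConfig = BorutaConfig(),
    feature_names: list[str] | None = None,
) -> BorutaResult:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X rows must align with y")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    n_features = X.shape[1]
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"f{j}" for j in range(n_features)]
    )
    if len(names) != n_features:
        raise ValueError("feature_names length mismatch")

    rng = np.random.default_rng(cfg.seed)
    active = np.ones(n_features, dtype=bool)      # not yet rejected
    decided = np.zeros(n_features, dtype=bool)    # confirmed or rejected
    confirmed = np.zeros(n_features, dtype=bool)
    hits = np.zeros(n_features, dtype=int)
    trials = np.zeros(n_features, dtype=int)
    hit_history: dict[str, list[int]] = {nm: [] for nm in names}
    imp_history: list[np.ndarray] = []            # per-iter importances (NaN when inactive)
    shadow_max_history: list[float] = []

    it = 0
    for it in range(1, cfg.max_iter + 1):
        cols = np.flatnonzero(active)
        Xa = add_shadows(X[:, cols], rng=rng, min_shadows=5)
        forest = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            class_weight="balanced",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(Xa, y)
        if cfg.importance == "permutation":
            imp = _oob_permutation_zscores(forest, Xa, y, rng)
        else:
            imp = forest.feature_importances_
        real_imp = imp[: len(cols)]
        shadow_imp = imp[len(cols):]  # may exceed len(cols): recycled shadows
        threshold = float(np.percentile(shadow_imp, cfg.percentile))
        shadow_max_history.append(float(shadow_imp.max()))

        row = np.full(n_features, np.nan)
        row[cols] = real_imp
        imp_history.append(row)

        hit_now = real_imp > threshold
        hits[cols] += hit_now.astype(int)
        trials[cols] += 1
        for j, h in zip(cols, hit_now):
            hit_history[names[j]].append(int(h))

        # two-sided binomial decision, Bonferroni over the total feature
        # count so the threshold does not weaken as rejections accumulate
        undecided = np.flatnonzero(active & ~decided)
        if undecided.size:
            bonf_alpha = cfg.alpha / n_features
            p_hi = binom.sf(hits[undecided] - 1, trials[undecided], 0.5)
            p_lo = binom.cdf(hits[undecided], trials[undecided], 0.5)
            newly_confirmed = undecided[p_hi < bonf_alpha]
            newly_rejected = undecided[p_lo < bonf_alpha]
            confirmed[newly_confirmed] = True
            decided[newly_confirmed] = True
            decided[newly_rejected] = True
            active[newly_rejected] = False
        if decided.all():
            break

    tentative_idx = np.flatnonzero(active & ~decided)
    # resolve leftovers: a feature whose median importance across
    # iterations beats the median best-shadow importance keeps weak
    # (tentative) support; the rest are rejected.  Only binomially
    # confirmed features count as confirmed.
    if tentative_idx.size and imp_history:
        imp_arr = np.vstack(imp_history)
        shadow_med = float(np.median(shadow_max_history))
        for j in tentative_idx:
            col = imp_arr[:, j]
            col = col[~np.isnan(col)]
            if not (col.size and float(np.median(col)) > shadow_med):
                decided[j] = True
                active[j] = False

    tentative_final = np.flatnonzero(active & ~decided & ~confirmed)
    rejected_final = np.flatnonzero(~active)
    confirmed_final = np.flatnonzero(confirmed)
    return BorutaResult(
        confirmed=tuple(names[j] for j in confirmed_final),
        rejected=tuple(names[j] for j in rejected_final),
        tentative=tuple(names[j] for j in tentative_final),
        hit_history=hit_history,
        n_iterations=it,
    )
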