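"""Max-relevance / min-redundancy (mRMR) feature ranking.

Continuous enrichment scores are discretized into three bins at
mean ± t·sd (t = 1 by default), mutual information is estimated by the
plug-in formula on empirical cell frequencies (log base 2, bits), and
features are ranked greedily: the first pick maximizes relevance
I(f; y); each subsequent pick maximizes the MID criterion

    I(f; y) − (1/|S|) Σ_{s ∈ S} I(f; s)

over the remaining features, with S the already-selected set.  Ties break
toward the smaller original column index.  The MIQ (quotient) criterion is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DiscretizationScheme:
    kind: str = "three-bin-mean-sigma"  # or "none"
    t: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("three-bin-mean-sigma", "none"):
            raise ValueError(f"unknown discretization kind {self.kind!r}")
        if self.t <= 0:
            raise ValueError("t must be > 0")


@dataclass(frozen=True)
class RankedFeatureList:
    """mRMR ordering, most to least important."""

    order: tuple[str, ...]
    relevance: dict[str, float]
    selection_scores: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.order) != set(self.relevance):
            raise ValueError("order must be a permutation of the scored features")


def discretize(x: np.ndarray, scheme: DiscretizationScheme = DiscretizationScheme()) -> np.ndarray:
    """Three-bin coding: below mean−t·sd → 0, within → 1, above mean+t·sd → 2.

    Sample standard deviation (ddof=1).  A constant vector codes as all 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    if scheme.kind == "none":
        return x.copy()
    mu = x.mean()
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0:
        return np.ones_like(x, dtype=int)
    out = np.ones(x.shape, dtype=int)
    out[x < mu - scheme.t * sd] = 0
    out[x > mu + scheme.t * sd] = 2
    return out


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI in bits: Σ p(x,y) log2[p(x,y)/(p(x)p(y))], 0·log 0 = 0."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("need two equal-length nonempty 1-D vectors")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])))
    return max(mi, 0.0)  # clip tiny negative rounding residue


def discretize_matrix(
    X: np.ndarray, scheme: DiscretizationScheme = DiscretizationScheme()
) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.column_stack([discretize(X[:, j], scheme) for j in range(X.shape[1])])


def mrmr_order(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    criterion: str = "MID",
) -> RankedFeatureList:
    """Greedy mRMR ordering of already-discretized feature columns.

    ``criterion`` is "MID" (relevance minus mean redundancy) or "MIQ"
    (relevance over mean redundancy).  The ranking runs until every
    feature is in the list.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need at least one feature column")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows must align with y")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    if criterion not in ("MID", "MIQ"):
        raise ValueError(f"unknown criterion {criterion!r}")
    F = X.shape[1]
    names = (
        list(feature_names) if feature_names is not None else [f"f{j}" for j in range(F)]
    )
    if len(names) != F:
        raise ValueError("feature_names length mismatch")

    relevance = np.array([mutual_information(X[:, j], y) for j in range(F)])
    selected: list[int] = []
    remaining = list(range(F))
    red_sum = np.zeros(F)  # Σ_{s in S} I(f; s), updated incrementally
    scores: dict[str, float] = {}

    while remaining:
        if not selected:
            crit = relevance[remaining]
        else:
            mean_red = red_sum[remaining] / len(selected)
            if criterion == "MID":
                crit = relevance[remaining] - mean_red
            else:
                crit = relevance[remaining] / np.maximum(mean_red, 1e-12)
        # argmax with ties broken toward the smaller original column index;
        # `remaining` is kept sorted so np.argmax's first-hit rule suffices
        best = remaining[int(np.argmax(crit))]
        scores[names[best]] = float(crit[remaining.index(best)])
        selected.append(best)
        remaining.remove(best)
        if remaining:
            for f in remaining:
                red_sum[f] += mutual_information(X[:, f], X[:, best])

    return RankedFeatureList(
        order=tuple(names[j] for j in selected),
        relevance={names[j]: float(relevance[j]) for j in range(F)},
        selection_scores=scores,
    )
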