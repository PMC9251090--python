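"""Final-tree training and IF–THEN rule extraction.

The final CART (Gini) tree is trained on *all* samples, rebalanced with
the same SMOTE recipe used during cross-validation, using the best IFS
feature prefix.  Each leaf yields one rule: the conjunction of threshold
conditions along the root-to-leaf path, simplified per feature to the
tightest lower/upper bound, predicting the leaf's majority class.  Rule
supports are reported on the real (non-synthetic) training samples only,
so the counts are interpretable as data coverage.  The rule set is
mutually exclusive and exhaustive over the feature space by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .ifs import IFSConfig, _balance_with_smote


@dataclass(frozen=True)
class DecisionRule:
    conditions: tuple[tuple[str, str, float], ...]  # (feature_id, "<="|">", threshold)
    predicted_class: int  # 1 = disease-associated, 0 = other
    support: tuple[int, int]  # (n_positive, n_negative) real samples at the leaf

    def matches(self, x: dict[str, float]) -> bool:
        for feat, rel, thr in self.conditions:
            if feat not in x:
                raise KeyError(f"probe vector missing feature {feat!r}")
            v = x[feat]
            if rel == "<=" and not v <= thr:
                return False
            if rel == ">" and not v > thr:
                return False
        return True

    def to_text(self) -> str:
        if not self.conditions:
            conds = "TRUE"
        else:
            conds = " AND ".join(
                f"{feat} {rel} {_sig4(thr)}" for feat, rel, thr in self.conditions
            )
        cls = "positive" if self.predicted_class == 1 else "negative"
        return (
            f"IF {conds} THEN class = {cls}"
            f"  [support +{self.support[0]}/-{self.support[1]}]"
        )


def _sig4(x: float) -> str:
    """Threshold rendering at 4 significant digits for the text report."""
    return f"{x:.4g}"


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[DecisionRule, ...]
    feature_universe: tuple[str, ...]

    def predict_one(self, x: dict[str, float]) -> int:
        missing = [f for f in self.feature_universe if f not in x]
        if missing:
            raise KeyError(f"probe vector missing features {missing[:5]}")
        hits = [r for r in self.rules if r.matches(x)]
        if len(hits) != 1:
            raise RuntimeError(
                f"rule set invariant breached: {len(hits)} rules matched one probe"
            )
        return hits[0].predicted_class

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_universe": list(self.feature_universe),
                "rules": [
                    {
                        "conditions": [
                            {"feature": f, "relation": r, "threshold": t}
                            for f, r, t in rule.conditions
                        ],
                        "predicted_class": rule.predicted_class,
                        "support_positive": rule.support[0],
                        "support_negative": rule.support[1],
                    }
                    for rule in self.rules
                ],
            },
            indent=1,
        )

    def to_text(self) -> str:
        return "\n".join(r.to_text() for r in self.rules) + "\n"

    def write(self, json_path: str | Path, text_path: str | Path | None = None) -> None:
        Path(json_path).write_text(self.to_json())
        if text_path is not None:
            Path(text_path).write_text(self.to_text())


def predict_with_rules(rs: RuleSet, x: dict[str, float]) -> int:
    """Classify one probe; exactly one rule must match."""
    return rs.predict_one(x)


def fit_final_tree(
    X_best: np.ndarray,
    y: np.ndarray,
    cfg: IFSConfig = IFSConfig(),
) -> DecisionTreeClassifier:
    """CART/Gini tree on all samples after SMOTE balancing, seeded."""
    X_best = np.asarray(X_best, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    rng = np.random.default_rng((cfg.seed, 23))
    X_bal, y_bal = _balance_with_smote(X_best, y, cfg.smote_k, rng)
    tree = DecisionTreeClassifier(
        **cfg.tree_params, random_state=int(rng.integers(2**31 - 1))
    )
    tree.fit(X_bal, y_bal)
    return tree


def extract_rules(
    tree: DecisionTreeClassifier,
    feature_names: list[str],
    X_real: np.ndarray | None = None,
    y_real: np.ndarray | None = None,
) -> RuleSet:
    """One rule per leaf, with per-feature bounds tightened.

    ``X_real``/``y_real`` (the non-synthetic training samples) supply the
    support counts; without them supports are taken from the tree's
    training-set leaf counts.
    """
    t = tree.tree_
    classes = list(tree.classes_)

    # real-sample leaf occupancy
    leaf_support: dict[int, list[int]] = {}
    if X_real is not None and y_real is not None:
        leaves = tree.apply(np.asarray(X_real, dtype=float))
        y_real = np.asarray(y_real)
        for leaf, label in zip(leaves, y_real):
            sup = leaf_support.setdefault(int(leaf), [0, 0])
            sup[0 if label == 1 else 1] += 1

    rules: list[DecisionRule] = []

    def walk(node: int, bounds: dict[str, list[float]]) -> None:
        if t.children_left[node] == -1:  # leaf
            conds: list[tuple[str, str, float]] = []
            for feat, (lo, hi) in bounds.items():
                if not math.isinf(lo):
                    conds.append((feat, ">", lo))
                if not math.isinf(hi):
                    conds.append((feat, "<=", hi))
            counts = t.value[node][0]
            pred = classes[int(np.argmax(counts))]
            if X_real is not None:
                sup = tuple(leaf_support.get(node, [0, 0]))
            else:
                by_class = {c: int(round(v)) for c, v in zip(classes, counts)}
                sup = (by_class.get(1, 0), by_class.get(0, 0))
            rules.append(
                DecisionRule(
                    conditions=tuple(conds), predicted_class=int(pred), support=sup
                )
            )
            return
        feat = feature_names[t.feature[node]]
        thr = float(t.threshold[node])
        lo, hi = bounds.get(feat, [-math.inf, math.inf])
        left = dict(bounds)
        left[feat] = [lo, min(hi, thr)]  # tightest upper bound
        walk(t.children_left[node], left)
        right = dict(bounds)
        right[feat] = [max(lo, thr), hi]  # tightest lower bound
        walk(t.children_right[node], right)

    walk(0, {})
    rules.sort(key=lambda r: -(r.support[0] + r.support[1]))
    return RuleSet(rules=tuple(rules), feature_universe=tuple(feature_names))
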