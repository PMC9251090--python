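"""Model/Results surface for the disease-gene classification workflow.

:class:`DiseaseGeneModel` holds the enrichment feature table and binary
labels; :meth:`DiseaseGeneModel.fit` runs the full selection cascade —
Boruta all-relevant filtering, mRMR ranking, incremental feature selection
with a SMOTE-balanced CART under stratified cross-validation — then trains
the final tree on the best prefix and extracts its IF–THEN rules.  The
returned :class:`DiseaseGeneResults` carries every intermediate artifact
plus a ``summary()`` table.

>>> model = DiseaseGeneModel.from_synthetic(SyntheticConfig(seed=7))
>>> res = model.fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .boruta import BorutaConfig, BorutaResult, boruta_run
from .enrichment import EnrichmentMatrix, build_matrix
from .ifs import IFSConfig, IFSCurve, MetricRecord, ifs_run
from .mrmr import DiscretizationScheme, RankedFeatureList, discretize_matrix, mrmr_order
from .rules import RuleSet, extract_rules, fit_final_tree
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset

log = logging.getLogger("genesieve")


def namespace_breakdown(
    features: list[str] | tuple[str, ...], meta: dict[str, str]
) -> dict[str, int]:
    """Count selected features per annotation namespace (BP/CC/MF/PATHWAY)."""
    missing = [f for f in features if f not in meta]
    if missing:
        raise KeyError(f"features missing from metadata: {missing[:5]}")
    counts = {"BP": 0, "CC": 0, "MF": 0, "PATHWAY": 0}
    for f in features:
        counts[meta[f]] += 1
    return counts


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Fan one global seed out into independent per-stage seeds (< 2**31)."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31 - 1)) for s in state]


@dataclass
class DiseaseGeneModel:
    """Disease-gene classifier over functional-enrichment features.

    Parameters
    ----------
    X : DataFrame
        Genes x terms matrix of -log10 hypergeometric enrichment scores.
    y : array of 0/1
        1 for disease-associated (positive) genes, aligned with ``X`` rows.
    namespaces : dict
        term id -> namespace (BP/CC/MF/PATHWAY), for reporting.
    """

    X: pd.DataFrame
    y: np.ndarray
    namespaces: dict[str, str] = field(default_factory=dict)
    boruta_config: BorutaConfig = field(default_factory=BorutaConfig)
    ifs_config: IFSConfig = field(default_factory=IFSConfig)
    discretization: DiscretizationScheme = field(default_factory=DiscretizationScheme)
    mrmr_criterion: str = "MID"
    truth: SyntheticDataset | None = None  # carried along for recovery checks

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X rows must align with y")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("y must be binary 0/1")

    # ------------------------------------------------------------------ #
    @classmethod
    def from_dataframe(
        cls,
        X: pd.DataFrame,
        y,
        namespaces: dict[str, str] | None = None,
        **kwargs,
    ) -> "DiseaseGeneModel":
        ns = namespaces or {c: "BP" for c in X.columns}
        return cls(X=X, y=np.asarray(y), namespaces=ns, **kwargs)

    @classmethod
    def from_enrichment(
        cls, mat: EnrichmentMatrix, positives: set[str], **kwargs
    ) -> "DiseaseGeneModel":
        y = np.array([1 if g in positives else 0 for g in mat.genes], dtype=int)
        return cls(
            X=mat.to_frame(), y=y, namespaces=mat.feature_namespaces, **kwargs
        )

    @classmethod
    def from_synthetic(
        cls, cfg: SyntheticConfig, min_score: int = 0, **kwargs
    ) -> "DiseaseGeneModel":
        ds = generate_dataset(cfg)
        mat = build_matrix(ds.catalog, ds.network, min_score=min_score)
        model = cls.from_enrichment(mat, set(ds.positives), **kwargs)
        model.truth = ds
        return model

    # ------------------------------------------------------------------ #
    def fit(self, seed: int | None = None) -> "DiseaseGeneResults":
        """Run Boruta -> mRMR -> IFS -> final tree -> rule extraction."""
        if seed is not None:
            s_boruta, s_ifs, *_ = _stage_seeds(seed)
            self.boruta_config = replace(self.boruta_config, seed=s_boruta)
            self.ifs_config = replace(self.ifs_config, seed=s_ifs)

        names = [str(c) for c in self.X.columns]
        Xv = self.X.to_numpy(dtype=float)

        boruta = boruta_run(
            Xv, self.y, self.boruta_config, feature_names=names
        )
        kept = list(boruta.confirmed)
        used_fallback = False
        if not kept:
            # nothing survived the filter (e.g. a null dataset): rank the
            # full feature set so downstream stages remain well defined
            log.warning("Boruta confirmed no features; ranking the full set")
            kept = names
            used_fallback = True

        kept_idx = [names.index(f) for f in kept]
        Xd = discretize_matrix(Xv[:, kept_idx], self.discretization)
        ranked = mrmr_order(
            Xd, self.y, feature_names=kept, criterion=self.mrmr_criterion
        )
        order_idx = [names.index(f) for f in ranked.order]
        X_ranked = Xv[:, order_idx]

        curve = ifs_run(X_ranked, self.y, self.ifs_config)
        best_n, best_rec = curve.best
        best_features = list(ranked.order[:best_n])

        tree = fit_final_tree(X_ranked[:, :best_n], self.y, self.ifs_config)
        rules = extract_rules(
            tree, best_features, X_real=X_ranked[:, :best_n], y_real=self.y
        )

        return DiseaseGeneResults(
            model=self,
            boruta=boruta,
            ranked=ranked,
            ifs_curve=curve,
            best_n_features=best_n,
            best_metrics=best_rec,
            best_features=tuple(best_features),
            final_tree=tree,
            rules=rules,
            boruta_fallback=used_fallback,
        )


@dataclass
class DiseaseGeneResults:
    """Fit artifacts: selection history, IFS curve, final tree and rules."""

    model: DiseaseGeneModel
    boruta: BorutaResult
    ranked: RankedFeatureList
    ifs_curve: IFSCurve
    best_n_features: int
    best_metrics: MetricRecord
    best_features: tuple[str, ...]
    final_tree: object
    rules: RuleSet
    boruta_fallback: bool = False

    @property
    def n_rules(self) -> int:
        return len(self.rules.rules)

    def namespace_breakdown(self) -> dict[str, int]:
        meta = self.model.namespaces
        return namespace_breakdown(list(self.best_features), meta)

    def ifs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ifs_curve.as_rows())

    def causal_term_recall(self) -> float | None:
        """Fraction of planted causal terms confirmed by Boruta (synthetic
        datasets only; None when no truth record is attached)."""
        truth = self.model.truth
        if truth is None:
            return None
        causal = set(truth.causal_terms)
        if not causal:
            return None
        return len(causal & set(self.boruta.confirmed)) / len(causal)

    def plot_ifs_curve(self, path=None, ax=None):
        """F1 against prefix size, the best point highlighted."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ns = [n for n, _ in self.ifs_curve.points]
        f1 = [r.f1 for _, r in self.ifs_curve.points]
        ax.plot(ns, f1, marker="o", lw=1)
        bn, br = self.ifs_curve.best
        ax.scatter([bn], [br.f1], color="crimson", zorder=3,
                   label=f"best: {bn} features, F1={br.f1:.3f}")
        ax.set_xlabel("number of features")
        ax.set_ylabel("F1-measure")
        ax.legend(frameon=False)
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax

    def summary(self) -> str:
        n_pos = int(self.model.y.sum())
        n_neg = int((1 - self.model.y).sum())
        m = self.best_metrics
        lines = [
            "Disease-gene classification summary",
            "=" * 51,
            f"samples                 {len(self.model.y)} "
            f"({n_pos} positive / {n_neg} negative)",
            f"input features          {self.model.X.shape[1]}",
            f"Boruta confirmed        {len(self.boruta.confirmed)}"
            + ("  (fallback: full set ranked)" if self.boruta_fallback else ""),
            f"Boruta rejected         {len(self.boruta.rejected)}",
            f"Boruta tentative        {len(self.boruta.tentative)}",
            f"best prefix (by F1)     {self.best_n_features} features",
            "-" * 51,
            f"ACC {m.acc:.3f}  SN {m.sn:.3f}  SP {m.sp:.3f}  "
            f"precision {m.precision:.3f}",
            f"F1 {m.f1:.3f}  MCC {m.mcc:.3f}",
            "-" * 51,
            f"decision rules          {self.n_rules}",
            "namespace breakdown     "
            + "  ".join(f"{k}:{v}" for k, v in self.namespace_breakdown().items()),
        ]
        recall = self.causal_term_recall()
        if recall is not None:
            lines.append(f"causal-term recall      {recall:.2f}")
        return "\n".join(lines)
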