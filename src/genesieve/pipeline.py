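"""End-to-end pipeline orchestration with persisted stage artifacts.

Every stage writes its output in the documented plain-text formats so the
workflow can be resumed or re-run stage by stage (see :mod:`genesieve.cli`
for the matching subcommands):

* ``featurize`` -> ``matrix.tsv`` + ``features.json`` (+ ``labels.txt``)
* ``boruta``    -> ``boruta.json`` + ``confirmed_matrix.tsv``
* ``mrmr``      -> ``ranked.tsv``
* ``ifs``       -> ``ifs_curve.tsv`` + ``best_subset.json`` + ``ifs_curve.png``
* ``rules``     -> ``rules.json`` + ``rules.txt``
* ``report``    -> ``report.json``
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .boruta import BorutaConfig
from .enrichment import build_matrix
from .ifs import IFSConfig
from .model import DiseaseGeneModel, DiseaseGeneResults, namespace_breakdown
from .mrmr import DiscretizationScheme
from .synthetic import SyntheticConfig, generate_dataset, write_dataset

log = logging.getLogger("genesieve")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and its inputs."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")


@dataclass
class PipelineConfig:
    """Either real-input paths (catalog/network/labels) or a synthetic
    configuration — never both."""

    out_dir: str | Path = "genesieve_out"
    seed: int = 0
    catalog_path: str | Path | None = None
    network_path: str | Path | None = None
    labels_path: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    min_score: int = 0
    boruta: BorutaConfig = field(default_factory=BorutaConfig)
    ifs: IFSConfig = field(default_factory=IFSConfig)
    discretization: DiscretizationScheme = field(default_factory=DiscretizationScheme)
    mrmr_criterion: str = "MID"

    def __post_init__(self) -> None:
        real = all(
            p is not None
            for p in (self.catalog_path, self.network_path, self.labels_path)
        )
        if real and self.synthetic is not None:
            raise ValueError("provide real-input paths or a synthetic config, not both")
        if not real and self.synthetic is None:
            raise ValueError("need catalog/network/labels paths or a synthetic config")


def _build_model(cfg: PipelineConfig) -> DiseaseGeneModel:
    try:
        if cfg.synthetic is not None:
            ds = generate_dataset(cfg.synthetic)
            write_dataset(ds, Path(cfg.out_dir) / "synthetic")
            mat = build_matrix(ds.catalog, ds.network, min_score=cfg.min_score)
            model = DiseaseGeneModel.from_enrichment(mat, set(ds.positives))
            model.truth = ds
        else:
            net = gio.read_edge_list(cfg.network_path)
            catalog = gio.read_gmt(cfg.catalog_path)
            universe = set(net.universe) | set(catalog.universe)
            net = gio.read_edge_list(cfg.network_path, universe=universe)
            catalog = gio.read_gmt(cfg.catalog_path, universe=universe)
            positives = gio.read_gene_list(cfg.labels_path)
            mat = build_matrix(catalog, net, min_score=cfg.min_score)
            model = DiseaseGeneModel.from_enrichment(mat, positives)
    except (OSError, ValueError, KeyError) as exc:
        raise StageError(
            "featurize",
            f"{exc} (catalog={cfg.catalog_path}, network={cfg.network_path}, "
            f"labels={cfg.labels_path})",
        ) from exc
    model.boruta_config = cfg.boruta
    model.ifs_config = cfg.ifs
    model.discretization = cfg.discretization
    model.mrmr_criterion = cfg.mrmr_criterion
    return model


def _persist(res: DiseaseGeneResults, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    model = res.model

    gio.write_feature_meta(model.namespaces, out / "features.json")
    model.X.to_csv(out / "matrix.tsv", sep="\t")
    (out / "labels.txt").write_text(
        "".join(f"{g}\t{l}\n" for g, l in zip(model.X.index, model.y))
    )

    (out / "boruta.json").write_text(
        json.dumps(
            {
                "confirmed": list(res.boruta.confirmed),
                "rejected": list(res.boruta.rejected),
                "tentative": list(res.boruta.tentative),
                "n_iterations": res.boruta.n_iterations,
                "fallback_full_set": res.boruta_fallback,
            },
            indent=1,
        )
    )
    model.X[list(res.boruta.confirmed)].to_csv(out / "confirmed_matrix.tsv", sep="\t")

    ranked_rows = [
        {
            "rank": i + 1,
            "feature_id": f,
            "namespace": model.namespaces.get(f, "BP"),
            "relevance": res.ranked.relevance[f],
            "criterion_score": res.ranked.selection_scores[f],
        }
        for i, f in enumerate(res.ranked.order)
    ]
    pd.DataFrame(ranked_rows).to_csv(out / "ranked.tsv", sep="\t", index=False)

    res.ifs_frame().to_csv(out / "ifs_curve.tsv", sep="\t", index=False)
    res.plot_ifs_curve(out / "ifs_curve.png")
    (out / "best_subset.json").write_text(
        json.dumps(
            {
                "n_features": res.best_n_features,
                "features": list(res.best_features),
                "metrics": res.best_metrics.as_dict(),
            },
            indent=1,
        )
    )
    res.rules.write(out / "rules.json", out / "rules.txt")

    report = {
        "n_samples": int(len(model.y)),
        "n_positive": int(model.y.sum()),
        "n_input_features": int(model.X.shape[1]),
        "n_confirmed": len(res.boruta.confirmed),
        "boruta_fallback": res.boruta_fallback,
        "best_n_features": res.best_n_features,
        "best_metrics": res.best_metrics.as_dict(),
        "n_rules": res.n_rules,
        "namespace_breakdown": res.namespace_breakdown(),
    }
    recall = res.causal_term_recall()
    if recall is not None:
        report["causal_term_recall"] = recall
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def run_pipeline(cfg: PipelineConfig) -> dict:
    """featurize -> boruta -> mrmr -> ifs -> rules, persisting everything.

    Returns the report dict (also written to ``report.json``).
    """
    out = Path(cfg.out_dir)
    t0 = time.time()
    model = _build_model(cfg)
    try:
        res = model.fit(seed=cfg.seed)
    except Exception as exc:  # noqa: BLE001 - annotate with stage context
        raise StageError("selection", str(exc)) from exc
    report = _persist(res, out)
    log.info("pipeline finished in %.1fs -> %s", time.time() - t0, out)
    return report


__all__ = [
    "PipelineConfig",
    "StageError",
    "run_pipeline",
    "namespace_breakdown",
]
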