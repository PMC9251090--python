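"""Synthetic annotation catalogs, interaction networks and labeled genes.

The generator emulates the structure of a disease-gene study without any
external download: a gene universe carrying overlapping term annotations in
four namespaces (BP, CC, MF and pathway sets), a sparse background
interaction network, and a planted set of "positive" (disease-associated)
genes whose network neighborhoods are enriched for a chosen subset of
causal terms.

The signal is planted through edges, not through direct annotation of the
positives: the enrichment features score a gene's *neighbor* set, so a
positive gene becomes distinguishable only if its neighborhood composition
is biased toward causal-term members.  Concretely, the background graph is
Erdős–Rényi with edge probability ``mean_degree / (n_genes - 1)``; each
edge incident to a positive gene then has its far endpoint rewired, with
probability ``effect_strength``, to a uniformly drawn member of a causal
term's gene set.  With ``effect_strength = 0`` nothing is rewired and
positives follow exactly the same generation law as negatives.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as gio
from .enrichment import NAMESPACES, AnnotationCatalog, GeneNetwork

log = logging.getLogger("genesieve")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``effect_strength`` is the per-edge probability that a positive gene's
    neighbor is drawn from a causal term's gene set rather than kept from
    the uniform background.
    """

    n_genes: int = 500
    n_terms_per_namespace: dict[str, int] = field(
        default_factory=lambda: {"BP": 40, "CC": 20, "MF": 20, "PATHWAY": 10}
    )
    term_size_range: tuple[int, int] = (10, 30)
    mean_degree: float = 8.0
    n_positive: int = 50
    n_causal_terms: int = 3
    effect_strength: float = 0.9
    causal_namespace: str = "BP"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid term_size_range {self.term_size_range}")
        if hi > self.n_genes:
            raise ValueError(
                f"term_size_range max {hi} exceeds n_genes {self.n_genes}"
            )
        if not (0 <= self.n_positive < self.n_genes):
            raise ValueError("n_positive must be in [0, n_genes)")
        if not (0.0 <= self.effect_strength <= 1.0):
            raise ValueError("effect_strength must be in [0, 1]")
        if self.causal_namespace not in NAMESPACES:
            raise ValueError(f"unknown causal namespace {self.causal_namespace!r}")
        total_terms = sum(self.n_terms_per_namespace.values())
        if self.n_causal_terms > total_terms:
            raise ValueError("n_causal_terms exceeds total term count")
        if self.n_causal_terms > self.n_terms_per_namespace.get(self.causal_namespace, 0):
            raise ValueError(
                f"n_causal_terms exceeds terms in namespace {self.causal_namespace!r}"
            )
        for ns in self.n_terms_per_namespace:
            if ns not in NAMESPACES:
                raise ValueError(f"unknown namespace {ns!r}")


@dataclass(frozen=True)
class SyntheticDataset:
    catalog: AnnotationCatalog
    network: GeneNetwork
    positives: frozenset[str]
    causal_terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.positives <= self.catalog.universe:
            raise ValueError("positives outside the gene universe")
        if not self.causal_terms <= set(self.catalog.term_ids):
            raise ValueError("causal terms missing from the catalog")


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_catalog(cfg: SyntheticConfig) -> AnnotationCatalog:
    """Sample overlapping term gene sets uniformly from the universe.

    Term sizes are uniform over ``term_size_range`` (inclusive); members
    are drawn without replacement within a term, freely across terms, so
    terms overlap like real annotation catalogs do.  Column order is GO
    namespaces (BP, CC, MF) first, then pathway terms.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    lo, hi = cfg.term_size_range
    terms: list[tuple[str, str, frozenset[str]]] = []
    for ns in NAMESPACES:  # fixed namespace order defines column order
        count = cfg.n_terms_per_namespace.get(ns, 0)
        for j in range(count):
            size = int(rng.integers(lo, hi + 1))
            members = rng.choice(cfg.n_genes, size=size, replace=False)
            terms.append((f"{ns}:{j:04d}", ns, frozenset(genes[i] for i in members)))
    return AnnotationCatalog(terms=tuple(terms), universe=frozenset(genes))


def pick_truth(cfg: SyntheticConfig, catalog: AnnotationCatalog) -> tuple[frozenset[str], frozenset[str]]:
    """Sample the planted positives and causal terms (seeded independently
    of the catalog draw so changing term counts does not reshuffle them)."""
    rng = np.random.default_rng((cfg.seed, 1))
    genes = sorted(catalog.universe)
    positives = frozenset(
        genes[i] for i in rng.choice(len(genes), size=cfg.n_positive, replace=False)
    )
    ns_terms = [t for t, ns, _ in catalog.terms if ns == cfg.causal_namespace]
    causal = frozenset(
        ns_terms[i] for i in rng.choice(len(ns_terms), size=cfg.n_causal_terms, replace=False)
    )
    return positives, causal


def generate_network(
    cfg: SyntheticConfig,
    catalog: AnnotationCatalog,
    positives: frozenset[str],
    causal_terms: frozenset[str],
) -> GeneNetwork:
    """Erdős–Rényi background plus causal rewiring around positive genes.

    Every unordered pair gets an edge with probability
    ``mean_degree / (n_genes - 1)``; each background edge touching a
    positive gene is then, with probability ``effect_strength``, rewired so
    its far endpoint is a uniform draw from the union of causal-term gene
    sets.  Self-loops and duplicate edges arising from rewiring are
    discarded, keeping the graph simple.
    """
    if not positives <= catalog.universe:
        raise ValueError("positives outside the catalog universe")
    if not causal_terms <= set(catalog.term_ids):
        raise ValueError("causal terms missing from the catalog")
    rng = np.random.default_rng((cfg.seed, 2))
    genes = sorted(catalog.universe)
    n = len(genes)
    p = min(1.0, cfg.mean_degree / max(n - 1, 1))

    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.shape[0]) < p
    base_edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))

    gidx = {g: i for i, g in enumerate(genes)}
    pos_idx = {gidx[g] for g in positives}
    term_members = {
        t: sorted(gidx[g] for g in s)
        for t, _, s in catalog.terms
        if t in causal_terms
    }
    causal_ids = sorted(term_members)
    # each positive gene is driven by one causal term: its rewired neighbors
    # come from that term's gene set, so the *per-term* neighborhood
    # enrichment the feature encoding measures is actually planted
    driver: dict[int, list[int]] = {}
    if causal_ids:
        for i in sorted(pos_idx):
            driver[i] = term_members[causal_ids[int(rng.integers(len(causal_ids)))]]

    edges: set[frozenset[str]] = set()
    for a, b in base_edges:
        if driver and cfg.effect_strength > 0 and (a in pos_idx or b in pos_idx):
            # rewire the far endpoint toward the anchor's driver-term members
            if a in pos_idx:
                anchor, far = a, b
            else:
                anchor, far = b, a
            pool = driver[anchor]
            if rng.random() < cfg.effect_strength:
                far = int(pool[rng.integers(len(pool))])
            if anchor == far:
                continue
            a, b = anchor, far
        e = frozenset((genes[a], genes[b]))
        if len(e) == 2:
            edges.add(e)
    return GeneNetwork(universe=frozenset(genes), edges=frozenset(edges))


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    catalog = generate_catalog(cfg)
    positives, causal = pick_truth(cfg, catalog)
    network = generate_network(cfg, catalog, positives, causal)
    return SyntheticDataset(
        catalog=catalog, network=network, positives=positives, causal_terms=causal
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Emit catalog (GMT), network (edge list), positives (gene list) and a
    truth sidecar (JSON) recording the causal terms for recovery tests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "catalog": gio.write_gmt(ds.catalog, out / "catalog.gmt"),
        "network": gio.write_edge_list(ds.network, out / "network.tsv"),
        "positives": gio.write_gene_list(ds.positives, out / "positives.txt"),
    }
    truth = out / "truth.json"
    truth.write_text(
        json.dumps(
            {
                "causal_terms": sorted(ds.causal_terms),
                "n_positive": len(ds.positives),
                "n_genes": len(ds.catalog.universe),
                "universe": sorted(ds.catalog.universe),
            },
            indent=1,
        )
    )
    paths["truth"] = truth
    log.info("wrote synthetic dataset to %s", out)
    return paths


def read_dataset(out_dir: str | Path) -> SyntheticDataset:
    """Round-trip loader for :func:`write_dataset` output."""
    out = Path(out_dir)
    truth = json.loads((out / "truth.json").read_text())
    universe = set(truth["universe"])
    network = gio.read_edge_list(out / "network.tsv", universe=universe)
    catalog = gio.read_gmt(out / "catalog.gmt", universe=universe)
    positives = gio.read_gene_list(out / "positives.txt")
    return SyntheticDataset(
        catalog=catalog,
        network=network,
        positives=frozenset(positives),
        causal_terms=frozenset(truth["causal_terms"]),
    )
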