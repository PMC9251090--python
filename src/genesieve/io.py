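"""Readers and writers for the plain-text interchange formats.

Formats
-------
GMT
    one term per line: ``term_id<TAB>namespace-tagged description<TAB>gene1<TAB>...``.
    The description field carries ``namespace=BP|CC|MF|PATHWAY``.
edge list
    whitespace/tab separated ``gene1 gene2 [score]`` with STRING-convention
    integer scores in [0, 1000]; the score column is optional.
labels
    one gene identifier per line.
matrix TSV
    header row of term ids, first column the gene id.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import NAMESPACES, AnnotationCatalog, EnrichmentMatrix, GeneNetwork

log = logging.getLogger("genesieve")


def write_gmt(catalog: AnnotationCatalog, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for term_id, ns, genes in catalog.terms:
            fields = [term_id, f"namespace={ns}", *sorted(genes)]
            fh.write("\t".join(fields) + "\n")
    return path


def read_gmt(path: str | Path, universe: set[str] | None = None) -> AnnotationCatalog:
    """Parse a GMT file; the universe defaults to the union of all gene sets."""
    terms: list[tuple[str, str, frozenset[str]]] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term_id, desc, genes = fields[0], fields[1], fields[2:]
            ns = "BP"
            if "namespace=" in desc:
                ns = desc.split("namespace=", 1)[1].split()[0]
            if ns not in NAMESPACES:
                raise ValueError(f"{path}:{lineno}: unknown namespace {ns!r}")
            terms.append((term_id, ns, frozenset(genes)))
    if universe is None:
        universe = set().union(*(g for _, _, g in terms)) if terms else set()
    return AnnotationCatalog(terms=tuple(terms), universe=frozenset(universe))


def write_edge_list(net: GeneNetwork, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for e in net.edges:
        a, b = sorted(e)
        if net.edge_score:
            rows.append((a, b, net.edge_score.get(e, 1000)))
        else:
            rows.append((a, b))
    rows.sort()
    with path.open("w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


def read_edge_list(path: str | Path, universe: set[str] | None = None) -> GeneNetwork:
    """Parse a STRING-style edge list; tolerates repeated/reversed edges."""
    edges: set[frozenset[str]] = set()
    scores: dict[frozenset[str], int] = {}
    genes: set[str] = set()
    any_score = False
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: edge line needs two endpoints")
            a, b = fields[0], fields[1]
            if a == b:
                continue  # drop self-loops silently; the graph is simple
            e = frozenset((a, b))
            edges.add(e)
            genes.update((a, b))
            if len(fields) >= 3:
                any_score = True
                scores[e] = int(float(fields[2]))
    if universe is None:
        universe = genes
    return GeneNetwork(
        universe=frozenset(universe),
        edges=frozenset(edges),
        edge_score=scores if any_score else {},
    )


def write_gene_list(genes: set[str] | list[str], path: str | Path) -> Path:
    path = Path(path)
    if not genes:
        warnings.warn(f"writing empty gene list to {path}", stacklevel=2)
        log.warning("writing empty gene list to %s", path)
    with path.open("w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
    return path


def read_gene_list(path: str | Path) -> set[str]:
    with Path(path).open() as fh:
        return {line.strip() for line in fh if line.strip()}


def write_matrix(mat: EnrichmentMatrix, path: str | Path, meta_path: str | Path | None = None) -> Path:
    """Write the feature matrix as TSV plus a term->namespace metadata JSON."""
    path = Path(path)
    mat.to_frame().to_csv(path, sep="\t")
    if meta_path is not None:
        write_feature_meta(mat.feature_namespaces, meta_path, n_universe=mat.n_universe)
    return path


def write_feature_meta(namespaces: dict[str, str], path: str | Path, n_universe: int | None = None) -> Path:
    path = Path(path)
    payload: dict = {"namespaces": namespaces}
    if n_universe is not None:
        payload["n_universe"] = n_universe
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_feature_meta(path: str | Path) -> dict[str, str]:
    payload = json.loads(Path(path).read_text())
    return payload["namespaces"]


def read_matrix(path: str | Path, meta_path: str | Path | None = None) -> tuple[pd.DataFrame, dict[str, str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    meta: dict[str, str] = {}
    if meta_path is not None:
        meta = read_feature_meta(meta_path)
    return df, meta


def labels_from_positives(genes: list[str] | tuple[str, ...], positives: set[str]) -> np.ndarray:
    """0/1 label vector aligned with a gene ordering (1 = disease-associated)."""
    return np.array([1 if g in positives else 0 for g in genes], dtype=int)
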