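"""Network-neighborhood functional-enrichment features.

Each gene is encoded by the enrichment of its direct interaction-network
neighborhood against every annotation term (GO-style BP/CC/MF terms plus
pathway gene sets).  For a gene ``g`` with neighbor set ``G`` of size ``n``,
a term annotating ``M`` of the ``N`` universe genes, and ``m = |G ∩ term|``,
the feature value is::

    ES(g, term) = -log10 P(X >= m),   X ~ Hypergeometric(N, M, n)

i.e. the upper-tail (one-sided over-representation) hypergeometric p-value
on a -log10 scale.  The resulting genes x terms matrix is the feature table
consumed by the downstream feature-selection and classification stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

NAMESPACES = ("BP", "CC", "MF", "PATHWAY")

#: cap applied to -log10(p) so underflowed p-values stay finite
DEFAULT_SCORE_CAP = 300.0


@dataclass(frozen=True)
class AnnotationCatalog:
    """Ordered term -> gene-set map over a fixed gene universe.

    The term order is significant: it defines the feature-column order of
    every matrix built from the catalog (GO namespaces first, then
    pathway terms, when built by the synthetic generator or loaded from a
    conventionally sorted GMT file).
    """

    terms: tuple[tuple[str, str, frozenset[str]], ...]  # (term_id, namespace, genes)
    universe: frozenset[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for term_id, ns, genes in self.terms:
            if term_id in seen:
                raise ValueError(f"duplicate term id {term_id!r}")
            seen.add(term_id)
            if ns not in NAMESPACES:
                raise ValueError(f"unknown namespace {ns!r} for term {term_id!r}")
            if not genes <= self.universe:
                stray = sorted(genes - self.universe)[:5]
                raise ValueError(
                    f"term {term_id!r} annotates genes outside the universe: {stray}"
                )

    @property
    def term_ids(self) -> list[str]:
        return [t[0] for t in self.terms]

    @property
    def namespaces(self) -> dict[str, str]:
        """term_id -> namespace map."""
        return {t[0]: t[1] for t in self.terms}

    def gene_sets(self) -> dict[str, frozenset[str]]:
        return {t[0]: t[2] for t in self.terms}

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected simple interaction graph with optional edge confidences.

    Edges are stored as frozensets of endpoint pairs; scores follow the
    STRING convention of integers in [0, 1000].  Absent scores mean every
    edge passes any confidence threshold of 0.
    """

    universe: frozenset[str]
    edges: frozenset[frozenset[str]]
    edge_score: dict[frozenset[str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(e)}")
            if not e <= self.universe:
                raise ValueError(f"edge endpoints outside universe: {set(e)}")

    def adjacency(self, min_score: int = 0) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {g: set() for g in self.universe}
        for e in self.edges:
            if min_score > 0 and self.edge_score.get(e, 1000) < min_score:
                continue
            a, b = tuple(e)
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class EnrichmentMatrix:
    """Genes x terms matrix of -log10 hypergeometric upper-tail p-values."""

    genes: tuple[str, ...]
    features: tuple[tuple[str, str], ...]  # (term_id, namespace), catalog order
    scores: np.ndarray
    n_universe: int

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.genes), len(self.features)):
            raise ValueError("score matrix shape does not match gene/feature labels")
        if not np.all(np.isfinite(self.scores)) or np.any(self.scores < 0):
            raise ValueError("scores must be finite and nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=pd.Index(self.genes, name="gene"),
            columns=[t for t, _ in self.features],
        )

    @property
    def feature_namespaces(self) -> dict[str, str]:
        return dict(self.features)


def neighbors(net: GeneNetwork, g: str, min_score: int = 0) -> set[str]:
    """Direct neighbors of ``g``, keeping only edges scoring >= ``min_score``.

    The gene itself is never a member of its own neighborhood.
    """
    if g not in net.universe:
        raise KeyError(f"gene {g!r} is not in the network universe")
    out: set[str] = set()
    for e in net.edges:
        if g in e:
            if min_score > 0 and net.edge_score.get(e, 1000) < min_score:
                continue
            (other,) = e - {g}
            out.add(other)
    return out


def hypergeom_upper_tail(N: int, M: int, n: int, m: int) -> float:
    """P(X >= m) for X ~ Hypergeometric(N, M, n).

    ``N`` universe size, ``M`` annotated genes, ``n`` neighborhood size,
    ``m`` annotated neighbors.  The tail is inclusive and the summation is
    implicitly clamped to min(n, M) by the survival function.
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= m <= min(n, M)):
        raise ValueError(
            f"invalid hypergeometric parameters N={N}, M={M}, n={n}, m={m}"
        )
    if m == 0:
        return 1.0
    # sf(m - 1) = P(X > m - 1) = P(X >= m)
    return float(hypergeom.sf(m - 1, N, M, n))


def enrichment_score(p: float, cap: float = DEFAULT_SCORE_CAP) -> float:
    """-log10(p), capped at ``cap`` to keep underflowed p-values finite."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    with np.errstate(divide="ignore"):
        s = -np.log10(p)
    return float(min(s, cap))


def build_matrix(
    catalog: AnnotationCatalog,
    net: GeneNetwork,
    genes: list[str] | tuple[str, ...] | None = None,
    min_score: int = 0,
    cap: float = DEFAULT_SCORE_CAP,
    include_self: bool = False,
) -> EnrichmentMatrix:
    """Score every gene's neighborhood against every catalog term.

    Genes with an empty neighborhood (after the confidence filter) get an
    all-zero row.  ``include_self`` optionally adds the gene itself to its
    neighborhood for sensitivity analysis; the default follows the
    neighbors-only definition.
    """
    if catalog.universe != net.universe:
        missing = sorted((catalog.universe ^ net.universe))[:10]
        raise ValueError(
            f"catalog and network universes differ (symmetric difference "
            f"starts with {missing})"
        )
    if genes is None:
        genes = sorted(catalog.universe)
    stray = [g for g in genes if g not in catalog.universe]
    if stray:
        raise ValueError(f"genes outside the catalog universe: {stray[:10]}")

    gene_index = {g: i for i, g in enumerate(sorted(catalog.universe))}
    N = len(catalog.universe)
    n_terms = len(catalog.terms)

    # term membership as a boolean matrix over the sorted universe
    member = np.zeros((n_terms, N), dtype=bool)
    M_sizes = np.empty(n_terms, dtype=np.int64)
    for j, (_tid, _ns, tgenes) in enumerate(catalog.terms):
        idx = [gene_index[g] for g in tgenes]
        member[j, idx] = True
        M_sizes[j] = len(tgenes)

    adj = net.adjacency(min_score=min_score)
    scores = np.zeros((len(genes), n_terms), dtype=float)
    for i, g in enumerate(genes):
        G = set(adj[g])
        if include_self:
            G.add(g)
        else:
            G.discard(g)
        n = len(G)
        if n == 0:
            continue
        nb = np.zeros(N, dtype=np.int64)
        nb[[gene_index[x] for x in G]] = 1
        m = member.astype(np.int64) @ nb  # annotated-neighbor counts per term
        with np.errstate(divide="ignore"):
            p = hypergeom.sf(m - 1, N, M_sizes, n)
        p = np.clip(p, 1e-320, 1.0)  # guard hard underflow before the log
        row = -np.log10(p)
        row[m == 0] = 0.0
        scores[i] = np.minimum(row, cap)

    return EnrichmentMatrix(
        genes=tuple(genes),
        features=tuple((t, ns) for t, ns, _ in catalog.terms),
        scores=scores,
        n_universe=N,
    )
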