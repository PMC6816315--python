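"""PPI clustering and gene-set / phenotype-overlap enrichment.

Protein-protein interaction handling follows the STRING convention: an
undirected graph with a combined confidence score in [0,1] per edge, and
a strict score cutoff (> 0.4 by default) deciding which edges count.
Clusters are connected components of the induced subgraph.

The PPI enrichment p-value uses a label-permutation null at fixed set
size: the query label is reassigned uniformly over graph nodes and the
within-set edge count recomputed.  (This is deliberately simpler than
STRING's degree-corrected null: it is self-contained and exactly
testable; see docs/methods.md.)

Gene-set enrichment is the one-sided hypergeometric overrepresentation
test with BH FDR across the library — the classic Fisher-style overlap
test that Enrichr-type tools report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as _st

from .simstats import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetLibrary",
    "EnrichmentResult",
    "load_ppi",
    "ppi_components",
    "ppi_enrichment_p",
    "load_gmt",
    "write_gmt",
    "overlap_enrichment",
    "load_trait_crosswalk",
    "phenotype_overlap",
]


def load_ppi(path) -> nx.Graph:
    """Read a geneA/geneB/combined_score TSV into an undirected graph.

    Self-loops are rejected; a repeated unordered pair keeps the first
    score with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    g = nx.Graph()
    for row in df.itertuples(index=False):
        a, b, s = row.geneA, row.geneB, float(row.combined_score)
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"combined score out of [0,1]: {s} ({a}-{b})")
        if a == b:
            raise ValueError(f"self-loop not allowed: {a}")
        if g.has_edge(a, b):
            logger.warning("duplicate PPI edge %s-%s dropped", a, b)
            continue
        g.add_edge(a, b, combined_score=s)
    return g


def _thresholded(graph: nx.Graph, cutoff: float) -> nx.Graph:
    keep = [
        (a, b) for a, b, s in graph.edges(data="combined_score") if s > cutoff
    ]
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(keep)
    return g


def ppi_components(
    genes: Iterable[str], graph: nx.Graph, cutoff: float = 0.4
) -> Tuple[List[List[str]], List[str]]:
    """Connected components of the query genes at a strict score cutoff.

    Returns ``(clusters, singletons)``: components of size >= 2 of the
    subgraph induced by the query on edges with score > cutoff, ordered
    by size descending then lexicographically, with members sorted; plus
    the remaining genes.  Query genes absent from the graph become
    singletons (warned).
    """
    genes = set(genes)
    missing = genes - set(graph.nodes)
    if missing:
        logger.warning("%d query gene(s) absent from PPI graph", len(missing))
    sub = _thresholded(graph, cutoff).subgraph(genes - missing)
    comps = [sorted(c) for c in nx.connected_components(sub)]
    clusters = sorted(
        (c for c in comps if len(c) >= 2), key=lambda c: (-len(c), c)
    )
    singles = sorted(
        [c[0] for c in comps if len(c) == 1] + sorted(missing)
    )
    return clusters, singles


def ppi_enrichment_p(
    genes: Iterable[str],
    graph: nx.Graph,
    cutoff: float = 0.4,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for interaction enrichment within a gene set.

    The observed statistic is the number of above-cutoff edges among the
    query genes; the null redraws the query as a uniform random node set
    of the same size, ``n_perm`` times.  p = (1 + #{null >= observed}) /
    (1 + n_perm), so the smallest attainable value is 1/(1+n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = set(genes) & set(graph.nodes)
    if len(genes) < 2:
        logger.warning("PPI enrichment on a set of < 2 mapped genes: p = 1")
        return 1.0
    thr = _thresholded(graph, cutoff)
    nodes = np.array(sorted(thr.nodes))
    adj = nx.to_numpy_array(thr, nodelist=nodes, dtype=bool)
    idx = {g: i for i, g in enumerate(nodes)}
    obs_idx = np.array([idx[g] for g in genes])
    observed = int(adj[np.ix_(obs_idx, obs_idx)].sum() // 2)
    rng = np.random.default_rng(seed)
    k = len(genes)
    hits = 0
    for _ in range(n_perm):
        perm = rng.choice(len(nodes), size=k, replace=False)
        count = int(adj[np.ix_(perm, perm)].sum() // 2)
        if count >= observed:
            hits += 1
    return (1 + hits) / (1 + n_perm)


@dataclass
class GeneSetLibrary:
    """Named gene sets plus an optional explicit background universe."""

    sets: Dict[str, FrozenSet[str]]
    background: Optional[FrozenSet[str]] = None

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"empty gene set: {name!r}")
            if self.background is not None and not members <= self.background:
                raise ValueError(
                    f"set {name!r} contains genes outside the declared background"
                )

    def all_genes(self) -> FrozenSet[str]:
        return frozenset().union(*self.sets.values())


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int          # overlap
    n_query: int
    K: int          # set size (within background)
    N: int          # background size
    p: float
    q: Optional[float] = None

    @property
    def significant(self) -> bool:
        return self.q is not None and self.q < 0.05


def load_gmt(path) -> GeneSetLibrary:
    """Read a GMT library (set name, description, then member genes)."""
    sets: Dict[str, FrozenSet[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, _desc, *genes = fields
            sets[name] = frozenset(g for g in genes if g)
    return GeneSetLibrary(sets=sets)


def write_gmt(library: GeneSetLibrary, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(library.sets):
            genes = "\t".join(sorted(library.sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def overlap_enrichment(
    query: Iterable[str],
    library: GeneSetLibrary,
    background: Optional[Iterable[str]] = None,
    fdr_level: float = 0.05,
) -> List[EnrichmentResult]:
    """One-sided hypergeometric overrepresentation of a query in each set.

    The background defaults to the union of library genes and the query.
    For each set, p = P(X >= k) with X hypergeometric (N background
    genes, K set members, n_query draws); q is BH across the library.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query gene set")
    if background is None:
        bg = set(library.all_genes()) | query
        logger.info("background defaulted to library ∪ query (%d genes)", len(bg))
    else:
        bg = set(background)
        if not query <= bg:
            raise ValueError("query must be a subset of the background")
    n = len(query & bg)
    N = len(bg)
    results = []
    for name in sorted(library.sets):
        members = library.sets[name] & bg
        K = len(members)
        k = len(query & members)
        p = float(_st.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        results.append(EnrichmentResult(name, k, n, K, N, p))
    qvals = bh_fdr([r.p for r in results])
    return [
        EnrichmentResult(r.set_name, r.k, r.n_query, r.K, r.N, r.p, float(q))
        for r, q in zip(results, qvals)
    ]


def load_trait_crosswalk(path) -> List[Tuple[str, str]]:
    """Read the phenotype-term <-> trait mapping (hpo_id, trait_label)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    return [(r.hpo_id, r.trait_label) for r in df.itertuples(index=False)]


def phenotype_overlap(
    gene_terms: Mapping[str, Set[str]],
    gene_traits: Mapping[str, Set[str]],
    trait_crosswalk: Sequence[Tuple[str, str]],
) -> pd.DataFrame:
    """Genes whose rare-disease phenotype terms match their GWAS traits.

    Emits one row per (gene, term, trait) where the gene carries the
    phenotype term, is associated with the trait, and the crosswalk links
    the two.  Adding crosswalk rows can only add output rows.
    """
    pairs = set(trait_crosswalk)
    rows = []
    for gene in sorted(set(gene_terms) & set(gene_traits)):
        terms, traits = gene_terms[gene], gene_traits[gene]
        for term, trait in sorted(pairs):
            if term in terms and trait in traits:
                rows.append({"gene": gene, "hpo_term": term, "trait": trait})
    return pd.DataFrame(rows, columns=["gene", "hpo_term", "trait"])
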