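"""Phenotype-ontology handling: OBO parsing and top-level category mapping.

An HPO-like ontology is a DAG of phenotype terms connected by ``is_a``
edges.  The children of the designated root ("Phenotypic abnormality" in
HPO) are the *top-level categories* — body-system-scale groupings such as
"Abnormality of the cardiovascular system".  Any deeper term maps to one
or more categories via its ancestor paths; a term reachable through
several categories belongs to each of them.

Only ``is_a`` edges are traversed; other relationship types (``part_of``
etc.) are ignored, matching how the HPO phenotype subontology is
structured.  Obsolete terms carrying a ``replaced_by`` tag are silently
remapped to their replacement; obsolete terms without one are dropped
with a logged warning.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Set

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyError",
    "OntologyTerm",
    "Ontology",
    "parse_obo",
    "toplevel_of",
    "project_to_categories",
    "rank_categories",
]


class OntologyError(ValueError):
    """Structural problem in an ontology file (cycle, dangling edge, ambiguous root)."""


@dataclass(frozen=True)
class OntologyTerm:
    id: str
    name: str
    parents: FrozenSet[str]
    obsolete: bool = False


@dataclass
class Ontology:
    """A rooted is_a DAG of phenotype terms.

    ``toplevel`` holds the root's direct children (the categories);
    ``aliases`` maps obsolete accessions to their replacements so that
    annotation files referring to superseded ids still resolve.
    """

    terms: Dict[str, OntologyTerm]
    root: str
    toplevel: FrozenSet[str]
    aliases: Dict[str, str] = field(default_factory=dict)
    _ancestor_cache: Dict[str, FrozenSet[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __contains__(self, accession: str) -> bool:
        return accession in self.terms or accession in self.aliases

    def resolve(self, accession: str) -> str:
        """Resolve an accession, following obsolete-term replacements."""
        if accession in self.terms:
            return accession
        if accession in self.aliases:
            return self.aliases[accession]
        raise KeyError(f"unknown ontology accession: {accession!r}")

    def ancestors(self, accession: str) -> FrozenSet[str]:
        """All is_a ancestors of a term (excluding the term itself), memoized."""
        acc = self.resolve(accession)
        cached = self._ancestor_cache.get(acc)
        if cached is not None:
            return cached
        out: Set[str] = set()
        for parent in self.terms[acc].parents:
            out.add(parent)
            out |= self.ancestors(parent)
        result = frozenset(out)
        self._ancestor_cache[acc] = result
        return result


def _stanza_parents(data: Mapping) -> FrozenSet[str]:
    # obonet stores raw is_a targets under "is_a" on the node data
    targets = data.get("is_a", [])
    return frozenset(t.split("!")[0].strip() for t in targets)


def parse_obo(path, root: Optional[str] = None) -> Ontology:
    """Parse an OBO 1.2 flat file into an :class:`Ontology`.

    Honors the ``id``, ``name``, ``is_a``, ``is_obsolete`` and
    ``replaced_by`` tags; everything else is ignored.  The root may be
    supplied explicitly; otherwise it is auto-detected as the unique
    parentless non-obsolete term, and a tie is a hard error.

    Raises
    ------
    OntologyError
        On an is_a cycle (naming one offending edge), a dangling is_a
        target, or an ambiguous auto-detected root.
    """
    graph = obonet.read_obo(path, ignore_obsolete=False)

    defined: Dict[str, Mapping] = {}
    for node, data in graph.nodes(data=True):
        if data:  # obonet adds bare nodes for dangling edge targets
            defined[node] = data

    aliases: Dict[str, str] = {}
    live: Dict[str, dict] = {}
    for acc, data in defined.items():
        if str(data.get("is_obsolete", "false")).lower() == "true":
            replacement = data.get("replaced_by", [])
            if replacement:
                aliases[acc] = replacement[0].split("!")[0].strip()
            else:
                logger.warning(
                    "dropping obsolete term %s (%s): no replaced_by",
                    acc, data.get("name", "?"),
                )
            continue
        live[acc] = {
            "name": data.get("name", acc),
            "parents": _stanza_parents(data),
        }

    # follow alias chains, remap parent references, detect dangling targets
    def _chase(acc: str, seen: tuple = ()) -> str:
        if acc in seen:
            raise OntologyError(f"replaced_by cycle involving {acc}")
        if acc in aliases:
            return _chase(aliases[acc], seen + (acc,))
        return acc

    aliases = {old: _chase(old) for old in aliases}
    for acc, rec in live.items():
        parents = set()
        for p in rec["parents"]:
            p = aliases.get(p, p)
            if p not in live:
                raise OntologyError(
                    f"dangling is_a target: {acc} -> {p} (no such term stanza)"
                )
            parents.add(p)
        rec["parents"] = frozenset(parents)

    dag = nx.DiGraph()
    dag.add_nodes_from(live)
    for acc, rec in live.items():
        for p in rec["parents"]:
            dag.add_edge(acc, p)
    try:
        cycle = nx.find_cycle(dag)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        a, b = cycle[0][0], cycle[0][1]
        raise OntologyError(f"is_a cycle detected (edge {a} -> {b})")

    if root is None:
        parentless = sorted(acc for acc, rec in live.items() if not rec["parents"])
        if len(parentless) != 1:
            raise OntologyError(
                "cannot auto-detect root: parentless terms "
                f"{parentless!r}; supply the root accession explicitly"
            )
        root = parentless[0]
    elif root not in live:
        raise OntologyError(f"declared root {root!r} not found among terms")

    # keep only terms that reach the root; other subontologies are dropped
    # (edges run child -> parent, so root-reaching terms are its nx "ancestors")
    reachable = nx.ancestors(dag, root) | {root}
    dropped = set(live) - reachable
    if dropped:
        logger.warning(
            "dropping %d term(s) not connected to root %s", len(dropped), root
        )
    terms = {
        acc: OntologyTerm(
            id=acc,
            name=live[acc]["name"],
            parents=frozenset(p for p in live[acc]["parents"] if p in reachable),
        )
        for acc in reachable
    }
    aliases = {old: new for old, new in aliases.items() if new in terms}
    toplevel = frozenset(
        acc for acc, t in terms.items() if root in t.parents
    )
    return Ontology(terms=terms, root=root, toplevel=toplevel, aliases=aliases)


def toplevel_of(onto: Ontology, term: str) -> FrozenSet[str]:
    """Top-level categories a term maps to, via is_a ancestor paths.

    A top-level term maps to itself.  The result is never empty for a
    term below the root.  Asking for the root is an error: the root is a
    bookkeeping node, not a phenotype.
    """
    acc = onto.resolve(term)
    if acc == onto.root:
        raise ValueError("the ontology root has no top-level category")
    if acc in onto.toplevel:
        return frozenset([acc])
    return onto.ancestors(acc) & onto.toplevel


def project_to_categories(onto: Ontology, terms: Iterable[str]) -> FrozenSet[str]:
    """Union of :func:`toplevel_of` over a set of terms."""
    out: Set[str] = set()
    for t in terms:
        out |= toplevel_of(onto, t)
    return frozenset(out)


def rank_categories(
    onto: Ontology, term_occurrences: Iterable[str], k: Optional[int] = None
) -> list[str]:
    """Rank top-level categories by total term occurrences; keep the top k.

    ``term_occurrences`` is a flat iterable of term accessions *with
    multiplicity* (e.g. one entry per disease-term annotation); each
    occurrence counts once toward every category its term maps to.  Ties
    are broken by accession.  With ``k=None`` all categories that occur
    at least once are returned.
    """
    counts: Counter = Counter()
    for t in term_occurrences:
        for cat in toplevel_of(onto, t):
            counts[cat] += 1
    ranked = sorted(counts, key=lambda c: (-counts[c], c))
    return ranked if k is None else ranked[:k]
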