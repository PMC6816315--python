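"""Synthetic knowledge-base generator.

Emits self-contained corpora with the joint statistical structure the
analysis assumes — an ontology DAG with named top-level categories, genes
annotated to one or more diseases, disease annotation sets with tunable
category-level and term-level sharing between same-gene diseases,
score-weighted gene-disease associations, PPI graphs with planted
cliques, and gene-set libraries with planted enriched sets — in exactly
the file formats the loaders consume.

The two sharing knobs drive the modular-pleiotropy signature:

* ``rho_cat`` — probability that a same-gene disease keeps each of the
  reference disease's annotation categories (high: diseases affect the
  same body systems);
* ``rho_term`` — probability that, within a kept category, each
  reference term is reused (low: the specific signs differ).

Fresh terms are always drawn outside the reference term set, so the
expected term-level Jaccard/Tanimoto coefficient of same-gene pairs is
monotone in ``rho_term`` and the category-level one in ``rho_cat``.

A single integer seed drives one named pseudorandom stream per artifact
type, so regenerating one fixture does not perturb the others; fixed
seed means byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = ["GeneratorConfig", "SyntheticOntology", "make_ontology",
           "make_corpus", "make_associations", "make_ppi", "make_library",
           "make_traits", "generate"]

_STREAMS = {"ontology": 1, "corpus": 2, "associations": 3, "ppi": 4,
            "library": 5, "traits": 6}

_ONSETS = ("neonatal", "infancy", "childhood", "adolescence", "adult")
_INHERITANCE = ("AR", "AD", "XLR", "Mg/mf")
_PREVALENCE = ("<1/1,000,000", "1-9/1,000,000", "1-9/100,000")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults realise the planted-modular regime the analysis is designed
    to detect: 50 genes whose diseases share 90% of their annotation
    categories but only 10% of their specific terms.
    """

    seed: int = 0
    # ontology
    n_categories: int = 10
    terms_per_category: int = 12
    multi_parent_fraction: float = 0.1
    # corpus
    n_genes: int = 50
    diseases_per_gene: Tuple[int, int] = (1, 4)
    terms_per_disease: Tuple[int, int] = (4, 8)
    n_cats_per_disease: int = 3
    rho_cat: float = 0.9
    rho_term: float = 0.1
    crosswalk_fraction: float = 0.5
    annotation_jitter: float = 0.1
    non_iuis_fraction: float = 0.2
    n_disease_classes: int = 29
    freq_annotation_prob: float = 0.6
    # associations: (weight, (lo, hi)) mixture over the three strata
    score_mixture: Tuple[Tuple[float, Tuple[float, float]], ...] = (
        (0.2, (0.3, 1.0)), (0.3, (0.1, 0.3)), (0.5, (0.0, 0.1))
    )
    n_variants: int = 200
    # ppi
    ppi_n_nodes: int = 100
    ppi_edge_prob: float = 0.05
    ppi_clique_size: int = 5
    # gene-set library
    library_n_sets: int = 20
    library_set_size: int = 15
    library_planted_overlap: int = 8
    query_size: int = 10
    # phenotype <-> trait overlap
    n_overlap_genes: int = 5
    n_traits: int = 15

    def __post_init__(self):
        for name in ("multi_parent_fraction", "rho_cat", "rho_term",
                     "crosswalk_fraction", "annotation_jitter",
                     "non_iuis_fraction", "freq_annotation_prob",
                     "ppi_edge_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("diseases_per_gene", "terms_per_disease"):
            lo, hi = getattr(self, name)
            if not 1 <= lo <= hi:
                raise ValueError(f"{name} range {lo, hi} is empty or invalid")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


def _tid(i: int) -> str:
    return f"ST:{i:07d}"


@dataclass
class SyntheticOntology:
    """Generated ontology: OBO text plus the category/term bookkeeping."""

    obo_text: str
    root: str
    categories: List[str]
    category_terms: Dict[str, List[str]]  # primary category -> leaf terms
    term_primary: Dict[str, str]          # leaf term -> primary category


def make_ontology(cfg: GeneratorConfig) -> SyntheticOntology:
    """Root + categories + leaves, each leaf under one primary category.

    A ``multi_parent_fraction`` of leaves receives a second parent in a
    different category, making the graph a genuine DAG.
    """
    rng = cfg.rng("ontology")
    root = _tid(1)
    categories = [_tid(2 + i) for i in range(cfg.n_categories)]
    lines = ["format-version: 1.2", "ontology: synthetic-phenotypes", "",
             "[Term]", f"id: {root}", "name: Phenotypic abnormality (root)", ""]
    for i, cat in enumerate(categories):
        lines += ["[Term]", f"id: {cat}", f"name: category {i + 1:02d}",
                  f"is_a: {root}", ""]
    category_terms: Dict[str, List[str]] = {c: [] for c in categories}
    term_primary: Dict[str, str] = {}
    nxt = 2 + cfg.n_categories
    for ci, cat in enumerate(categories):
        for j in range(cfg.terms_per_category):
            term = _tid(nxt)
            nxt += 1
            category_terms[cat].append(term)
            term_primary[term] = cat
            lines += ["[Term]", f"id: {term}",
                      f"name: sign {ci + 1:02d}-{j + 1:02d}",
                      f"is_a: {cat}"]
            if cfg.n_categories > 1 and rng.random() < cfg.multi_parent_fraction:
                other = categories[
                    (ci + 1 + int(rng.integers(cfg.n_categories - 1)))
                    % cfg.n_categories
                ]
                lines.append(f"is_a: {other}")
            lines.append("")
    return SyntheticOntology(
        obo_text="\n".join(lines), root=root, categories=categories,
        category_terms=category_terms, term_primary=term_primary,
    )


def _sample_terms(
    rng: np.random.Generator,
    cats: Sequence[str],
    n: int,
    pools: Dict[str, List[str]],
    exclude: Set[str],
) -> List[str]:
    """Draw up to n distinct terms from the pools of ``cats``, avoiding ``exclude``."""
    available = sorted(
        t for c in cats for t in pools[c] if t not in exclude
    )
    if not available:
        return []
    n = min(n, len(available))
    picked = rng.choice(len(available), size=n, replace=False)
    return [available[i] for i in sorted(picked)]


def make_corpus(
    cfg: GeneratorConfig, onto: SyntheticOntology
) -> Dict[str, pd.DataFrame]:
    """Generate the disease/annotation/gene/crosswalk tables.

    Per gene: a reference disease fixes the category set and term sets;
    each further disease keeps categories with probability ``rho_cat``
    (resampling otherwise) and reuses reference terms within kept
    categories with probability ``rho_term`` (fresh non-reference terms
    otherwise).  A ``crosswalk_fraction`` of OMIM diseases is duplicated
    into ORPHANET with ``annotation_jitter`` term replacement, producing
    the matched cross-vocabulary pairs.
    """
    rng = cfg.rng("corpus")
    lo, hi = cfg.terms_per_disease
    if hi > cfg.n_cats_per_disease * cfg.terms_per_category:
        raise ValueError(
            "terms_per_disease exceeds the terms available in "
            f"{cfg.n_cats_per_disease} categories"
        )
    pools = onto.category_terms
    cats_all = onto.categories
    class_pool = [f"C{i + 1:02d}" for i in range(cfg.n_disease_classes)]

    disease_rows: List[dict] = []
    annotation_rows: List[dict] = []
    gene_rows: List[dict] = []
    crosswalk_rows: List[dict] = []
    next_omim = 300000
    next_orpha = 600000
    next_iuis = 1

    def _register(did: str, name: str, terms: Sequence[str], vocab: str) -> None:
        disease_rows.append({
            "disease_id": did,
            "name": name,
            "onset": _ONSETS[int(rng.integers(len(_ONSETS)))],
            "inheritance": ";".join(
                sorted(rng.choice(_INHERITANCE,
                                  size=int(rng.integers(1, 3)),
                                  replace=False))
            ),
            "prevalence_class": _PREVALENCE[int(rng.integers(len(_PREVALENCE)))],
            "classifications": ";".join(
                sorted(rng.choice(class_pool,
                                  size=int(rng.integers(1, 5)),
                                  replace=False))
            ),
        })
        for t in terms:
            freq = ""
            if rng.random() < cfg.freq_annotation_prob:
                u = rng.random()
                if u < 0.3:
                    freq = str(int(rng.integers(80, 100)))
                elif u < 0.7:
                    freq = str(int(rng.integers(30, 80)))
                elif u < 0.9:
                    freq = str(int(rng.integers(5, 30)))
                else:
                    freq = str(int(rng.integers(1, 5)))
            annotation_rows.append(
                {"disease_id": did, "db": vocab, "term_id": t, "frequency": freq}
            )

    for gi in range(cfg.n_genes):
        gene = f"G{gi + 1:04d}"
        k = int(rng.integers(cfg.diseases_per_gene[0],
                             cfg.diseases_per_gene[1] + 1))
        ref_cats: List[str] = []
        ref_terms: Set[str] = set()
        for dj in range(k):
            if dj == 0:
                idx = rng.choice(len(cats_all),
                                 size=min(cfg.n_cats_per_disease, len(cats_all)),
                                 replace=False)
                cats = sorted(cats_all[i] for i in sorted(idx))
                n_terms = int(rng.integers(lo, hi + 1))
                terms = _sample_terms(rng, cats, n_terms, pools, set())
                ref_cats, ref_terms = cats, set(terms)
            elif cfg.rho_cat == 1.0 and cfg.rho_term == 1.0:
                cats, terms = list(ref_cats), sorted(ref_terms)
            else:
                cats = []
                for c in ref_cats:
                    if rng.random() < cfg.rho_cat:
                        cats.append(c)
                    else:
                        others = [c2 for c2 in cats_all
                                  if c2 not in ref_cats and c2 not in cats]
                        if others:
                            cats.append(others[int(rng.integers(len(others)))])
                cats = sorted(set(cats))
                reused = sorted(
                    t for t in sorted(ref_terms)
                    if onto.term_primary[t] in cats and rng.random() < cfg.rho_term
                )
                n_terms = int(rng.integers(lo, hi + 1))
                fresh = _sample_terms(
                    rng, cats, max(0, n_terms - len(reused)), pools,
                    ref_terms | set(reused),
                )
                terms = sorted(set(reused) | set(fresh))
                if not terms:  # degenerate pools: fall back to any term
                    terms = _sample_terms(rng, cats, 1, pools, set())
            did = f"OMIM:{next_omim}"
            next_omim += 1
            _register(did, f"synthetic disease {did}", terms, "OMIM")
            gene_rows.append({"gene": gene, "disease_id": did})
            if rng.random() < cfg.non_iuis_fraction:
                # an "other rare disease" of this gene: outside the expert
                # list, hence no crosswalk row and no matched duplicate
                continue
            iuis = f"IUIS:{next_iuis:04d}"
            next_iuis += 1
            orpha_id = ""
            if rng.random() < cfg.crosswalk_fraction:
                orpha_id = f"ORPHA:{next_orpha}"
                next_orpha += 1
                jittered = []
                for t in terms:
                    if rng.random() < cfg.annotation_jitter:
                        repl = _sample_terms(
                            rng, [onto.term_primary[t]], 1, pools,
                            set(terms) | set(jittered),
                        )
                        jittered.append(repl[0] if repl else t)
                    else:
                        jittered.append(t)
                _register(orpha_id, f"synthetic disease {orpha_id}",
                          sorted(set(jittered)), "ORPHA")
                gene_rows.append({"gene": gene, "disease_id": orpha_id})
            crosswalk_rows.append(
                {"iuis_id": iuis, "omim_id": did, "orpha_id": orpha_id}
            )

    return {
        "diseases": pd.DataFrame(disease_rows),
        "annotations": pd.DataFrame(annotation_rows),
        "genes": pd.DataFrame(gene_rows),
        "crosswalk": pd.DataFrame(crosswalk_rows),
    }


def _draw_scores(rng: np.random.Generator, n: int,
                 mixture: Tuple[Tuple[float, Tuple[float, float]], ...]
                 ) -> np.ndarray:
    weights = np.array([w for w, _ in mixture], dtype=float)
    weights /= weights.sum()
    comp = rng.choice(len(mixture), size=n, p=weights)
    lo = np.array([b[0] for _, b in mixture])
    hi = np.array([b[1] for _, b in mixture])
    u = rng.random(n)
    return lo[comp] + u * (hi[comp] - lo[comp])


def make_associations(
    cfg: GeneratorConfig, genes_df: pd.DataFrame
) -> Dict[str, pd.DataFrame]:
    """Scored gene-disease associations and a variant table.

    One association per gene-disease link, scores drawn from the
    configured stratum mixture; variants get scores with roughly half in
    the high-confidence [0.65, 1] band and allele frequencies present for
    about half, log-uniform between 3e-5 and 0.5.
    """
    rng = cfg.rng("associations")
    links = genes_df.sort_values(["gene", "disease_id"]).reset_index(drop=True)
    scores = _draw_scores(rng, len(links), cfg.score_mixture)
    assoc = pd.DataFrame({
        "gene": links["gene"],
        "disease_id": links["disease_id"],
        "score": np.round(scores, 4),
    })
    genes = links["gene"].to_numpy()
    dids = links["disease_id"].to_numpy()
    rows = []
    for i in range(cfg.n_variants):
        j = int(rng.integers(len(links)))
        score = (
            rng.uniform(0.65, 1.0) if rng.random() < 0.5
            else rng.uniform(0.0, 0.65)
        )
        af = ""
        if rng.random() < 0.5:
            af = f"{10 ** rng.uniform(np.log10(3e-5), np.log10(0.5)):.6g}"
        rows.append({
            "variant_id": f"var{i + 1:05d}",
            "gene": genes[j],
            "disease_id": dids[j],
            "score": round(score, 4),
            "allele_frequency": af,
        })
    return {"associations": assoc, "variants": pd.DataFrame(rows)}


def make_ppi(cfg: GeneratorConfig, genes: Sequence[str]) -> pd.DataFrame:
    """Erdős–Rényi background plus a planted high-score clique.

    Nodes are the supplied genes, padded with filler proteins up to
    ``ppi_n_nodes``; background edges appear with ``ppi_edge_prob`` and
    uniform scores; the first ``ppi_clique_size`` genes form a complete
    clique at score 0.95.
    """
    rng = cfg.rng("ppi")
    nodes = list(genes)[: cfg.ppi_n_nodes]
    nodes += [f"N{i + 1:04d}" for i in range(cfg.ppi_n_nodes - len(nodes))]
    edges: Dict[Tuple[str, str], float] = {}
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if rng.random() < cfg.ppi_edge_prob:
                edges[(nodes[i], nodes[j])] = round(float(rng.random()), 3)
    clique = list(genes)[: cfg.ppi_clique_size]
    for i in range(len(clique)):
        for j in range(i + 1, len(clique)):
            a, b = sorted((clique[i], clique[j]))
            edges[(a, b)] = 0.95
    rows = [
        {"geneA": a, "geneB": b, "combined_score": s}
        for (a, b), s in sorted(edges.items())
    ]
    return pd.DataFrame(rows, columns=["geneA", "geneB", "combined_score"])


def make_library(
    cfg: GeneratorConfig, genes: Sequence[str]
) -> Tuple[Dict[str, List[str]], List[str]]:
    """Random gene sets plus one set with planted overlap against the query.

    Returns ``(sets, query)``; the query is the first ``query_size``
    genes, and ``set_planted`` contains ``library_planted_overlap`` of
    them.  The background universe is the genes plus filler symbols.
    """
    rng = cfg.rng("library")
    query = sorted(genes)[: cfg.query_size]
    background = sorted(genes) + [f"BG{i + 1:04d}" for i in range(200)]
    non_query = [g for g in background if g not in query]
    sets: Dict[str, List[str]] = {}
    for i in range(cfg.library_n_sets):
        idx = rng.choice(len(non_query), size=cfg.library_set_size, replace=False)
        sets[f"set_{i + 1:02d}"] = sorted(non_query[j] for j in sorted(idx))
    n_ov = min(cfg.library_planted_overlap, len(query), cfg.library_set_size)
    fill_idx = rng.choice(len(non_query), size=cfg.library_set_size - n_ov,
                          replace=False)
    sets["set_planted"] = sorted(
        query[:n_ov] + [non_query[j] for j in sorted(fill_idx)]
    )
    return sets, query


def make_traits(
    cfg: GeneratorConfig,
    gene_terms: Dict[str, Set[str]],
) -> Dict[str, pd.DataFrame]:
    """GWAS-style gene-trait table plus a term<->trait crosswalk.

    The first ``n_overlap_genes`` genes are planted overlaps: one of
    their phenotype terms is linked to a trait they also carry.  The
    remaining trait assignments are noise without crosswalk support.
    """
    rng = cfg.rng("traits")
    genes = sorted(gene_terms)
    traits = [f"trait_{i + 1:02d}" for i in range(cfg.n_traits)]
    trait_rows, xwalk_rows = [], []
    planted = [g for g in genes if gene_terms[g]][: cfg.n_overlap_genes]
    for i, gene in enumerate(planted):
        term = sorted(gene_terms[gene])[0]
        trait = traits[i % len(traits)]
        trait_rows.append({"gene": gene, "trait": trait})
        xwalk_rows.append({"hpo_id": term, "trait_label": trait})
    for gene in genes:
        if rng.random() < 0.3:
            trait_rows.append(
                {"gene": gene,
                 "trait": traits[int(rng.integers(len(traits)))]}
            )
    gt = pd.DataFrame(trait_rows, columns=["gene", "trait"])
    gt = gt.drop_duplicates().sort_values(["gene", "trait"]).reset_index(drop=True)
    xw = pd.DataFrame(xwalk_rows, columns=["hpo_id", "trait_label"])
    xw = xw.drop_duplicates().reset_index(drop=True)
    return {"gwas_traits": gt, "trait_crosswalk": xw}


def generate(cfg: GeneratorConfig, outdir) -> Dict[str, Path]:
    """Write the full synthetic knowledge base to ``outdir``.

    Produces ontology.obo, diseases/annotations/genes/crosswalk TSVs,
    associations and variants TSVs, ppi.tsv, library.gmt,
    gwas_traits.tsv, trait_crosswalk.tsv and a manifest.json recording
    the configuration.  Byte-identical for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    onto = make_ontology(cfg)
    corpus_tables = make_corpus(cfg, onto)
    assoc_tables = make_associations(cfg, corpus_tables["genes"])
    gene_list = sorted(corpus_tables["genes"]["gene"].unique())
    ppi = make_ppi(cfg, gene_list)
    sets, query = make_library(cfg, gene_list)

    terms_by_disease: Dict[str, Set[str]] = {}
    for r in corpus_tables["annotations"].itertuples(index=False):
        terms_by_disease.setdefault(r.disease_id, set()).add(r.term_id)
    gene_terms: Dict[str, Set[str]] = {}
    for r in corpus_tables["genes"].itertuples(index=False):
        gene_terms.setdefault(r.gene, set()).update(
            terms_by_disease.get(r.disease_id, set())
        )
    trait_tables = make_traits(cfg, gene_terms)

    paths: Dict[str, Path] = {}

    def _write_df(name: str, df: pd.DataFrame) -> None:
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p

    p = outdir / "ontology.obo"
    p.write_text(onto.obo_text, encoding="utf-8")
    paths["ontology"] = p
    for name, df in {**corpus_tables, **assoc_tables,
                     **trait_tables, "ppi": ppi}.items():
        _write_df(name, df)
    gmt = outdir / "library.gmt"
    with open(gmt, "w", encoding="utf-8") as fh:
        for name in sorted(sets):
            fh.write(f"{name}\tsynthetic\t" + "\t".join(sets[name]) + "\n")
    paths["library"] = gmt
    manifest = {
        "config": dataclasses.asdict(cfg),
        "root": onto.root,
        "query_genes": query,
        "ppi_clique_genes": gene_list[: cfg.ppi_clique_size],
    }
    mp = outdir / "manifest.json"
    with open(mp, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = mp
    return paths
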