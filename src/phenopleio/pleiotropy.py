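"""Two-level phenotypic-similarity profiling of disease pairs.

The scientific core of the package.  Diseases linked to the same gene
(gene-based pairs, per source vocabulary) and diseases matched across
vocabularies (crosswalk pairs) are compared at two levels of the
phenotype ontology:

* **term level** — raw annotation sets; the universe is the set of
  distinct terms annotated anywhere in the corpus;
* **category level** — annotation sets projected onto the selected
  top-level categories; the universe is the number of selected
  categories.

Low term-level similarity combined with high category-level similarity
for same-gene pairs is the signature of *modular pleiotropy*: one gene's
diseases present different specific signs that nevertheless affect the
same body systems.  The study quantifies this with Jaccard/Tanimoto
coefficients, exact hypergeometric significance, per-family BH FDR, and
Mann-Whitney contrasts between cohorts.

The study is exposed in the modelling idiom: build a
:class:`SimilarityStudy` from a loaded corpus and ontology, call
:meth:`~SimilarityStudy.fit`, and read the returned
:class:`SimilarityStudyResult` (per-pair profiles, summary statistics,
contrasts, ``summary()`` table).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .corpus import Corpus, CrosswalkRow
from .ontology import Ontology, project_to_categories, rank_categories
from .simstats import SetComparison, bh_fdr, compare_sets, jaccard_exact_p, rank_sum_compare

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

__all__ = [
    "DiseasePair",
    "PairSimilarityProfile",
    "gene_based_pairs",
    "crosswalk_pairs",
    "pair_similarity",
    "permute_disease_terms",
    "SimilarityStudy",
    "SimilarityStudyResult",
    "category_gene_similarity",
]


@dataclass(frozen=True)
class DiseasePair:
    """An unordered disease pair, canonically ordered d1 < d2."""

    d1: str
    d2: str
    shared_genes: FrozenSet[str] = frozenset()
    origin: str = "gene_based"  # gene_based | crosswalk

    def __post_init__(self):
        if self.d1 == self.d2:
            raise ValueError(f"degenerate pair: {self.d1}")
        if self.d1 > self.d2:
            raise ValueError("pair not canonically ordered (d1 < d2 required)")
        if self.origin == "gene_based" and not self.shared_genes:
            raise ValueError("gene-based pair requires a nonempty shared_genes set")


@dataclass(frozen=True)
class PairSimilarityProfile:
    pair: DiseasePair
    level: str  # term | category
    comparison: Optional[SetComparison]
    excluded: bool = False  # a side had no annotations at this level


def _vocab(disease_id: str) -> str:
    return disease_id.split(":", 1)[0]


def gene_based_pairs(
    gene_to_diseases: Mapping[str, Set[str]], vocabulary: str
) -> List[DiseasePair]:
    """All unique disease pairs sharing at least one gene, per vocabulary.

    Each gene with >= 2 diseases in the vocabulary contributes its
    C(k, 2) unordered pairs; a pair arising from several genes appears
    once, with the genes unioned into ``shared_genes``.
    """
    merged: Dict[Tuple[str, str], Set[str]] = {}
    for gene, dids in gene_to_diseases.items():
        in_vocab = sorted(d for d in dids if _vocab(d) == vocabulary)
        for i in range(len(in_vocab)):
            for j in range(i + 1, len(in_vocab)):
                merged.setdefault((in_vocab[i], in_vocab[j]), set()).add(gene)
    return [
        DiseasePair(d1, d2, frozenset(genes), origin="gene_based")
        for (d1, d2), genes in sorted(merged.items())
    ]


def crosswalk_pairs(crosswalk: Iterable[CrosswalkRow]) -> List[DiseasePair]:
    """One matched (OMIM, ORPHANET) pair per crosswalk row carrying both ids."""
    seen: Set[Tuple[str, str]] = set()
    out: List[DiseasePair] = []
    for row in crosswalk:
        if not (row.omim_id and row.orpha_id):
            continue
        d1, d2 = sorted((row.omim_id, row.orpha_id))
        if (d1, d2) in seen:
            continue
        seen.add((d1, d2))
        out.append(DiseasePair(d1, d2, frozenset(), origin="crosswalk"))
    return sorted(out, key=lambda p: (p.d1, p.d2))


def _level_sets(
    terms: Set[str], onto: Ontology, level: str, categories: FrozenSet[str]
) -> Set[str]:
    if level == "term":
        return set(terms)
    if level == "category":
        return set(project_to_categories(onto, terms) & categories)
    raise ValueError(f"unknown level: {level!r}")


def pair_similarity(
    pair: DiseasePair,
    disease_terms: Mapping[str, Set[str]],
    onto: Ontology,
    level: str,
    n_universe: int,
    categories: Optional[FrozenSet[str]] = None,
) -> PairSimilarityProfile:
    """Similarity profile of one pair at one level.

    A pair with an empty annotation set on either side (at the requested
    level) is flagged excluded rather than silently dropped.
    """
    cats = categories if categories is not None else onto.toplevel
    a = _level_sets(disease_terms.get(pair.d1, set()), onto, level, cats)
    b = _level_sets(disease_terms.get(pair.d2, set()), onto, level, cats)
    if not a or not b:
        return PairSimilarityProfile(pair, level, None, excluded=True)
    return PairSimilarityProfile(pair, level, compare_sets(a, b, n_universe))


def permute_disease_terms(
    disease_terms: Mapping[str, Set[str]], seed: int
) -> Dict[str, Set[str]]:
    """Reassign annotation sets across diseases uniformly at random.

    Null-calibration device: pair structure is kept, phenotype content is
    shuffled, so no genuine similarity signal survives.
    """
    rng = np.random.default_rng(seed)
    keys = sorted(disease_terms)
    sets = [set(disease_terms[k]) for k in keys]
    perm = rng.permutation(len(keys))
    return {k: sets[i] for k, i in zip(keys, perm)}


_COHORTS = ("omim_gene_based", "orphanet_gene_based", "crosswalk")
_CONTRAST_PAIRS = (
    ("omim_gene_based", "crosswalk"),
    ("orphanet_gene_based", "crosswalk"),
    ("omim_gene_based", "orphanet_gene_based"),
    ("pooled_gene_based", "crosswalk"),
)


class SimilarityStudy:
    """Model object for the two-level disease-pair similarity study.

    Parameters
    ----------
    corpus : Corpus
        Loaded knowledge base (diseases, annotations, genes, crosswalk).
    onto : Ontology
        Parsed phenotype ontology.
    top_k_categories : int or None
        Keep the k top-level categories with the most annotation
        occurrences; ``None`` keeps every category that occurs.
    fdr_level : float
        BH threshold used for flagging (one family per cohort x level).
    """

    def __init__(
        self,
        corpus: Corpus,
        onto: Ontology,
        top_k_categories: Optional[int] = None,
        fdr_level: float = 0.05,
    ):
        if not 0 < fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")
        self.corpus = corpus
        self.onto = onto
        self.top_k_categories = top_k_categories
        self.fdr_level = fdr_level

    def selected_categories(self) -> FrozenSet[str]:
        occurrences = [
            t for rec in self.corpus.diseases.values() for t in rec.terms
        ]
        return frozenset(
            rank_categories(self.onto, occurrences, self.top_k_categories)
        )

    def cohort_pairs(self) -> Dict[str, List[DiseasePair]]:
        return {
            "omim_gene_based": gene_based_pairs(
                self.corpus.gene_to_diseases, "OMIM"
            ),
            "orphanet_gene_based": gene_based_pairs(
                self.corpus.gene_to_diseases, "ORPHA"
            ),
            "crosswalk": crosswalk_pairs(self.corpus.crosswalk),
        }

    def fit(
        self, disease_terms: Optional[Mapping[str, Set[str]]] = None
    ) -> "SimilarityStudyResult":
        """Compute all pair profiles, FDR, summaries and contrasts.

        ``disease_terms`` overrides the corpus annotation map (used for
        permutation-null calibration); by default the corpus's own
        annotations are profiled.
        """
        terms = (
            {d: set(t) for d, t in disease_terms.items()}
            if disease_terms is not None
            else self.corpus.disease_terms()
        )
        categories = self.selected_categories()
        universes = {
            "term": len(set().union(*terms.values()) if terms else set()),
            "category": len(categories),
        }
        warnings: List[str] = []
        records = []
        for cohort, pairs in self.cohort_pairs().items():
            if not pairs:
                warnings.append(f"cohort {cohort} is empty")
            for level in ("term", "category"):
                profiles = [
                    pair_similarity(
                        p, terms, self.onto, level, universes[level], categories
                    )
                    for p in pairs
                ]
                included = [pr for pr in profiles if not pr.excluded]
                n_excl = len(profiles) - len(included)
                if n_excl:
                    warnings.append(
                        f"{cohort}/{level}: {n_excl} pair(s) excluded "
                        "(empty annotation side)"
                    )
                qvals = bh_fdr([pr.comparison.p for pr in included])
                qiter = iter(qvals)
                for pr in profiles:
                    cmp = pr.comparison
                    rec = {
                        "cohort": cohort,
                        "level": level,
                        "d1": pr.pair.d1,
                        "d2": pr.pair.d2,
                        "origin": pr.pair.origin,
                        "shared_genes": ";".join(sorted(pr.pair.shared_genes)),
                        "excluded": pr.excluded,
                    }
                    if cmp is not None:
                        rec.update(
                            na=cmp.na, nb=cmp.nb, nc=cmp.nc,
                            n_universe=cmp.n_universe,
                            T=cmp.T, p=cmp.p, q=float(next(qiter)),
                        )
                    records.append(rec)
        profile_cols = [
            "cohort", "level", "d1", "d2", "origin", "shared_genes",
            "excluded", "na", "nb", "nc", "n_universe", "T", "p", "q",
        ]
        profiles_df = pd.DataFrame(records, columns=profile_cols)

        stats_rows = []
        for (cohort, level), grp in profiles_df[~profiles_df.excluded].groupby(
            ["cohort", "level"], sort=True
        ):
            t = grp["T"].to_numpy()
            q25, q75 = np.percentile(t, [25, 75]) if len(t) else (np.nan, np.nan)
            stats_rows.append(
                {
                    "cohort": cohort, "level": level, "n": len(t),
                    "mean_T": float(np.mean(t)) if len(t) else np.nan,
                    "median_T": float(np.median(t)) if len(t) else np.nan,
                    "iqr_T": float(q75 - q25) if len(t) else np.nan,
                    "n_significant": int((grp["q"] < self.fdr_level).sum()),
                }
            )
        stats_df = pd.DataFrame(
            stats_rows,
            columns=["cohort", "level", "n", "mean_T", "median_T", "iqr_T",
                     "n_significant"],
        )

        contrasts = self._contrasts(profiles_df, warnings)
        return SimilarityStudyResult(
            profiles=profiles_df,
            cohort_stats=stats_df,
            contrasts=contrasts,
            categories=sorted(categories),
            universes=universes,
            fdr_level=self.fdr_level,
            warnings=warnings,
        )

    def _contrasts(
        self, profiles: pd.DataFrame, warnings: List[str]
    ) -> pd.DataFrame:
        inc = profiles[~profiles.excluded]
        rows = []
        for level in ("term", "category"):
            values: Dict[str, np.ndarray] = {}
            for cohort in _COHORTS:
                sel = inc[(inc.cohort == cohort) & (inc.level == level)]
                values[cohort] = sel["T"].to_numpy()
            values["pooled_gene_based"] = np.concatenate(
                [values["omim_gene_based"], values["orphanet_gene_based"]]
            )
            for a, b in _CONTRAST_PAIRS:
                if len(values[a]) < 2 or len(values[b]) < 2:
                    warnings.append(
                        f"contrast {a} vs {b} at {level} level skipped "
                        "(cohort with < 2 pairs)"
                    )
                    continue
                u, p = rank_sum_compare(values[a], values[b])
                rows.append(
                    {"level": level, "cohort_a": a, "cohort_b": b,
                     "n_a": len(values[a]), "n_b": len(values[b]),
                     "U": u, "p": p}
                )
        return pd.DataFrame(
            rows, columns=["level", "cohort_a", "cohort_b", "n_a", "n_b", "U", "p"]
        )


@dataclass
class SimilarityStudyResult:
    """Fitted similarity study: per-pair profiles, summaries, contrasts."""

    profiles: pd.DataFrame
    cohort_stats: pd.DataFrame
    contrasts: pd.DataFrame
    categories: List[str]
    universes: Dict[str, int]
    fdr_level: float
    warnings: List[str] = field(default_factory=list)

    def median_T(self, cohort: str, level: str) -> float:
        sel = self.cohort_stats[
            (self.cohort_stats.cohort == cohort)
            & (self.cohort_stats.level == level)
        ]
        return float(sel["median_T"].iloc[0]) if len(sel) else float("nan")

    def contrast_p(self, cohort_a: str, cohort_b: str, level: str) -> float:
        sel = self.contrasts[
            (self.contrasts.cohort_a == cohort_a)
            & (self.contrasts.cohort_b == cohort_b)
            & (self.contrasts.level == level)
        ]
        return float(sel["p"].iloc[0]) if len(sel) else float("nan")

    def summary(self) -> str:
        """Human-readable study summary table."""
        lines = ["Two-level disease-pair similarity study",
                 "=" * 40,
                 f"categories selected: {len(self.categories)}"
                 f" | term universe: {self.universes['term']}",
                 "",
                 "Cohort summaries (included pairs):"]
        lines.append(self.cohort_stats.to_string(index=False,
                                                 float_format="%.4f"))
        lines.append("")
        lines.append("Rank-sum contrasts of T distributions:")
        if len(self.contrasts):
            lines.append(self.contrasts.to_string(index=False,
                                                  float_format="%.4g"))
        else:
            lines.append("  (none computable)")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        """Write the per-pair profile table (fixed column order)."""
        df = self.profiles.copy()
        df.insert(0, "schema_version", SCHEMA_VERSION)
        df.to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "categories": self.categories,
            "universes": self.universes,
            "fdr_level": self.fdr_level,
            "cohort_stats": self.cohort_stats.to_dict(orient="records"),
            "contrasts": self.contrasts.to_dict(orient="records"),
            "warnings": self.warnings,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def category_gene_similarity(
    corpus: Corpus,
    onto: Ontology,
    categories: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Genetic similarity between top-level categories.

    Each category's gene set contains the genes with at least one
    annotated term mapping into it (via their diseases).  All unordered
    category pairs are scored with the Jaccard/Tanimoto coefficient and
    its exact p (universe = all corpus genes), BH-adjusted across the
    pair family.  Categories with no genes are excluded with a warning.
    """
    if categories is None:
        categories = sorted(
            SimilarityStudy(corpus, onto).selected_categories()
        )
    terms = corpus.disease_terms()
    gene_sets: Dict[str, Set[str]] = {c: set() for c in categories}
    for gene, dids in corpus.gene_to_diseases.items():
        gterms: Set[str] = set()
        for d in dids:
            gterms |= terms.get(d, set())
        for cat in project_to_categories(onto, gterms):
            if cat in gene_sets:
                gene_sets[cat].add(gene)
    empty = [c for c, s in gene_sets.items() if not s]
    for c in empty:
        logger.warning("category %s has no genes; excluded", c)
        del gene_sets[c]
    universe = len(corpus.gene_to_diseases)
    cats = sorted(gene_sets)
    rows = []
    for i in range(len(cats)):
        for j in range(i + 1, len(cats)):
            a, b = gene_sets[cats[i]], gene_sets[cats[j]]
            cmp = compare_sets(a, b, universe)
            rows.append(
                {"category_a": cats[i], "category_b": cats[j],
                 "na": cmp.na, "nb": cmp.nb, "nc": cmp.nc,
                 "n_universe": universe, "T": cmp.T, "p": cmp.p}
            )
    df = pd.DataFrame(
        rows, columns=["category_a", "category_b", "na", "nb", "nc",
                       "n_universe", "T", "p"]
    )
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
    else:
        df["q"] = pd.Series(dtype=float)
    return df
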