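"""Knowledge-base tables: diseases, annotations, genes, crosswalk, frequencies.

All inputs are tab-delimited UTF-8 files with a mandatory header row;
lines starting with ``#`` are comments.  Disease identity is always
vocabulary-qualified (``OMIM:102700``, ``ORPHA:39041``, ``IUIS:...``):
the "same disease" across vocabularies exists only through the crosswalk,
never through name matching.

Expected headers
----------------
diseases.tsv     disease_id  name  onset  inheritance  prevalence_class  classifications
annotations.tsv  disease_id  db  term_id  frequency        (frequency: percent or blank)
genes.tsv        gene  disease_id
crosswalk.tsv    iuis_id  omim_id  orpha_id                (blank cells allowed)

``inheritance`` and ``classifications`` may hold several ``;``-separated
labels.  An optional override crosswalk with the same header carries
manual curation; its rows replace auto rows for the same IUIS id.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .ontology import Ontology, toplevel_of

logger = logging.getLogger(__name__)

__all__ = [
    "CorpusError",
    "DiseaseRecord",
    "FrequencyAnnotation",
    "CrosswalkRow",
    "Corpus",
    "FREQUENCY_BANDS",
    "read_tsv",
    "classify_frequency",
    "load_corpus",
    "frequent_symptom_table",
    "summarize_corpus",
]


class CorpusError(ValueError):
    """Referential-integrity or format violation in an input table."""


@dataclass
class DiseaseRecord:
    disease_id: str
    name: str
    terms: Set[str] = field(default_factory=set)
    onset: Optional[str] = None
    inheritance: Tuple[str, ...] = ()
    prevalence_class: Optional[str] = None
    classifications: FrozenSet[str] = frozenset()

    @property
    def vocabulary(self) -> str:
        return self.disease_id.split(":", 1)[0]


# ORPHANET frequency bands, as (lo, hi) percent bounds per class.
FREQUENCY_BANDS: Dict[str, Tuple[int, int]] = {
    "obligate": (100, 100),
    "very_frequent": (80, 99),
    "frequent": (30, 79),
    "occasional": (5, 29),
    "very_rare": (1, 4),
    "excluded": (0, 0),
}


@dataclass(frozen=True)
class FrequencyAnnotation:
    disease_id: str
    term: str
    freq_class: str
    range_lo: int
    range_hi: int


@dataclass(frozen=True)
class CrosswalkRow:
    iuis_id: str
    omim_id: Optional[str]
    orpha_id: Optional[str]
    provenance: str = "auto"  # auto | override


@dataclass
class Corpus:
    """Loaded and validated knowledge base."""

    diseases: Dict[str, DiseaseRecord]
    gene_to_diseases: Dict[str, Set[str]]
    crosswalk: List[CrosswalkRow]
    freq_annotations: List[FrequencyAnnotation]

    def disease_terms(self) -> Dict[str, Set[str]]:
        return {d: rec.terms for d, rec in self.diseases.items()}

    def genes(self) -> List[str]:
        return sorted(self.gene_to_diseases)

    def annotated_terms(self) -> Set[str]:
        """Distinct ontology terms annotated to at least one disease.

        This is the sampling universe for term-level similarity tests.
        """
        out: Set[str] = set()
        for rec in self.diseases.values():
            out |= rec.terms
        return out


def read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    """Read a headered, '#'-commented TSV and check required columns."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CorpusError(f"{path}: missing required column(s) {missing}")
    return df


def classify_frequency(pct: float) -> str:
    """Map a percent prevalence to its ORPHANET frequency class.

    Obligate 100%; very frequent 80-99%; frequent 30-79%; occasional
    5-29%; very rare 1-4%; excluded 0%.  Non-integer values fall in the
    band whose integer edges bracket them (right-open closure).
    """
    if not 0 <= pct <= 100:
        raise ValueError(f"percent out of range: {pct}")
    if pct == 100:
        return "obligate"
    if pct >= 80:
        return "very_frequent"
    if pct >= 30:
        return "frequent"
    if pct >= 5:
        return "occasional"
    if pct > 0:
        return "very_rare"
    return "excluded"


def _split_multi(cell: str) -> Tuple[str, ...]:
    return tuple(s.strip() for s in cell.split(";") if s.strip())


def load_corpus(
    onto: Ontology,
    diseases_path,
    annotations_path,
    genes_path,
    crosswalk_path,
    overrides_path=None,
) -> Corpus:
    """Load all tables, enforce referential integrity, and assemble a Corpus.

    Every annotation row must reference a declared disease and a term
    resolvable in the ontology; offenders are collected and reported in a
    single :class:`CorpusError`.  Exactly duplicated rows are dropped
    with a warning (the result equals the deduplicated input).
    """
    ddf = read_tsv(diseases_path, ["disease_id", "name"])
    adf = read_tsv(annotations_path, ["disease_id", "term_id"])
    gdf = read_tsv(genes_path, ["gene", "disease_id"])

    diseases: Dict[str, DiseaseRecord] = {}
    for row in ddf.itertuples(index=False):
        did = row.disease_id
        if did in diseases:
            raise CorpusError(f"duplicate disease_id {did!r} in disease table")
        diseases[did] = DiseaseRecord(
            disease_id=did,
            name=row.name,
            onset=getattr(row, "onset", "") or None,
            inheritance=_split_multi(getattr(row, "inheritance", "")),
            prevalence_class=getattr(row, "prevalence_class", "") or None,
            classifications=frozenset(_split_multi(getattr(row, "classifications", ""))),
        )

    problems: List[str] = []
    n_dups = 0
    seen_ann: Set[Tuple[str, str]] = set()
    freq_annotations: List[FrequencyAnnotation] = []
    for i, row in enumerate(adf.itertuples(index=False), start=2):
        did, term = row.disease_id, row.term_id
        if did not in diseases:
            problems.append(f"annotations row {i}: unknown disease {did!r}")
            continue
        try:
            term = onto.resolve(term)
        except KeyError:
            problems.append(f"annotations row {i}: unknown term {row.term_id!r}")
            continue
        if (did, term) in seen_ann:
            n_dups += 1
            continue
        seen_ann.add((did, term))
        diseases[did].terms.add(term)
        freq_cell = getattr(row, "frequency", "")
        if freq_cell != "":
            if freq_cell in FREQUENCY_BANDS:
                cls = freq_cell
            else:
                cls = classify_frequency(float(freq_cell))
            lo, hi = FREQUENCY_BANDS[cls]
            freq_annotations.append(
                FrequencyAnnotation(did, term, cls, lo, hi)
            )
    if n_dups:
        logger.warning("dropped %d duplicated annotation row(s)", n_dups)

    gene_to_diseases: Dict[str, Set[str]] = defaultdict(set)
    for i, row in enumerate(gdf.itertuples(index=False), start=2):
        if row.disease_id not in diseases:
            problems.append(f"genes row {i}: unknown disease {row.disease_id!r}")
            continue
        gene_to_diseases[row.gene].add(row.disease_id)

    if problems:
        raise CorpusError(
            "referential integrity violations:\n  " + "\n  ".join(problems)
        )

    crosswalk = _load_crosswalk(crosswalk_path, overrides_path)
    logger.info(
        "corpus loaded: %d diseases, %d genes, %d annotations, %d crosswalk rows",
        len(diseases), len(gene_to_diseases), len(seen_ann), len(crosswalk),
    )
    return Corpus(
        diseases=diseases,
        gene_to_diseases=dict(gene_to_diseases),
        crosswalk=crosswalk,
        freq_annotations=freq_annotations,
    )


def _load_crosswalk(path, overrides_path=None) -> List[CrosswalkRow]:
    cols = ["iuis_id", "omim_id", "orpha_id"]
    auto = read_tsv(path, cols)
    rows: List[CrosswalkRow] = []
    override_iuis: Set[str] = set()
    if overrides_path is not None:
        over = read_tsv(overrides_path, cols)
        for r in over.itertuples(index=False):
            override_iuis.add(r.iuis_id)
            rows.append(
                CrosswalkRow(r.iuis_id, r.omim_id or None, r.orpha_id or None,
                             provenance="override")
            )
    for r in auto.itertuples(index=False):
        if r.iuis_id in override_iuis:
            continue  # manual curation wins
        rows.append(
            CrosswalkRow(r.iuis_id, r.omim_id or None, r.orpha_id or None)
        )
    seen: Set[Tuple[Optional[str], Optional[str]]] = set()
    deduped: List[CrosswalkRow] = []
    for r in rows:
        key = (r.omim_id, r.orpha_id)
        if r.omim_id and r.orpha_id and key in seen:
            logger.warning("duplicate crosswalk pair %s dropped", key)
            continue
        seen.add(key)
        deduped.append(r)
    return deduped


def frequent_symptom_table(
    freq_annotations: Iterable[FrequencyAnnotation],
    onto: Ontology,
    min_diseases: int = 3,
    classes: Tuple[str, ...] = ("frequent", "very_frequent"),
) -> pd.DataFrame:
    """Clinical signs recurring across diseases at frequent+ prevalence.

    Keeps every (term, frequency class) combination — restricted to the
    requested classes — observed in at least ``min_diseases`` distinct
    diseases, grouped by the term's top-level categories (a multi-category
    term appears once per category).  Sorted by category, then number of
    diseases descending, then term accession.
    """
    if min_diseases < 1:
        raise ValueError("min_diseases must be >= 1")
    per_key: Dict[Tuple[str, str], Set[str]] = defaultdict(set)
    for fa in freq_annotations:
        if fa.freq_class in classes:
            per_key[(fa.term, fa.freq_class)].add(fa.disease_id)
    rows = []
    for (term, cls), dis in per_key.items():
        if len(dis) >= min_diseases:
            for cat in sorted(toplevel_of(onto, term)):
                rows.append(
                    {"category": cat, "term": term, "freq_class": cls,
                     "n_diseases": len(dis)}
                )
    df = pd.DataFrame(rows, columns=["category", "term", "freq_class", "n_diseases"])
    if len(df):
        df = df.sort_values(
            ["category", "n_diseases", "term"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return df


def _crosswalk_ids(crosswalk: Iterable[CrosswalkRow]) -> Set[str]:
    out: Set[str] = set()
    for r in crosswalk:
        out.add(r.iuis_id)
        if r.omim_id:
            out.add(r.omim_id)
        if r.orpha_id:
            out.add(r.orpha_id)
    return out


def summarize_corpus(corpus: Corpus) -> Dict[str, dict]:
    """Descriptive summaries, split by crosswalk membership.

    Diseases whose id appears in the crosswalk form the ``iuis``
    partition; the rest are ``non_iuis``.  Per partition: histograms of
    onset, inheritance, prevalence class, genes per disease and
    classifications per disease.  ``gene_venn`` counts genes linked only
    to crosswalk diseases, only to others, or to both.
    """
    member = _crosswalk_ids(corpus.crosswalk)
    disease_genes: Dict[str, Set[str]] = defaultdict(set)
    for g, dids in corpus.gene_to_diseases.items():
        for d in dids:
            disease_genes[d].add(g)

    out: Dict[str, dict] = {}
    for part in ("iuis", "non_iuis"):
        recs = [
            r for d, r in corpus.diseases.items()
            if (d in member) == (part == "iuis")
        ]
        out[part] = {
            "n_diseases": len(recs),
            "onset": dict(Counter(r.onset for r in recs if r.onset)),
            "inheritance": dict(
                Counter(m for r in recs for m in r.inheritance)
            ),
            "prevalence_class": dict(
                Counter(r.prevalence_class for r in recs if r.prevalence_class)
            ),
            "n_genes_per_disease": dict(
                Counter(len(disease_genes[r.disease_id]) for r in recs)
            ),
            "n_classifications_per_disease": dict(
                Counter(len(r.classifications) for r in recs)
            ),
        }

    venn = {"iuis_only": 0, "both": 0, "non_iuis_only": 0}
    for g, dids in corpus.gene_to_diseases.items():
        has_iuis = any(d in member for d in dids)
        has_other = any(d not in member for d in dids)
        if has_iuis and has_other:
            venn["both"] += 1
        elif has_iuis:
            venn["iuis_only"] += 1
        elif has_other:
            venn["non_iuis_only"] += 1
    out["gene_venn"] = venn
    return out
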