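"""Scored gene-disease association handling.

Covers the DisGeNET-style layer of the pipeline: score stratification
into the S1/S2/S3 confidence groups, reporting of diseases carrying more
than one high-score gene association, the disease specificity (DSI) and
disease pleiotropy (DPI) indices, and variant-level summaries.

Score strata: S1 >= 0.3, S2 in [0.1, 0.3), S3 < 0.1.  The middle band is
printed as "0.1-0.29" in two-decimal score conventions; the half-open
closure makes the partition exhaustive for continuous scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ScoredAssociation",
    "VariantAssociation",
    "GeneMetrics",
    "load_associations",
    "load_variants",
    "load_reference_multigene_table",
    "stratify",
    "multi_gene_diseases",
    "dsi",
    "dpi",
    "gene_metrics",
    "variant_summary",
]


@dataclass(frozen=True)
class ScoredAssociation:
    gene: str
    disease_id: str
    score: float
    source_count: Optional[int] = None

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"association score out of [0,1]: {self.score}")


@dataclass(frozen=True)
class VariantAssociation:
    variant_id: str
    gene: str
    disease_id: str
    score: float
    allele_frequency: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"variant score out of [0,1]: {self.score}")
        af = self.allele_frequency
        if af is not None and not 0.0 < af <= 1.0:
            raise ValueError(f"allele frequency out of (0,1]: {af}")


@dataclass(frozen=True)
class GeneMetrics:
    gene: str
    n_diseases: int
    dsi: float
    dpi: Optional[float]


def load_associations(path) -> List[ScoredAssociation]:
    """Read a gene/disease_id/score TSV; duplicated keys keep the first row."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    out: List[ScoredAssociation] = []
    seen = set()
    for row in df.itertuples(index=False):
        key = (row.gene, row.disease_id)
        if key in seen:
            logger.warning("duplicate association %s dropped", key)
            continue
        seen.add(key)
        out.append(ScoredAssociation(row.gene, row.disease_id, float(row.score)))
    return out


def load_variants(path) -> List[VariantAssociation]:
    """Read a variant TSV (empty allele_frequency cell = missing)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        af = getattr(row, "allele_frequency", "")
        out.append(
            VariantAssociation(
                row.variant_id, row.gene, row.disease_id, float(row.score),
                float(af) if af != "" else None,
            )
        )
    return out


def load_reference_multigene_table() -> pd.DataFrame:
    """The packaged curated table of multi-gene inborn errors of immunity.

    One row per (disease, gene) with the association score, the PPI
    cluster id (blank = singleton), the printed per-disease PPI
    enrichment p-value string, and its parsed float (reporting-floor
    values like "<1.0E-16" parse to the floor).
    """
    ref = resources.files("phenopleio.data") / "multigene_disease_associations.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                         keep_default_na=False)
    df["score"] = df["score"].astype(float)
    df["ppi_p_value"] = df["ppi_p"].str.lstrip("<").astype(float)
    return df


def stratify(assocs: Iterable[ScoredAssociation]) -> Dict[str, List[ScoredAssociation]]:
    """Partition associations into the S1/S2/S3 score groups."""
    out: Dict[str, List[ScoredAssociation]] = {"S1": [], "S2": [], "S3": []}
    for a in assocs:
        if a.score >= 0.3:
            out["S1"].append(a)
        elif a.score >= 0.1:
            out["S2"].append(a)
        else:
            out["S3"].append(a)
    return out


def multi_gene_diseases(
    assocs: Iterable[ScoredAssociation],
    min_genes: int = 2,
    min_score: float = 0.3,
) -> pd.DataFrame:
    """Diseases with at least ``min_genes`` associations at score >= ``min_score``.

    One row per retained disease with its gene list sorted by descending
    score (symbol-ascending on ties).  Output is independent of input row
    order.
    """
    if min_genes < 1 or min_score <= 0:
        raise ValueError("thresholds must be positive")
    per_disease: Dict[str, List[ScoredAssociation]] = {}
    for a in assocs:
        if a.score >= min_score:
            per_disease.setdefault(a.disease_id, []).append(a)
    rows = []
    for did in sorted(per_disease):
        hits = per_disease[did]
        if len(hits) < min_genes:
            continue
        hits.sort(key=lambda a: (-a.score, a.gene))
        rows.append(
            {
                "disease_id": did,
                "n_genes": len(hits),
                "genes": [a.gene for a in hits],
                "scores": [a.score for a in hits],
            }
        )
    return pd.DataFrame(rows, columns=["disease_id", "n_genes", "genes", "scores"])


def dsi(n_diseases_gene: int, n_diseases_total: int) -> float:
    """Disease specificity index.

    ``DSI = log(d_g / d_T) / log(1 / d_T)`` where d_g is the gene's
    disease count and d_T the total disease count: 1 for a gene tied to a
    single disease, 0 for a gene tied to every disease.  Base-independent.
    """
    if n_diseases_gene < 1:
        raise ValueError("DSI undefined for a gene with zero diseases")
    if n_diseases_total < 2 or n_diseases_gene > n_diseases_total:
        raise ValueError("need 1 <= n_diseases_gene <= n_diseases_total, total >= 2")
    return math.log(n_diseases_gene / n_diseases_total) / math.log(1 / n_diseases_total)


def dpi(disease_classes_of_gene: Iterable[str], n_classes_total: int) -> Optional[float]:
    """Disease pleiotropy index: fraction of disease classes the gene spans.

    Returns ``None`` (recorded as missing) when none of the gene's
    diseases carry a class label.
    """
    if n_classes_total < 1:
        raise ValueError("n_classes_total must be >= 1")
    classes = set(disease_classes_of_gene)
    if not classes:
        return None
    return len(classes) / n_classes_total


def gene_metrics(
    assocs: Iterable[ScoredAssociation],
    disease_classes: Mapping[str, Set[str]],
    n_classes_total: int = 29,
) -> List[GeneMetrics]:
    """Per-gene disease count, DSI and DPI over an association table.

    ``disease_classes`` maps disease ids to their classification labels
    (the DPI class system; the default total of 29 matches the MeSH
    disease-class count used by DisGeNET).  DSI needs at least two
    distinct diseases in the table overall.
    """
    gene_diseases: Dict[str, Set[str]] = {}
    for a in assocs:
        gene_diseases.setdefault(a.gene, set()).add(a.disease_id)
    all_diseases = set().union(*gene_diseases.values()) if gene_diseases else set()
    total = len(all_diseases)
    out = []
    for gene in sorted(gene_diseases):
        dids = gene_diseases[gene]
        classes = set()
        for d in dids:
            classes |= set(disease_classes.get(d, ()))
        out.append(
            GeneMetrics(
                gene=gene,
                n_diseases=len(dids),
                dsi=dsi(len(dids), total),
                dpi=dpi(classes, n_classes_total),
            )
        )
    return out


def variant_summary(
    variants: Iterable[VariantAssociation],
    af_threshold: float = 0.05,
    score_lo: float = 0.65,
    score_hi: float = 1.0,
) -> dict:
    """Counts over a variant-association table.

    Reports the total variant count, how many carry allele-frequency
    data, the minimum observed AF, how many exceed ``af_threshold``
    (common variants), and how many have association scores inside
    ``[score_lo, score_hi]`` (the high-confidence band).
    """
    variants = list(variants)
    afs = [v.allele_frequency for v in variants if v.allele_frequency is not None]
    return {
        "n_variants": len(variants),
        "n_af_present": len(afs),
        "min_af": min(afs) if afs else None,
        "n_af_above_threshold": sum(1 for af in afs if af > af_threshold),
        "n_score_in_range": sum(
            1 for v in variants if score_lo <= v.score <= score_hi
        ),
    }
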