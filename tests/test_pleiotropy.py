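"""Disease-pair construction and the two-level similarity study."""

import numpy as np
import pytest

from phenopleio.corpus import CrosswalkRow
from phenopleio.ontology import parse_obo
from phenopleio.pleiotropy import (
    DiseasePair,
    SimilarityStudy,
    category_gene_similarity,
    crosswalk_pairs,
    gene_based_pairs,
    pair_similarity,
    permute_disease_terms,
)
from phenopleio.corpus import load_corpus
from phenopleio.synthetic import GeneratorConfig, generate

from .conftest import write_toy_corpus
from .oracles import intersection_tail_p


class TestGeneBasedPairs:
    def test_three_diseases_give_three_pairs(self):
        pairs = gene_based_pairs({"g": {"OMIM:1", "OMIM:2", "OMIM:3"}}, "OMIM")
        assert len(pairs) == 3
        assert all(p.shared_genes == {"g"} for p in pairs)
        assert all(p.d1 < p.d2 for p in pairs)

    def test_shared_pair_deduplicated_with_union(self):
        pairs = gene_based_pairs(
            {"g1": {"OMIM:1", "OMIM:2"}, "g2": {"OMIM:1", "OMIM:2"}}, "OMIM"
        )
        assert len(pairs) == 1
        assert pairs[0].shared_genes == {"g1", "g2"}

    def test_disjoint_genes_full_count(self):
        mapping = {
            f"g{i}": {f"OMIM:{3 * i + j}" for j in range(3)} for i in range(5)
        }
        pairs = gene_based_pairs(mapping, "OMIM")
        assert len(pairs) == 15  # 5 genes x C(3,2)

    def test_vocabulary_filter(self):
        pairs = gene_based_pairs({"g": {"OMIM:1", "ORPHA:2", "OMIM:3"}}, "OMIM")
        assert len(pairs) == 1

    def test_upper_bound_on_pair_count(self):
        rng = np.random.default_rng(0)
        mapping = {
            f"g{i}": {f"OMIM:{rng.integers(20)}" for _ in range(4)}
            for i in range(10)
        }
        pairs = gene_based_pairs(mapping, "OMIM")
        bound = sum(
            len(d) * (len(d) - 1) // 2 for d in mapping.values()
        )
        assert len(pairs) <= bound


class TestCrosswalkPairs:
    def test_full_row_yields_pair(self):
        rows = [CrosswalkRow("IUIS:1", "OMIM:100", "ORPHA:5")]
        (pair,) = crosswalk_pairs(rows)
        assert (pair.d1, pair.d2) == ("OMIM:100", "ORPHA:5")
        assert pair.origin == "crosswalk" and pair.shared_genes == frozenset()

    def test_partial_row_skipped(self):
        assert crosswalk_pairs([CrosswalkRow("IUIS:1", "OMIM:100", None)]) == []

    def test_duplicate_target_pair_deduplicated(self):
        rows = [CrosswalkRow("IUIS:1", "OMIM:100", "ORPHA:5"),
                CrosswalkRow("IUIS:2", "OMIM:100", "ORPHA:5")]
        assert len(crosswalk_pairs(rows)) == 1


class TestPairSimilarity:
    def test_identical_sets_are_maximal_at_both_levels(self, toy_onto):
        pair = DiseasePair("OMIM:1", "OMIM:2", frozenset({"g"}))
        terms = {"OMIM:1": {"TT:0010", "TT:0013"},
                 "OMIM:2": {"TT:0010", "TT:0013"}}
        for level, universe in (("term", 6), ("category", 3)):
            prof = pair_similarity(pair, terms, toy_onto, level, universe)
            assert prof.comparison.T == 1.0

    def test_modular_signature_case(self, toy_onto):
        # disjoint terms projecting into the same single category
        pair = DiseasePair("OMIM:1", "OMIM:2", frozenset({"g"}))
        terms = {"OMIM:1": {"TT:0010"}, "OMIM:2": {"TT:0011"}}
        t = pair_similarity(pair, terms, toy_onto, "term", 6)
        c = pair_similarity(pair, terms, toy_onto, "category", 3)
        assert t.comparison.T == 0.0
        assert c.comparison.T == 1.0

    def test_partial_overlap_counts(self, toy_onto):
        pair = DiseasePair("OMIM:1", "OMIM:2", frozenset({"g"}))
        terms = {"OMIM:1": {"TT:0010", "TT:0011", "TT:0012"},
                 "OMIM:2": {"TT:0012", "TT:0013"}}
        prof = pair_similarity(pair, terms, toy_onto, "term", 6)
        cmp = prof.comparison
        assert (cmp.na, cmp.nb, cmp.nc) == (3, 2, 1)
        assert cmp.T == pytest.approx(1 / 4)  # nc/(na+nb-nc)
        cat = pair_similarity(pair, terms, toy_onto, "category", 3).comparison
        # {C1, C2} vs {C1(only via TT:0012? no: TT:0012 in C1+C2), C2}
        assert cat.T == pytest.approx(1.0)

    def test_empty_side_is_flagged_excluded(self, toy_onto):
        pair = DiseasePair("OMIM:1", "OMIM:2", frozenset({"g"}))
        prof = pair_similarity(
            pair, {"OMIM:1": {"TT:0010"}, "OMIM:2": set()}, toy_onto, "term", 6
        )
        assert prof.excluded and prof.comparison is None


class TestSimilarityStudy:
    def test_modular_planting_recovers_signature(self, synth_corpus):
        onto, corpus = synth_corpus
        result = SimilarityStudy(corpus, onto).fit()
        gap = (result.median_T("omim_gene_based", "category")
               - result.median_T("omim_gene_based", "term"))
        assert gap > 0.3
        p = result.contrast_p("omim_gene_based", "crosswalk", "term")
        assert p < 0.05

    def test_degenerate_identical_copies(self, tmp_path):
        cfg = GeneratorConfig(seed=3, n_genes=15, annotation_jitter=0.0,
                              crosswalk_fraction=1.0, non_iuis_fraction=0.0,
                              diseases_per_gene=(2, 3))
        generate(cfg, tmp_path)
        onto = parse_obo(tmp_path / "ontology.obo")
        corpus = load_corpus(onto, tmp_path / "diseases.tsv",
                             tmp_path / "annotations.tsv",
                             tmp_path / "genes.tsv", tmp_path / "crosswalk.tsv")
        result = SimilarityStudy(corpus, onto).fit()
        xw = result.profiles[(result.profiles.cohort == "crosswalk")
                             & (result.profiles.level == "term")]
        assert (xw["T"] == 1.0).all()
        assert result.contrast_p("pooled_gene_based", "crosswalk",
                                 "term") < 0.05

    def test_missing_cohort_reported_with_warning(self, tmp_path):
        paths = write_toy_corpus(tmp_path)
        # strip ORPHANET diseases entirely
        (tmp_path / "genes.tsv").write_text(
            "gene\tdisease_id\ng1\tOMIM:1\ng1\tOMIM:2\ng2\tOMIM:3\ng2\tOMIM:4\n"
        )
        (tmp_path / "diseases.tsv").write_text(
            "disease_id\tname\nOMIM:1\ta\nOMIM:2\tb\nOMIM:3\tc\nOMIM:4\td\n"
        )
        (tmp_path / "annotations.tsv").write_text(
            "disease_id\tdb\tterm_id\tfrequency\n"
            "OMIM:1\tOMIM\tTT:0010\t\nOMIM:2\tOMIM\tTT:0011\t\n"
            "OMIM:3\tOMIM\tTT:0013\t\nOMIM:4\tOMIM\tTT:0014\t\n"
        )
        (tmp_path / "crosswalk.tsv").write_text(
            "iuis_id\tomim_id\torpha_id\nIUIS:1\tOMIM:1\t\n"
        )
        onto = parse_obo(paths["ontology"])
        corpus = load_corpus(onto, tmp_path / "diseases.tsv",
                             tmp_path / "annotations.tsv",
                             tmp_path / "genes.tsv", tmp_path / "crosswalk.tsv")
        result = SimilarityStudy(corpus, onto).fit()
        assert any("orphanet_gene_based is empty" in w for w in result.warnings)
        omim = result.profiles[result.profiles.cohort == "omim_gene_based"]
        assert len(omim) > 0

    def test_profiles_satisfy_count_invariants(self, synth_corpus):
        onto, corpus = synth_corpus
        result = SimilarityStudy(corpus, onto).fit()
        inc = result.profiles[~result.profiles.excluded]
        assert (inc.nc <= np.minimum(inc.na, inc.nb)).all()
        assert (inc.na <= inc.n_universe).all() and (inc.nb <= inc.n_universe).all()
        cat = inc[inc.level == "category"]
        assert (cat.n_universe == len(result.categories)).all()
        assert inc["T"].between(0, 1).all()
        assert (inc.q >= inc.p - 1e-12).all()

    def test_null_permutation_rarely_significant(self, synth_corpus):
        onto, corpus = synth_corpus
        study = SimilarityStudy(corpus, onto)
        terms = corpus.disease_terms()
        frac = []
        for seed in range(5):
            res = study.fit(disease_terms=permute_disease_terms(terms, seed))
            inc = res.profiles[~res.profiles.excluded]
            frac.append(float((inc.q < 0.05).mean()))
        assert np.mean(frac) <= 0.10

    def test_summary_mentions_cohorts(self, synth_corpus):
        onto, corpus = synth_corpus
        text = SimilarityStudy(corpus, onto).fit().summary()
        assert "omim_gene_based" in text and "crosswalk" in text


class TestCategoryGeneSimilarity:
    def test_identical_gene_sets_maximal(self, toy_corpus):
        onto, corpus = toy_corpus
        df = category_gene_similarity(corpus, onto)
        assert (df["T"] <= 1.0).all() and (df["T"] >= 0.0).all()
        assert (df["q"] >= df["p"] - 1e-12).all()

    def test_hand_counted_pair(self):
        # categories with gene sets {g1..g4} and {g3..g6} in a 10-gene corpus
        from phenopleio.simstats import compare_sets

        cmp = compare_sets({"g1", "g2", "g3", "g4"},
                           {"g3", "g4", "g5", "g6"}, 10)
        assert cmp.T == pytest.approx(2 / 6)
        assert cmp.p == pytest.approx(float(intersection_tail_p(10, 4, 4, 2)),
                                      rel=1e-12)

    def test_single_category_empty_matrix(self, toy_corpus):
        onto, corpus = toy_corpus
        df = category_gene_similarity(corpus, onto, categories=["TT:0002"])
        assert len(df) == 0
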