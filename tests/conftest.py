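"""Shared fixtures: a hand-checkable toy ontology + corpus, and a seeded
synthetic knowledge base generated once per session."""

from __future__ import annotations

from pathlib import Path

import pytest

from phenopleio.corpus import load_corpus
from phenopleio.ontology import parse_obo
from phenopleio.synthetic import GeneratorConfig, generate

TOY_OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: TT:0001
name: root

[Term]
id: TT:0002
name: category one
is_a: TT:0001

[Term]
id: TT:0003
name: category two
is_a: TT:0001

[Term]
id: TT:0004
name: category three
is_a: TT:0001

[Term]
id: TT:0010
name: sign one
is_a: TT:0002

[Term]
id: TT:0011
name: sign two (deep)
is_a: TT:0010

[Term]
id: TT:0012
name: sign three (two categories)
is_a: TT:0002
is_a: TT:0003

[Term]
id: TT:0013
name: sign four
is_a: TT:0003

[Term]
id: TT:0014
name: sign five
is_a: TT:0004

[Term]
id: TT:0015
name: sign six
is_a: TT:0004
"""

DISEASES_TSV = """\
disease_id\tname\tonset\tinheritance\tprevalence_class\tclassifications
OMIM:1\tdisease one\tinfancy\tAR\t<1/1,000,000\tA;B
OMIM:2\tdisease two\tneonatal\tAR\t<1/1,000,000\tA
OMIM:3\tdisease three\tchildhood\tAD\t1-9/1,000,000\tB;C
OMIM:4\tdisease four\t\t\t\tC
OMIM:5\tdisease five\t\t\t\t
OMIM:6\tdisease six\t\t\t\t
OMIM:7\tdisease seven\t\t\t\t
ORPHA:11\tdisease one (orpha)\t\t\t\tA
ORPHA:12\tdisease twelve\t\t\t\t
"""

ANNOTATIONS_TSV = """\
disease_id\tdb\tterm_id\tfrequency
OMIM:1\tOMIM\tTT:0010\t85
OMIM:1\tOMIM\tTT:0011\t45
OMIM:1\tOMIM\tTT:0012\t
OMIM:2\tOMIM\tTT:0012\t
OMIM:2\tOMIM\tTT:0013\t40
OMIM:3\tOMIM\tTT:0014\t
OMIM:4\tOMIM\tTT:0010\t
OMIM:4\tOMIM\tTT:0013\t35
OMIM:4\tOMIM\tTT:0014\t
OMIM:5\tOMIM\tTT:0011\t50
OMIM:6\tOMIM\tTT:0015\t
OMIM:7\tOMIM\tTT:0011\t60
OMIM:7\tOMIM\tTT:0015\t
ORPHA:11\tORPHA\tTT:0010\t
ORPHA:11\tORPHA\tTT:0011\t
ORPHA:11\tORPHA\tTT:0012\t
ORPHA:12\tORPHA\tTT:0013\t
"""

GENES_TSV = """\
gene\tdisease_id
g1\tOMIM:1
g1\tOMIM:2
g1\tORPHA:11
g2\tOMIM:3
g2\tOMIM:4
g3\tOMIM:5
g4\tORPHA:12
g5\tOMIM:6
g5\tOMIM:7
g6\tOMIM:6
"""

CROSSWALK_TSV = """\
iuis_id\tomim_id\torpha_id
IUIS:1\tOMIM:1\tORPHA:11
IUIS:2\tOMIM:2\t
IUIS:3\tOMIM:3\t
"""


def write_toy_corpus(tmp_path: Path) -> dict:
    """Write the hand-checkable 6-gene / 9-disease corpus; return paths."""
    paths = {
        "ontology": tmp_path / "ontology.obo",
        "diseases": tmp_path / "diseases.tsv",
        "annotations": tmp_path / "annotations.tsv",
        "genes": tmp_path / "genes.tsv",
        "crosswalk": tmp_path / "crosswalk.tsv",
    }
    paths["ontology"].write_text(TOY_OBO)
    paths["diseases"].write_text(DISEASES_TSV)
    paths["annotations"].write_text(ANNOTATIONS_TSV)
    paths["genes"].write_text(GENES_TSV)
    paths["crosswalk"].write_text(CROSSWALK_TSV)
    return paths


@pytest.fixture(scope="session")
def toy_onto():
    import io

    return parse_obo(io.StringIO(TOY_OBO))


@pytest.fixture()
def toy_corpus(tmp_path):
    paths = write_toy_corpus(tmp_path)
    onto = parse_obo(paths["ontology"])
    corpus = load_corpus(
        onto, paths["diseases"], paths["annotations"], paths["genes"],
        paths["crosswalk"],
    )
    return onto, corpus


@pytest.fixture(scope="session")
def synth_dir(tmp_path_factory):
    """Default-condition synthetic knowledge base, generated once."""
    out = tmp_path_factory.mktemp("synth")
    generate(GeneratorConfig(seed=1), out)
    return out


@pytest.fixture(scope="session")
def synth_corpus(synth_dir):
    onto = parse_obo(synth_dir / "ontology.obo")
    corpus = load_corpus(
        onto,
        synth_dir / "diseases.tsv",
        synth_dir / "annotations.tsv",
        synth_dir / "genes.tsv",
        synth_dir / "crosswalk.tsv",
    )
    return onto, corpus
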