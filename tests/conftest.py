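import sys
from pathlib import Path

import dendropy
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make the naive oracles importable

from repsum.airr_io import CloneTreeSet, RepertoireTable
from repsum.synthetic_data import default_spec, generate_repertoire


def make_table(records, trees=None) -> RepertoireTable:
    return RepertoireTable.from_records(records, trees=trees)


@pytest.fixture
def annotated_records():
    """Six handcrafted records exercising every recognized AIRR field."""
    return [
        dict(
            sequence_alignment="ATGCGTACGT", germline_alignment="ATGCGAACGT",
            junction="TGTGCGTGG", junction_aa="CAW",
            v_call="IGHV1-2*02,IGHV1-2*04", d_call="IGHD3-10*01", j_call="IGHJ4*02",
            v_3p_deletion=0, v_5p_deletion=0, d_3p_deletion=1, d_5p_deletion=2,
            j_3p_deletion=0, j_5p_deletion=3, np1="AAG", np2="",
            clone_id="1", productive=True, locus="IGH",
        ),
        dict(
            sequence_alignment="ATGC.TACGT", germline_alignment="ATGCGTAC-T",
            junction="TGTGCG", junction_aa="CA",
            v_call="IGHV1-2*02", d_call="IGHD3-10*01", j_call="IGHJ4*02",
            v_3p_deletion=2, v_5p_deletion=0, d_3p_deletion=0, d_5p_deletion=0,
            j_3p_deletion=0, j_5p_deletion=1, np1="GG", np2="TA",
            clone_id="1", productive=True, locus="IGH",
        ),
        dict(
            sequence_alignment="GGGGCCCCAA", germline_alignment="GGGGCCCCAA",
            junction="TGTAAATGG", junction_aa="CKW",
            v_call="IGHV3-23*01", d_call="IGHD2-2*01", j_call="IGHJ6*01",
            v_3p_deletion=1, v_5p_deletion=0, d_3p_deletion=4, d_5p_deletion=0,
            j_3p_deletion=0, j_5p_deletion=0, np1="", np2="C",
            clone_id="2", productive=True, locus="IGH",
        ),
        dict(
            sequence_alignment="TTTTAAAACC", germline_alignment="TTTAAAAACC",
            junction="TGTTTTTTTTGG", junction_aa="CFFW",
            v_call="IGHV3-23*01", d_call="IGHD2-2*01", j_call="IGHJ4*02",
            v_3p_deletion=5, v_5p_deletion=0, d_3p_deletion=0, d_5p_deletion=1,
            j_3p_deletion=0, j_5p_deletion=2, np1="ACGT", np2="GG",
            clone_id="2", productive=False, locus="IGH",
        ),
        dict(
            sequence_alignment="ATATATATAT", germline_alignment="ATATATATAT",
            junction="TGTCATTGG", junction_aa="CHW",
            v_call="IGHV1-2*02", d_call="IGHD3-10*01", j_call="IGHJ6*01",
            v_3p_deletion=0, v_5p_deletion=0, d_3p_deletion=2, d_5p_deletion=2,
            j_3p_deletion=0, j_5p_deletion=0, np1="TT", np2="AC",
            clone_id="3", productive=True, locus="IGH",
        ),
        dict(
            sequence_alignment="ANGTCGTNCA", germline_alignment="ACGTCGTACA",
            junction="TGTGATTGG", junction_aa="CDW",
            v_call="IGHV4-34*01", d_call="IGHD2-2*01", j_call="IGHJ4*02",
            v_3p_deletion=3, v_5p_deletion=0, d_3p_deletion=0, d_5p_deletion=0,
            j_3p_deletion=0, j_5p_deletion=1, np1="GAGA", np2="T",
            clone_id="3", productive=True, locus="IGH",
        ),
    ]


@pytest.fixture
def annotated_table(annotated_records):
    return make_table(annotated_records)


@pytest.fixture(scope="session")
def synthetic_table():
    """A medium synthetic repertoire shared across read-only tests."""
    return generate_repertoire(default_spec(seed=5, n_sequences=80))


def tree_from_tuple(tup) -> dendropy.Tree:
    from naive import to_newick

    return dendropy.Tree.get(
        data=to_newick(tup) + ";", schema="newick", rooting="force-rooted"
    )


@pytest.fixture
def tree_set():
    """Balanced and caterpillar 4-leaf trees plus a 3-leaf star."""
    balanced = (("a", "b"), ("c", "d"))
    caterpillar = ((("a", "b"), "c"), "d")
    star = ("x", "y", "z")
    return (
        CloneTreeSet(
            {
                "balanced": tree_from_tuple(balanced),
                "caterpillar": tree_from_tuple(caterpillar),
                "star": tree_from_tuple(star),
            }
        ),
        {"balanced": balanced, "caterpillar": caterpillar, "star": star},
    )
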