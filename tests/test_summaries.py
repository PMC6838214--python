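import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import naive
from conftest import make_table
from repsum import aa_properties as aap
from repsum.airr_io import degap, normalize_gene_call
from repsum.summaries import (
    COLDSPOT_MOTIFS,
    HOTSPOT_MOTIFS,
    CategoricalCounts,
    EmptySummaryError,
    aa_kmer_counts,
    aa_property_distribution,
    cdr3_length_distribution,
    cluster_size_distribution,
    colless_like_index,
    gc_content_distribution,
    gene_usage_counts,
    germline_distance_distribution,
    hill_diversity,
    in_frame_percentage,
    insertion_transition_matrix,
    motif_count_distribution,
    nearest_neighbor_distribution,
    pairwise_distance_distribution,
    per_gene_substitution_rates,
    positional_mutation_distances,
    rearrangement_length_distribution,
    string_distance,
    tree_shape_indices,
)

SEQ = st.text(alphabet="ACGT", min_size=0, max_size=12)


class TestStringMetrics:
    @given(a=SEQ, b=SEQ)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_levenshtein_matches_dp_oracle_and_is_symmetric(self, a, b):
        d = string_distance(a, b)
        assert d == naive.levenshtein(a, b)
        assert d == string_distance(b, a)
        assert d >= 0

    def test_hamming_requires_equal_lengths(self):
        assert string_distance("ACGT", "ACTT", metric="hamming") == 1
        with pytest.raises(ValueError):
            string_distance("AC", "ACG", metric="hamming")


class TestSequenceSummaries:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCC", 1.0), ("ATAT", 0.0), ("GANT", 1 / 3)],
    )
    def test_gc_content_excludes_ambiguous_bases(self, seq, expected):
        t = make_table([{"sequence_alignment": seq}])
        assert gc_content_distribution(t).values[0] == pytest.approx(expected)

    def test_gc_content_skips_allgap_records(self):
        t = make_table(
            [{"sequence_alignment": "NNN"}, {"sequence_alignment": "GGCC"}]
        )
        dist = gc_content_distribution(t)
        assert dist.values.tolist() == [1.0]
        with pytest.raises(EmptySummaryError):
            gc_content_distribution(make_table([{"sequence_alignment": "NN"}]))

    @pytest.mark.parametrize(
        "seqs,expected",
        [
            (["AAAA", "AAAT"], [1]),
            (["AC", "AC", "GT"], [0, 2, 2]),
            (["TT", "TT", "TT"], [0, 0, 0]),
        ],
    )
    def test_pairwise_distances_match_brute_force(self, seqs, expected):
        got = sorted(pairwise_distance_distribution(seqs).values)
        assert got == sorted(naive.pairwise_distances(seqs))
        assert got == sorted(map(float, expected))

    def test_nearest_neighbor_hand_examples(self):
        assert sorted(
            nearest_neighbor_distribution(["AAAA", "AAAT", "TTTT"], k=1).values
        ) == [1, 1, 3]
        assert nearest_neighbor_distribution(["A", "A"], k=1).values.tolist() == [0, 0]
        with pytest.raises(ValueError):
            nearest_neighbor_distribution(["A", "C"], k=2)

    def test_nearest_neighbor_subset_inequality(self):
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(15)]
        full = nearest_neighbor_distribution(seqs, k=1).values
        for _ in range(25):
            keep = sorted(rng.choice(len(seqs), size=8, replace=False))
            sub = [seqs[i] for i in keep]
            sub_nn = nearest_neighbor_distribution(sub, k=1).values
            for pos, orig in enumerate(keep):
                assert sub_nn[pos] >= full[orig]

    @pytest.mark.parametrize(
        "seq,motifs,expected",
        [("TACTAC", ["WRC"], 2), ("GTC", ["SYC"], 1), ("TNCTAC", ["WRC"], 1)],
    )
    def test_motif_counts_match_sliding_window(self, seq, motifs, expected):
        t = make_table([{"sequence_alignment": seq}])
        got = motif_count_distribution(t, motifs).values[0]
        assert got == naive.motif_count(seq, motifs) == expected

    def test_motif_errors(self):
        t = make_table([{"sequence_alignment": "ACGT"}])
        with pytest.raises(ValueError):
            motif_count_distribution(t, [])
        with pytest.raises(ValueError, match="IUPAC"):
            motif_count_distribution(t, ["WRZ"])


class TestAnnotationSummaries:
    def test_cdr3_lengths(self):
        t = make_table(
            [
                {"junction": "TGTGCG", "junction_aa": "CA"},
                {"junction": "TGT", "junction_aa": None},
            ]
        )
        assert sorted(cdr3_length_distribution(t, "nt").values) == [3, 6]
        aa = cdr3_length_distribution(t, "aa")
        assert aa.values.tolist() == [2]
        assert aa.n_source == 1

    def test_gene_usage_first_call_and_allele_collapse(self):
        t = make_table(
            [
                {"v_call": "IGHV1-2*02,IGHV1-2*04", "d_call": "IGHD3-10*01", "j_call": "IGHJ4*02"},
                {"v_call": "IGHV1-2*04", "d_call": "IGHD3-10*02", "j_call": "IGHJ4*01"},
            ]
        )
        joint = gene_usage_counts(t, ("V", "D", "J"))
        assert joint.counts == {("IGHV1-2", "IGHD3-10", "IGHJ4"): 2}

    def test_marginal_equals_joint_axis_sum(self, synthetic_table):
        joint = gene_usage_counts(synthetic_table, ("V", "D", "J"))
        v_marginal = gene_usage_counts(synthetic_table, ("V",))
        collapsed: dict = {}
        for (v, _, _), c in joint.counts.items():
            collapsed[v] = collapsed.get(v, 0) + c
        assert collapsed == v_marginal.counts

    def test_aa_property_reference_values(self):
        t = make_table([{"junction_aa": "A"}])
        assert aa_property_distribution(t, "gravy").values[0] == pytest.approx(1.8)
        t = make_table([{"junction_aa": "FWYA"}])
        assert aa_property_distribution(t, "aromaticity").values[0] == pytest.approx(0.75)
        assert aa_property_distribution(
            make_table([{"junction_aa": "K"}]), "charge"
        ).values[0] > 0
        assert aa_property_distribution(
            make_table([{"junction_aa": "D"}]), "charge"
        ).values[0] < 0

    def test_aliphatic_index_formula(self):
        # mole-percent form: pure Ala = 100, pure Leu = 390
        assert aa_property_distribution(
            make_table([{"junction_aa": "AA"}]), "aliphatic_index"
        ).values[0] == pytest.approx(100.0)
        assert aa_property_distribution(
            make_table([{"junction_aa": "L"}]), "aliphatic_index"
        ).values[0] == pytest.approx(390.0)

    def test_nonstandard_residues_skipped(self):
        t = make_table([{"junction_aa": "CXR"}, {"junction_aa": "CAR"}])
        dist = aa_property_distribution(t, "gravy")
        assert dist.n_source == 1

    def test_kmer_counts_and_conservation(self):
        t = make_table([{"junction_aa": "CAR"}, {"junction_aa": "AAA"}])
        two = aa_kmer_counts(t, 2)
        assert two.counts == {"CA": 1, "AR": 1, "AA": 2}
        assert two.total == sum(max(len(s) - 1, 0) for s in ("CAR", "AAA"))
        assert aa_kmer_counts(make_table([{"junction_aa": "AAA"}]), 1).counts == {"A": 3}

    def test_rearrangement_lengths_from_columns_and_np_strings(self):
        t = make_table(
            [
                {"v_3p_deletion": 0, "np1": ""},
                {"v_3p_deletion": 2, "np1": "AAG"},
                {"v_3p_deletion": 2, "np1": "T"},
            ]
        )
        assert sorted(rearrangement_length_distribution(t, "v_3p_deletion").values) == [0, 2, 2]
        assert sorted(rearrangement_length_distribution(t, "np1_length").values) == [0, 1, 3]

    def test_transition_matrix_hand_example(self):
        t = make_table([{"np1": "AAG"}])
        m = insertion_transition_matrix(t, "np1")
        assert m.counts[0, 0] == 1 and m.counts[0, 2] == 1
        assert m.entries[0].tolist() == [0.5, 0.0, 0.5, 0.0]
        with pytest.raises(EmptySummaryError):
            insertion_transition_matrix(make_table([{"np1": "A"}, {"np1": "G"}]), "np1")

    def test_transition_rows_normalized(self, synthetic_table):
        m = insertion_transition_matrix(synthetic_table, "np1")
        rowsums = m.entries.sum(axis=1)
        for i, s in enumerate(rowsums):
            assert s == pytest.approx(1.0 if m.counts[i].sum() else 0.0)

    def test_germline_distance(self):
        t = make_table(
            [
                {"sequence_alignment": "AAAT", "germline_alignment": "AAAA"},
                {"sequence_alignment": "CCCC", "germline_alignment": "CCCC"},
            ]
        )
        assert sorted(germline_distance_distribution(t).values) == [0, 1]

    def test_positional_mutation_distances(self):
        t = make_table(
            [
                {"sequence_alignment": "ATAT", "germline_alignment": "AAAA"},
                {"sequence_alignment": "ACGT", "germline_alignment": "ACGA"},
            ]
        )
        dist = positional_mutation_distances(t)
        # mutations at offsets 1 and 3 in the first record; single mutation
        # in the second contributes nothing
        assert dist.values.tolist() == [2]
        assert (dist.values >= 1).all()

    def test_per_gene_substitution_rates(self):
        t = make_table(
            [
                {"v_call": "IGHV1*01", "sequence_alignment": "AAAT", "germline_alignment": "AAAA"},
                {"v_call": "IGHV1*02", "sequence_alignment": "CCCC", "germline_alignment": "CCCC"},
            ]
        )
        rates = per_gene_substitution_rates(t)
        assert rates == {"IGHV1": pytest.approx(1 / 8)}
        per_pos = per_gene_substitution_rates(t, per_position=True)["IGHV1"]
        assert per_pos.tolist() == [0.0, 0.0, 0.0, 0.5]

    def test_in_frame_percentage(self):
        t = make_table([{"junction": "A" * 9}, {"junction": "A" * 10}])
        assert in_frame_percentage(t) == pytest.approx(50.0)
        assert in_frame_percentage(make_table([{"junction": "AAA"}])) == 100.0


class TestClusterSummaries:
    def test_cluster_sizes_and_conservation(self):
        t = make_table([{"clone_id": "1"}, {"clone_id": "1"}, {"clone_id": "2"}])
        dist = cluster_size_distribution(t)
        assert sorted(dist.values) == [1, 2]
        assert dist.values.sum() == 3

    @pytest.mark.parametrize(
        "counts,q,expected",
        [
            ({"a": 5, "b": 5, "c": 5, "d": 5}, 0.0, 4.0),
            ({"a": 5, "b": 5, "c": 5, "d": 5}, 1.0, 4.0),
            ({"a": 5, "b": 5, "c": 5, "d": 5}, 2.0, 4.0),
            ({"a": 3, "b": 1}, 2.0, 1.6),
            ({"a": 3, "b": 1, "c": 2}, 0.0, 3.0),
        ],
    )
    def test_hill_numbers(self, counts, q, expected):
        cc = CategoricalCounts(counts, "clusters")
        assert hill_diversity(cc, q) == pytest.approx(expected)
        assert hill_diversity(cc, q) == pytest.approx(naive.hill(counts.values(), q))

    def test_hill_rejects_negative_order(self):
        with pytest.raises(ValueError):
            hill_diversity(CategoricalCounts({"a": 1}, "c"), -1)


class TestTreeSummaries:
    def test_sackin_hand_values(self, tree_set):
        trees, shapes = tree_set
        dist = tree_shape_indices(trees, "sackin")
        got = {
            name: naive.sackin(shape)
            for name, shape in shapes.items()
        }
        assert got["balanced"] == 8 and got["caterpillar"] == 9
        assert sorted(dist.values) == sorted(
            float(naive.sackin(s)) for s in shapes.values()
        )

    def test_cophenetic_star_is_zero(self, tree_set):
        trees, shapes = tree_set
        dist = tree_shape_indices(trees, "cophenetic")
        values = dict(zip(trees.trees.keys(), dist.values))
        assert values["star"] == 0.0
        for name in shapes:
            assert values[name] == pytest.approx(naive.cophenetic(shapes[name]))

    def test_colless_like_matches_enumeration(self, tree_set):
        trees, shapes = tree_set
        dist = tree_shape_indices(trees, "colless_like")
        values = dict(zip(trees.trees.keys(), dist.values))
        for name in shapes:
            assert values[name] == pytest.approx(naive.colless_like(shapes[name]))


class TestInvariants:
    def test_summaries_permutation_invariant(self, annotated_table):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(annotated_table))
        shuffled = annotated_table.subset(perm)
        for fn in (
            gc_content_distribution,
            lambda t: cdr3_length_distribution(t, "nt"),
            germline_distance_distribution,
            lambda t: motif_count_distribution(t, HOTSPOT_MOTIFS),
        ):
            a = sorted(fn(annotated_table).values)
            b = sorted(fn(shuffled).values)
            assert a == b

    def test_markov_chain_transition_recovery(self):
        # pooled transition frequencies converge to the generating matrix
        rng = np.random.default_rng(11)
        T = np.array(
            [
                [0.7, 0.1, 0.1, 0.1],
                [0.1, 0.7, 0.1, 0.1],
                [0.25, 0.25, 0.25, 0.25],
                [0.4, 0.1, 0.4, 0.1],
            ]
        )
        strings = []
        for _ in range(400):
            s = [rng.integers(4)]
            for _ in range(14):
                s.append(rng.choice(4, p=T[s[-1]]))
            strings.append("".join("ACGT"[i] for i in s))
        t = make_table([{"np1": s} for s in strings])
        m = insertion_transition_matrix(t, "np1")
        assert np.abs(m.entries - T).sum(axis=1).max() < 0.1
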