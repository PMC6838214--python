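import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import naive
from conftest import make_table
from repsum.divergence import (
    LN2,
    compare_repertoires,
    discretize,
    jsd,
    l1_divergence,
    matrix_l1,
    results_to_frame,
)
from repsum.summaries import CategoricalCounts, insertion_transition_matrix

SAMPLE = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=1, max_size=40
)


class TestDiscretize:
    def test_bin_count_scales_with_smaller_support(self):
        p = [0.0, 1.0, 2.0, 3.0, 4.0]  # support 5
        q = list(np.linspace(0, 4, 9))  # support 9
        bp, _ = discretize(p, q)
        # B = max(min(5, 9), 2) = 5 bins before any removal
        assert len(bp.bin_edges) - 1 == 5

    def test_two_constant_samples_use_lower_bound_of_two_bins(self):
        bp, bq = discretize([1.0, 1.0], [1.0])
        assert len(bp.bin_edges) - 1 == 2

    def test_one_sided_bins_dropped_and_renormalized(self):
        # values 0 and 1 in P only, 2 in both: the pure-P bins are discarded
        p = [0.0, 2.0]
        q = [2.0, 2.0]
        bp, bq = discretize(p, q)
        assert bp.probs.sum() == pytest.approx(1.0)
        assert bq.probs.sum() == pytest.approx(1.0)
        assert (bp.probs == bq.probs).all()


class TestJSD:
    @given(x=SAMPLE)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_identity_on_self(self, x):
        assert jsd(x, x).value == 0.0

    @given(x=SAMPLE, y=SAMPLE)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_and_bounded(self, x, y):
        a = jsd(x, y).value
        b = jsd(y, x).value
        assert a == pytest.approx(b, abs=1e-12)
        assert 0.0 <= a <= LN2

    def test_disjoint_supports_are_maximally_divergent(self):
        with pytest.warns(UserWarning, match="maximal divergence"):
            r = jsd([0.0, 0.1], [10.0, 10.1])
        assert r.value == pytest.approx(LN2)

    def test_matches_discrete_oracle_on_shared_bins(self):
        p = [0, 0, 1, 1, 1, 2]
        q = [0, 1, 1, 2, 2, 2]
        bp, bq = discretize(p, q)
        expected = naive.jensen_shannon_discrete(bp.probs, bq.probs)
        assert jsd(p, q).value == pytest.approx(expected)

    def test_same_distribution_jsd_shrinks_with_sample_size(self):
        # integer-valued summaries (lengths, counts, distances) have bounded
        # support, so two large samples from one distribution converge
        rng = np.random.default_rng(3)
        small = jsd(rng.poisson(5, size=50), rng.poisson(5, size=50)).value
        big = jsd(rng.poisson(5, size=20000), rng.poisson(5, size=20000)).value
        assert big < 0.01
        assert big < small


class TestL1:
    def test_hand_examples(self):
        a = CategoricalCounts({"A": 3, "B": 1}, "u")
        b = CategoricalCounts({"A": 1, "B": 2}, "u")
        assert l1_divergence(a, b).value == 3
        assert l1_divergence(a, b, normalize=True).value == pytest.approx(5 / 6)
        assert l1_divergence(a, a).value == 0

    def test_missing_categories_count_as_zero(self):
        a = CategoricalCounts({"A": 2}, "u")
        b = CategoricalCounts({"B": 2}, "u")
        assert l1_divergence(a, b).value == 4

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            cats = list("ABCDE")
            x, y, z = (
                CategoricalCounts(
                    {c: int(k) for c, k in zip(cats, rng.integers(0, 9, 5))}, "u"
                )
                for _ in range(3)
            )
            dxy = l1_divergence(x, y).value
            dyz = l1_divergence(y, z).value
            dxz = l1_divergence(x, z).value
            assert dxz <= dxy + dyz + 1e-12

    def test_matrix_l1_flattens_cells(self):
        t1 = make_table([{"np1": "AAG"}])
        t2 = make_table([{"np1": "AAG"}])
        m1 = insertion_transition_matrix(t1, "np1")
        m2 = insertion_transition_matrix(t2, "np1")
        assert matrix_l1(m1, m2).value == 0.0


class TestCompareRepertoires:
    def test_self_comparison_is_zero_everywhere(self, annotated_table):
        results = compare_repertoires(annotated_table, annotated_table)
        for r in results:
            if not r.skipped:
                assert r.value == pytest.approx(0.0, abs=1e-12), r.summary_name

    def test_alignment_only_pair_skips_annotated_summaries(self):
        t = make_table(
            [
                {"sequence_alignment": "ACGTACGT"},
                {"sequence_alignment": "ACGTTCGT"},
                {"sequence_alignment": "AGGTACGA"},
            ]
        )
        results = compare_repertoires(t, t)
        by_name = {r.summary_name: r for r in results}
        assert not by_name["gc_content"].skipped
        assert by_name["v_usage"].skipped
        assert "capability" in by_name["v_usage"].reason

    def test_output_covers_capability_intersection(self, annotated_table):
        aligned_only = make_table(
            [{"sequence_alignment": s} for s in annotated_table.column("sequence_alignment")]
        )
        results = compare_repertoires(annotated_table, aligned_only)
        computed = {r.summary_name for r in results if not r.skipped}
        skipped = {r.summary_name for r in results if r.skipped}
        assert "gc_content" in computed
        assert {"v_usage", "cdr3_length", "cluster_size"} <= skipped

    def test_tidy_frame_round_trip(self, annotated_table):
        df = results_to_frame(compare_repertoires(annotated_table, annotated_table))
        assert set(["summary", "method", "value", "n_left", "n_right"]) <= set(df.columns)
        assert len(df) > 10
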