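"""Duplex architecture classification and the span mixture model."""

import numpy as np
import pytest

from duplexatlas.duplexfold import DuplexStructure
from duplexatlas.features import (
    annotate_loops,
    classify_symmetry,
    composition,
    duplex_features,
    fit_span_mixture,
    span_classify,
)


def build(arm1_len, arm2_len, pairs):
    """DuplexStructure with explicit pairing on poly-G/poly-C arms."""
    return DuplexStructure(
        arm1_seq="G" * arm1_len, arm2_seq="C" * arm2_len,
        pairing=sorted(pairs), energy=-1.0,
    )


def helix(n, arm1_len=None, arm2_len=None, offset1=0, offset2=0):
    """n stacked pairs starting at offset1 in arm1, ending near the 3' end
    of arm2 (antiparallel)."""
    a1 = arm1_len or (n + offset1)
    a2 = arm2_len or (n + offset2)
    pairs = [(offset1 + k, a2 - 1 - offset2 - k) for k in range(n)]
    return build(a1, a2, pairs)


class TestLoops:
    def test_uninterrupted_helix_has_no_loops(self):
        assert annotate_loops(helix(5)) == []

    def test_single_nt_gap_on_one_arm_is_bulge(self):
        # pairs (0,9),(1,8) then skip arm1 position 2, resume (3,7),(4,6)
        st = build(5, 10, [(0, 9), (1, 8), (3, 7), (4, 6)])
        loops = annotate_loops(st)
        assert len(loops) == 1
        lp = loops[0]
        assert (lp.kind, lp.arm1_len, lp.arm2_len, lp.stem_position) == ("bulge", 1, 0, 1)

    def test_two_nt_gap_both_arms_is_internal_loop(self):
        st = build(6, 6, [(0, 5), (1, 4), (4, 1), (5, 0)])
        loops = annotate_loops(st)
        assert len(loops) == 1
        assert (loops[0].kind, loops[0].arm1_len, loops[0].arm2_len) == ("internal_loop", 2, 2)

    def test_empty_pairing_errors(self):
        with pytest.raises(ValueError):
            annotate_loops(build(4, 4, []))


class TestSymmetry:
    def test_perfect(self):
        assert classify_symmetry(helix(4)) == "perfect"

    def test_mirrored_internal_loop_is_symmetric(self):
        st = build(6, 6, [(0, 5), (1, 4), (4, 1), (5, 0)])
        assert classify_symmetry(st) == "symmetric"

    def test_single_bulge_is_asymmetric_with_bulge(self):
        st = build(5, 10, [(0, 9), (1, 8), (3, 7), (4, 6)])
        assert classify_symmetry(st) == "asymmetric_with_bulge"

    def test_unequal_internal_loop_without_bulge(self):
        # gap of 2 on arm1 and 1 on arm2: internal loop, asymmetric, no bulge
        st = build(7, 6, [(0, 5), (1, 4), (4, 2), (5, 1), (6, 0)])
        assert classify_symmetry(st) == "asymmetric_no_bulge"

    @pytest.mark.parametrize("loop_size", [1, 2, 3, 4])
    def test_mirrored_loops_symmetric_for_any_size(self, loop_size):
        n = 3
        a = n * 2 + loop_size
        pairs = [(k, a - 1 - k) for k in range(n)]
        pairs += [(n + loop_size + k, a - 1 - n - loop_size - k) for k in range(n)]
        st = build(a, a, pairs)
        assert classify_symmetry(st) == "symmetric"


class TestSpanClass:
    @pytest.mark.parametrize(
        "span,expected",
        [(0, "short"), (24, "short"), (25, "medium"), (100, "medium"), (101, "long"), (5000, "long")],
    )
    def test_boundaries(self, span, expected):
        assert span_classify(span) == expected

    def test_partition_property(self, rng):
        for span in rng.integers(0, 3000, size=200):
            assert span_classify(int(span)) in {"short", "medium", "long"}

    def test_derived_tag_passes_through(self):
        assert span_classify(500, derived=True) == "derived"

    def test_inter_transcript_errors(self):
        with pytest.raises(ValueError):
            span_classify(None)


class TestComposition:
    def test_all_gc_perfect_helix(self):
        assert composition(helix(4)) == (0.0, 100.0, 100.0, 4, 4)

    def test_mixed_au_content(self):
        st = DuplexStructure(
            "GGAA", "TTCC", pairing=[(0, 3), (1, 2), (2, 1), (3, 0)], energy=-1.0
        )
        au, gc, pp, n, longest = composition(st)
        assert au == 50.0 and gc == 50.0 and n == 4

    def test_longest_stem_segment_across_bulge(self):
        # 3 pairs, bulge, then 5 pairs
        pairs = [(k, 12 - k) for k in range(3)] + [(4 + k, 9 - k) for k in range(5)]
        st = build(9, 13, pairs)
        assert composition(st)[4] == 5

    def test_empty_structure_zeroes(self):
        assert composition(build(4, 4, [])) == (0.0, 0.0, 0.0, 0, 0)

    def test_percent_paired_counts_both_arms(self):
        st = helix(4, arm1_len=8, arm2_len=8, offset1=2, offset2=2)
        assert composition(st)[2] == pytest.approx(100 * 8 / 16)


class TestSpanMixture:
    def test_recovers_planted_two_component_mixture(self):
        rng = np.random.default_rng(42)
        spans = np.concatenate(
            [rng.normal(250, 50, size=1000), rng.normal(20, 8, size=1000)]
        )
        fit = fit_span_mixture(spans, k=2, rng=np.random.default_rng(0))
        (w1, m1, s1), (w2, m2, s2) = fit.components
        assert m1 == pytest.approx(250, abs=3 * 50 / np.sqrt(1000))
        assert m2 == pytest.approx(20, abs=3 * 8 / np.sqrt(1000))
        assert w1 == pytest.approx(0.5, abs=0.05)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(3)
        spans = np.concatenate([rng.normal(100, 10, 300), rng.normal(10, 2, 300)])
        fit = fit_span_mixture(spans, k=2, rng=np.random.default_rng(1))
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-8)

    def test_k1_is_sample_moments(self):
        rng = np.random.default_rng(5)
        x = rng.normal(50, 5, size=500)
        fit = fit_span_mixture(x, k=1, rng=np.random.default_rng(0))
        (w, mu, sd) = fit.components[0]
        assert w == pytest.approx(1.0)
        assert mu == pytest.approx(x.mean(), abs=1e-6)
        assert sd == pytest.approx(x.std(), rel=1e-3)

    def test_degenerate_all_equal(self):
        fit = fit_span_mixture([7.0] * 20, k=2, rng=np.random.default_rng(0))
        assert fit.components == [(1.0, 7.0, pytest.approx(1e-3))]

    def test_components_sorted_by_mean_descending(self):
        rng = np.random.default_rng(8)
        spans = np.concatenate([rng.normal(30, 3, 200), rng.normal(300, 30, 200)])
        fit = fit_span_mixture(spans, k=2, rng=np.random.default_rng(2))
        assert fit.means[0] > fit.means[1]


def test_duplex_features_record():
    st = build(5, 10, [(0, 9), (1, 8), (3, 7), (4, 6)])
    f = duplex_features(st, span=150)
    assert f.n_bulges == 1 and f.n_internal_loops == 0
    assert f.symmetry_class == "asymmetric_with_bulge"
    assert f.span_class == "long"
    assert f.longest_stem_segment == 2


from hypothesis import given, settings, strategies as st


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.integers(min_value=0, max_value=100000))
def test_span_classes_partition_all_finite_spans(span):
    cls = span_classify(span)
    assert cls in {"short", "medium", "long"}
    assert (cls == "short") == (span < 25)
    assert (cls == "long") == (span > 100)
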