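"""Hybrid solution cascade: filters, selection, multimap resolution, dedup."""

import numpy as np
import pytest

from duplexatlas.align import PartialAlignment, ReferenceIndex, partial_align
from duplexatlas.hybrids import (
    AMBIGUOUS,
    HYBRID,
    NO_SOLUTION,
    NON_HYBRID,
    HybridRead,
    HybridSolution,
    call_hybrid,
    dedup_hybrids,
    detect_hybrids,
    filter_alignments,
    place_linker_hybrid,
    resolve_multimap,
)
from duplexatlas.reference import TranscriptInterval


def aln(q0, q1, tx="TX1", t0=None, t1=None, e=1e-6, read="r"):
    if t0 is None:
        t0 = q0 + 100
    if t1 is None:
        t1 = t0 + (q1 - q0)
    return PartialAlignment(read, q0, q1, tx, t0, t1, matches=q1 - q0, e_value=e)


def sol(pq, pref, dq, dref):
    return HybridSolution(
        prox_q=pq,
        prox_ref=TranscriptInterval(*pref),
        dist_q=dq,
        dist_ref=TranscriptInterval(*dref),
    )


class TestFilterAlignments:
    def test_evalue_boundary(self):
        keep = aln(0, 20, e=0.001)
        drop = aln(0, 20, e=0.0011)
        out = filter_alignments([keep, drop])
        assert out == [keep]

    def test_evalue_well_above_threshold_removed(self):
        assert filter_alignments([aln(0, 20, e=0.01)]) == []

    def test_more_than_100_alignments_drops_read(self):
        alns = [aln(0, 20, t0=i * 25) for i in range(101)]
        assert filter_alignments(alns) == []
        assert len(filter_alignments(alns[:100])) == 100

    def test_best_per_qspan_kept_with_ties(self):
        a = PartialAlignment("r", 0, 20, "TX1", 100, 120, matches=20, e_value=1e-9)
        b = PartialAlignment("r", 0, 20, "TX2", 300, 320, matches=18, e_value=1e-7)
        c = PartialAlignment("r", 0, 20, "TX3", 500, 520, matches=20, e_value=1e-9)
        out = filter_alignments([a, b, c])
        assert set((x.transcript_id) for x in out) == {"TX1", "TX3"}


class TestCallHybrid:
    def test_non_hybrid_when_15_nt_unaligned(self):
        # 60-nt read, one 45-nt alignment: exactly 15 unaligned => non-hybrid
        assert call_hybrid(60, [aln(0, 45)])[0] == NON_HYBRID

    def test_hybrid_when_16_nt_unaligned(self):
        out, s = call_hybrid(60, [aln(0, 44), aln(44, 60, tx="TX2", t0=500)])
        assert out == HYBRID

    def test_non_hybrid_prioritised_over_hybrid_solutions(self):
        # a near-full-length alignment coexists with a valid two-arm pairing
        alns = [aln(0, 50), aln(0, 30, tx="TX2", t0=700), aln(30, 60, tx="TX3", t0=900)]
        assert call_hybrid(60, alns)[0] == NON_HYBRID

    @pytest.mark.parametrize("gap,ok", [(4, True), (5, False)])
    def test_q_gap_boundary(self, gap, ok):
        alns = [aln(0, 28), aln(28 + gap, 60, tx="TX2", t0=500)]
        outcome, _ = call_hybrid(60 + gap, alns)
        assert (outcome == HYBRID) is ok

    @pytest.mark.parametrize("ov,ok", [(4, True), (5, False)])
    def test_q_overlap_boundary(self, ov, ok):
        alns = [aln(0, 30), aln(30 - ov, 60, tx="TX2", t0=500)]
        outcome, _ = call_hybrid(60, alns)
        assert (outcome == HYBRID) is ok

    def test_reference_overlap_same_transcript_removed(self):
        # arms overlap by 1 nt on the reference -> no solution
        alns = [aln(0, 30, t0=100), aln(30, 60, t0=129)]
        assert call_hybrid(60, alns)[0] == NO_SOLUTION
        # adjacent (non-overlapping) arms survive
        alns = [aln(0, 30, t0=100), aln(30, 60, t0=130)]
        assert call_hybrid(60, alns)[0] == HYBRID

    @pytest.mark.parametrize("offset,ok", [(5, True), (6, False)])
    def test_start_offset_boundary(self, offset, ok):
        alns = [aln(offset, 30), aln(30, 60, tx="TX2", t0=500)]
        outcome, _ = call_hybrid(64, alns)
        assert (outcome == HYBRID) is ok

    def test_multiple_solutions_ambiguous(self):
        alns = [
            aln(0, 30, tx="TX1", t0=100),
            aln(30, 60, tx="TX2", t0=500),
            aln(30, 60, tx="TX3", t0=700),
        ]
        outcome, payload = call_hybrid(60, alns)
        assert outcome == AMBIGUOUS and len(payload) == 2

    def test_no_alignments(self):
        assert call_hybrid(60, []) == (NO_SOLUTION, None)


class TestResolveMultimap:
    def test_pool_overlap_selects(self):
        s1 = sol((0, 30), ("TX1", 100, 130), (30, 60), ("TX1", 400, 430))
        s2 = sol((0, 30), ("TX2", 100, 130), (30, 60), ("TX2", 400, 430))
        pool = [sol((0, 28), ("TX1", 95, 123), (28, 58), ("TX1", 395, 425))]
        assert resolve_multimap([s1, s2], pool) == (HYBRID, s1)

    def test_total_aligned_breaks_pool_ties(self):
        s1 = sol((0, 29), ("TX1", 100, 129), (29, 58), ("TX1", 400, 429))
        s2 = sol((0, 26), ("TX1", 100, 126), (26, 52), ("TX1", 400, 426))
        pool = [sol((0, 30), ("TX1", 100, 130), (30, 60), ("TX1", 400, 430))]
        assert resolve_multimap([s2, s1], pool) == (HYBRID, s1)

    def test_equal_total_aligned_is_ambiguous(self):
        s1 = sol((0, 30), ("TX1", 100, 130), (30, 60), ("TX1", 400, 430))
        s2 = sol((0, 30), ("TX1", 102, 132), (30, 60), ("TX1", 402, 432))
        pool = [sol((0, 30), ("TX1", 101, 131), (30, 60), ("TX1", 401, 431))]
        assert resolve_multimap([s1, s2], pool)[0] == AMBIGUOUS

    def test_no_pool_overlap_is_ambiguous(self):
        s1 = sol((0, 30), ("TX1", 100, 130), (30, 60), ("TX1", 400, 430))
        pool = [sol((0, 30), ("TX9", 0, 30), (30, 60), ("TX9", 300, 330))]
        assert resolve_multimap([s1, s1], pool)[0] == AMBIGUOUS


def hyb(read_id, umi, p0=100, d0=400, tx="TX1"):
    return HybridRead(
        read_id=read_id,
        umi=umi,
        solution=sol((0, 30), (tx, p0, p0 + 30), (30, 60), (tx, d0, d0 + 30)),
        source="direct",
    )


class TestDedup:
    def test_identical_hybrids_same_umi_collapse(self):
        assert len(dedup_hybrids([hyb("a", "AAAA"), hyb("b", "AAAA")])) == 1

    def test_directional_merge_hamming1(self):
        hybrids = [hyb(f"a{i}", "AAAA") for i in range(10)] + [hyb("b", "AAAT")]
        assert len(dedup_hybrids(hybrids)) == 1

    def test_balanced_counts_not_merged(self):
        # count(A) < 2*count(B) - 1 on both sides: two separate molecules
        hybrids = [hyb(f"a{i}", "AAAA") for i in range(5)] + [
            hyb(f"b{i}", "AAAT") for i in range(5)
        ]
        assert len(dedup_hybrids(hybrids)) == 2

    def test_different_arm_start_never_merged(self):
        out = dedup_hybrids([hyb("a", "AAAA", d0=400), hyb("b", "AAAA", d0=460)])
        assert len(out) == 2

    def test_missing_umi_errors(self):
        with pytest.raises(ValueError):
            dedup_hybrids([hyb("a", "")])


@pytest.fixture
def linker_refs(rng):
    refs = {
        f"TX{i}": "".join(rng.choice(list("ACGT"), size=900)) for i in range(3)
    }
    return refs, ReferenceIndex(refs)


class TestPlaceLinkerHybrid:
    def test_both_arms_unique(self, linker_refs):
        refs, index = linker_refs
        arms = ((refs["TX0"][100:130], 0), (refs["TX1"][500:530], 49))
        h = place_linker_hybrid("r", "AACGT", arms, index, "linker_full")
        assert h is not None
        assert h.solution.prox_ref == TranscriptInterval("TX0", 100, 130)
        assert h.solution.dist_ref == TranscriptInterval("TX1", 500, 530)
        assert h.solution.prox_q == (0, 30) and h.solution.dist_q == (49, 79)

    def test_multimapping_arm_drops_read(self, rng):
        repeat = "".join(rng.choice(list("ACGT"), size=30))
        filler1 = "".join(rng.choice(list("ACGT"), size=300))
        filler2 = "".join(rng.choice(list("ACGT"), size=300))
        refs = {"TX0": filler1 + repeat + filler2 + repeat}
        index = ReferenceIndex(refs)
        unique = refs["TX0"][50:80]
        assert place_linker_hybrid("r", "AAAAA", ((repeat, 0), (unique, 49)), index, "linker_full") is None

    def test_reference_overlapping_arms_rejected(self, linker_refs):
        refs, index = linker_refs
        arms = ((refs["TX0"][100:130], 0), (refs["TX0"][115:145], 49))
        assert place_linker_hybrid("r", "AAAAA", arms, index, "linker_full") is None


def test_detect_hybrids_end_to_end_counts(rng):
    refs = {f"TX{i}": "".join(rng.choice(list("ACGT"), size=1000)) for i in range(3)}
    index = ReferenceIndex(refs)
    reads = []
    # 10 hybrid reads, 5 contiguous (non-hybrid) reads
    for i in range(10):
        p, d = int(rng.integers(0, 300)), int(rng.integers(500, 900))
        reads.append((f"h{i}", "AAAA", refs["TX0"][p : p + 35] + refs["TX1"][d : d + 40]))
    for i in range(5):
        p = int(rng.integers(0, 800))
        reads.append((f"n{i}", "CCCC", refs["TX2"][p : p + 75]))
    hybrids, counts = detect_hybrids(reads, index)
    assert counts[HYBRID] == 10
    assert counts[NON_HYBRID] == 5
    assert len(hybrids) == 10


def test_short_arms_recover_fewer_reads():
    """Reads with 15-nt arms are recovered less often than reads with
    25-30 nt arms (shorter fragments align ambiguously or fall below the
    significance threshold)."""
    from duplexatlas.simulate import SimulationConfig, simulate_reads, simulate_transcriptome

    fracs = {}
    for lo in (15, 25, 30):
        rng = np.random.default_rng(40)
        cfg = SimulationConfig(
            n_transcripts=15, length_range=(1000, 2000), n_duplexes=100,
            arm_length_range=(lo, lo + 2), pcr_duplication_rate=0.0,
            read_length_range=(60, 100) if lo < 25 else (75, 100),
        )
        rec, truth = simulate_transcriptome(cfg, rng)
        reads = simulate_reads(rec, truth, cfg, rng, n_reads=300, read_types=(0, 1, 0))
        index = ReferenceIndex({t: r.sequence for t, r in rec.items()})
        triples = [(rid, s[: cfg.umi_length], s[cfg.umi_length :]) for rid, s in reads]
        hybrids, _ = detect_hybrids(triples, index)
        fracs[lo] = len(hybrids) / len(reads)
    assert fracs[15] < fracs[25]
    assert fracs[15] < fracs[30]
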