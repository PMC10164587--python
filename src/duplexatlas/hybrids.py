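"""Hybrid read identification: the solution-selection cascade.

A read without a linker may still contain a hybrid formed by direct
proximity ligation.  Identification proceeds read by read:

1. all partial alignments are computed and filtered on significance
   (e-value <= 0.001), multimapping load (reads with > 100 alignments are
   discarded) and per-q-span dominance (only the best-scoring alignment per
   distinct read span is kept, ties retained);
2. if one alignment explains essentially the whole read (<= 15 nt
   unaligned) the read is called non-hybrid — non-hybrid solutions are
   deliberately prioritised over hybrid ones to control false positives;
3. otherwise alignment pairs ordered in the read are cross-joined and
   filtered: arms may overlap or gap by at most 4 nt in the read, arms of an
   intra-transcript pair must not overlap on the reference, and the first
   arm must start within 5 nt of the read 5' end (the crosslink position,
   by the cDNA truncation convention);
4. a single surviving solution is accepted; multiple solutions are retried
   against the pool of unique solutions from the whole run and otherwise
   declared ambiguous.

Accepted hybrids are deduplicated with a directional UMI network keyed on
the transcript and start coordinate of both arms.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .align import PartialAlignment, ReferenceIndex, partial_align
from .reference import TranscriptInterval

log = logging.getLogger(__name__)

MAX_EVALUE = 0.001
MAX_HITS = 100
MAX_UNALIGNED = 15
MAX_GAP = 4
MAX_START_OFFSET = 5

HYBRID_SOURCES = ("linker_full", "linker_trunc", "direct")

# call_hybrid outcome labels
NON_HYBRID = "non_hybrid"
HYBRID = "hybrid"
AMBIGUOUS = "ambiguous"
NO_SOLUTION = "no_solution"


@dataclass(frozen=True)
class HybridSolution:
    """A two-arm resolution of a read; proximal = 5'-most arm in the read."""

    prox_q: tuple[int, int]
    prox_ref: TranscriptInterval
    dist_q: tuple[int, int]
    dist_ref: TranscriptInterval

    def __post_init__(self) -> None:
        if self.prox_q[0] > self.dist_q[0]:
            raise ValueError("proximal q-interval must precede distal")

    @property
    def total_aligned(self) -> int:
        return (self.prox_q[1] - self.prox_q[0]) + (self.dist_q[1] - self.dist_q[0])

    @property
    def inter_transcript(self) -> bool:
        return self.prox_ref.transcript_id != self.dist_ref.transcript_id

    def ref_ordered(self) -> tuple[TranscriptInterval, TranscriptInterval]:
        """Arms in reference orientation: lower-coordinate arm first.

        For intra-transcript solutions the lower-coordinate arm is the
        proximal arm of the duplex regardless of read order; inter-transcript
        solutions keep read order.
        """
        if not self.inter_transcript and self.dist_ref.start < self.prox_ref.start:
            return self.dist_ref, self.prox_ref
        return self.prox_ref, self.dist_ref


@dataclass(frozen=True)
class HybridRead:
    read_id: str
    umi: str
    solution: HybridSolution
    source: str  # linker_full | linker_trunc | direct

    def __post_init__(self) -> None:
        if self.source not in HYBRID_SOURCES:
            raise ValueError(f"unknown hybrid source {self.source!r}")


def filter_alignments(
    alignments: Sequence[PartialAlignment],
    max_evalue: float = MAX_EVALUE,
    max_hits: int = MAX_HITS,
) -> list[PartialAlignment]:
    """Significance + multimapping + per-q-span dominance filter.

    All alignments must belong to one read.  Returns [] (read dropped) when
    more than ``max_hits`` alignments survive the e-value filter.
    """
    kept = [a for a in alignments if a.e_value <= max_evalue]
    if len(kept) > max_hits:
        log.debug("read %s dropped: %d alignments", kept[0].read_id, len(kept))
        return []
    by_span: dict[tuple[int, int], list[PartialAlignment]] = defaultdict(list)
    for a in kept:
        by_span[(a.q_start, a.q_end)].append(a)
    out: list[PartialAlignment] = []
    for span, group in by_span.items():
        best = max(a.matches for a in group)
        out.extend(a for a in group if a.matches == best)
    out.sort(key=lambda a: (a.q_start, a.q_end, a.transcript_id, a.t_start))
    return out


def _candidate_solutions(
    alignments: Sequence[PartialAlignment],
    max_gap: int,
    max_start_offset: int,
) -> list[HybridSolution]:
    """Cross-join ordered alignment pairs and apply the three pair filters."""
    solutions: dict[tuple, HybridSolution] = {}
    for a in alignments:
        if a.q_start > max_start_offset:
            continue  # first arm must start at the crosslink (read 5' end)
        for b in alignments:
            if b is a or b.q_start < a.q_start:
                continue
            if b.q_start == a.q_start and b.q_end <= a.q_end:
                continue
            # read-space geometry: |gap or overlap| <= max_gap
            delta = b.q_start - a.q_end  # >0 gap, <0 overlap
            if delta > max_gap or -delta > max_gap:
                continue
            if (
                a.transcript_id == b.transcript_id
                and min(a.t_end, b.t_end) > max(a.t_start, b.t_start)
            ):
                continue  # intra-transcript arms must not overlap the reference
            sol = HybridSolution(
                prox_q=(a.q_start, a.q_end),
                prox_ref=TranscriptInterval(a.transcript_id, a.t_start, a.t_end),
                dist_q=(b.q_start, b.q_end),
                dist_ref=TranscriptInterval(b.transcript_id, b.t_start, b.t_end),
            )
            key = (sol.prox_q, sol.prox_ref, sol.dist_q, sol.dist_ref)
            solutions[key] = sol
    return list(solutions.values())


def call_hybrid(
    read_length: int,
    alignments: Sequence[PartialAlignment],
    max_gap: int = MAX_GAP,
    max_unaligned: int = MAX_UNALIGNED,
    max_start_offset: int = MAX_START_OFFSET,
) -> tuple[str, HybridSolution | list[HybridSolution] | None]:
    """Classify one read given its filtered alignments.

    Returns ``(outcome, payload)`` with outcome one of non_hybrid / hybrid /
    ambiguous / no_solution.  For ambiguous reads the payload is the list of
    surviving candidate solutions (for later pool-based resolution).
    """
    if not alignments:
        return (NO_SOLUTION, None)
    # non-hybrid takes precedence: one alignment covers all but <= max_unaligned nt
    for a in alignments:
        if read_length - a.length <= max_unaligned:
            return (NON_HYBRID, None)
    candidates = _candidate_solutions(alignments, max_gap, max_start_offset)
    if not candidates:
        return (NO_SOLUTION, None)
    if len(candidates) == 1:
        return (HYBRID, candidates[0])
    return (AMBIGUOUS, candidates)


def _arms_overlap(s1: HybridSolution, s2: HybridSolution) -> bool:
    """Both reference arms overlap by >= 1 nt (in reference orientation)."""
    a1, b1 = s1.ref_ordered()
    a2, b2 = s2.ref_ordered()
    return a1.overlap(a2) > 0 and b1.overlap(b2) > 0


def resolve_multimap(
    read_solutions: Sequence[HybridSolution],
    unique_solutions_pool: Sequence[HybridSolution],
) -> tuple[str, HybridSolution | None]:
    """Resolve a multi-solution read against the run's unique solutions.

    Solutions whose both arms overlap a pooled unique solution are kept; of
    several, the one with the greatest total aligned length wins; remaining
    ties (or no pool overlap) are ambiguous.
    """
    overlapping = [
        s
        for s in read_solutions
        if any(_arms_overlap(s, u) for u in unique_solutions_pool)
    ]
    if not overlapping:
        return (AMBIGUOUS, None)
    if len(overlapping) == 1:
        return (HYBRID, overlapping[0])
    best = max(s.total_aligned for s in overlapping)
    winners = [s for s in overlapping if s.total_aligned == best]
    if len(winners) == 1:
        return (HYBRID, winners[0])
    return (AMBIGUOUS, None)


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    return sum(x != y for x, y in zip(a, b)) == 1


def dedup_hybrids(hybrids: Sequence[HybridRead]) -> list[HybridRead]:
    """Collapse PCR duplicates with a directional UMI network.

    Hybrids are grouped by the transcript and start coordinate of both arms
    (in reference orientation); within a group, UMIs at Hamming distance 1
    are connected when count(A) >= 2*count(B) - 1, and each connected
    network is collapsed to its highest-count UMI, keeping one
    representative hybrid per network.
    """
    groups: dict[tuple, list[HybridRead]] = defaultdict(list)
    for h in hybrids:
        if not h.umi:
            raise ValueError(f"{h.read_id}: missing UMI")
        prox, dist = h.solution.ref_ordered()
        key = (prox.transcript_id, prox.start, dist.transcript_id, dist.start)
        groups[key].append(h)

    out: list[HybridRead] = []
    for key, members in groups.items():
        counts: Counter[str] = Counter(h.umi for h in members)
        umis = sorted(counts, key=lambda u: (-counts[u], u))
        parent: dict[str, str] = {u: u for u in umis}

        def find(u: str) -> str:
            while parent[u] != u:
                parent[u] = parent[parent[u]]
                u = parent[u]
            return u

        for i, a in enumerate(umis):
            for b in umis[i + 1 :]:
                ca, cb = counts[a], counts[b]
                if _hamming1(a, b) and (ca >= 2 * cb - 1 or cb >= 2 * ca - 1):
                    parent[find(b)] = find(a)
        networks: dict[str, list[str]] = defaultdict(list)
        for u in umis:
            networks[find(u)].append(u)
        first_by_umi: dict[str, HybridRead] = {}
        for h in members:
            first_by_umi.setdefault(h.umi, h)
        for root, net in networks.items():
            rep_umi = max(net, key=lambda u: (counts[u], u))
            out.append(first_by_umi[rep_umi])
    out.sort(key=lambda h: h.read_id)
    return out


def place_linker_hybrid(
    read_id: str,
    umi: str,
    arms: tuple[tuple[str, int], tuple[str, int]],
    index: ReferenceIndex,
    source: str,
    max_evalue: float = MAX_EVALUE,
) -> HybridRead | None:
    """Place the two arms of a linker-containing read independently.

    Each arm must have a unique best placement (score ties drop the read)
    and, for intra-transcript placements, the two arms must not overlap the
    reference — the same exclusion applied to direct-ligation solutions.
    """
    placements = []
    for arm_seq, offset in arms:
        alns = [
            a
            for a in partial_align(read_id, arm_seq, index)
            if a.e_value <= max_evalue
        ]
        if not alns:
            return None
        best = max(a.matches for a in alns)
        top = [a for a in alns if a.matches == best]
        if len(top) != 1:
            return None
        placements.append((top[0], offset))
    (pa, po), (da, do) = placements
    if pa.transcript_id == da.transcript_id and min(pa.t_end, da.t_end) > max(
        pa.t_start, da.t_start
    ):
        return None
    solution = HybridSolution(
        prox_q=(po + pa.q_start, po + pa.q_end),
        prox_ref=TranscriptInterval(pa.transcript_id, pa.t_start, pa.t_end),
        dist_q=(do + da.q_start, do + da.q_end),
        dist_ref=TranscriptInterval(da.transcript_id, da.t_start, da.t_end),
    )
    return HybridRead(read_id=read_id, umi=umi, solution=solution, source=source)


def detect_hybrids(
    reads: Iterable[tuple[str, str, str]],
    index: ReferenceIndex,
    max_evalue: float = MAX_EVALUE,
    max_hits: int = MAX_HITS,
    max_gap: int = MAX_GAP,
    max_unaligned: int = MAX_UNALIGNED,
    max_start_offset: int = MAX_START_OFFSET,
    alignments_by_read: Mapping[str, Sequence[PartialAlignment]] | None = None,
) -> tuple[list[HybridRead], Counter]:
    """Full direct-ligation cascade over (read_id, umi, sequence) triples.

    Two passes: unique solutions are collected first, then multi-solution
    reads are resolved against that pool.  Pre-computed alignments (e.g.
    from PSL import) may be supplied via ``alignments_by_read``.  Returns
    deduplicated hybrids and per-class counts.
    """
    counts: Counter[str] = Counter()
    unique: list[tuple[str, str, HybridSolution]] = []
    pending: list[tuple[str, str, list[HybridSolution]]] = []
    for read_id, umi, seq in reads:
        if alignments_by_read is not None:
            alns = list(alignments_by_read.get(read_id, []))
        else:
            alns = partial_align(read_id, seq, index)
        filtered = filter_alignments(alns, max_evalue=max_evalue, max_hits=max_hits)
        outcome, payload = call_hybrid(
            len(seq),
            filtered,
            max_gap=max_gap,
            max_unaligned=max_unaligned,
            max_start_offset=max_start_offset,
        )
        if outcome == HYBRID:
            unique.append((read_id, umi, payload))
        elif outcome == AMBIGUOUS:
            pending.append((read_id, umi, payload))
        else:
            counts[outcome] += 1

    pool = [sol for _, _, sol in unique]
    hybrids = [
        HybridRead(read_id=rid, umi=umi, solution=sol, source="direct")
        for rid, umi, sol in unique
    ]
    counts[HYBRID] += len(unique)
    for read_id, umi, candidates in pending:
        outcome, sol = resolve_multimap(candidates, pool)
        if outcome == HYBRID:
            hybrids.append(
                HybridRead(read_id=read_id, umi=umi, solution=sol, source="direct")
            )
            counts[HYBRID] += 1
        else:
            counts[AMBIGUOUS] += 1
    deduped = dedup_hybrids(hybrids)
    counts["unique_after_dedup"] = len(deduped)
    log.info("hybrid detection: %s", dict(counts))
    return deduped, counts
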