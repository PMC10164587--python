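"""Graph-based clustering of hybrids into duplexes.

Several hybrid reads may report the same underlying duplex.  Hybrids whose
two arms each overlap reciprocally by at least half of the combined arm
span are joined by an edge; connected components of the resulting graph
are duplexes.  Duplex arm ends are the per-arm medians of the member
coordinates (lower middle value for even counts, keeping integer
coordinates), and support is the component size.  The same clustering is
reused to merge atlases from different evidence sources (linker hybrids,
direct-ligation hybrids, derived stem-loops).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .hybrids import HybridRead
from .reference import TranscriptInterval

log = logging.getLogger(__name__)

MIN_OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class ArmPair:
    """A pair of reference arm intervals with an evidence source tag.

    The unit of clustering: every hybrid read and every already-built duplex
    reduces to one of these.  ``proximal`` is the lower-coordinate arm for
    intra-transcript pairs.
    """

    proximal: TranscriptInterval
    distal: TranscriptInterval
    source: str = "direct"  # linker | direct | derived

    @property
    def transcript_pair(self) -> tuple[str, str]:
        return (self.proximal.transcript_id, self.distal.transcript_id)

    @property
    def intra(self) -> bool:
        return self.proximal.transcript_id == self.distal.transcript_id


@dataclass
class Duplex:
    duplex_id: str
    proximal: TranscriptInterval
    distal: TranscriptInterval
    support: int
    sources: frozenset[str] = field(default_factory=frozenset)

    @property
    def span(self) -> int | None:
        """Reference distance between the arms; None for inter-transcript."""
        if self.proximal.transcript_id != self.distal.transcript_id:
            return None
        return self.distal.start - self.proximal.end

    def as_arm_pair(self, source: str | None = None) -> ArmPair:
        src = source if source is not None else (sorted(self.sources)[0] if self.sources else "direct")
        return ArmPair(self.proximal, self.distal, src)


def hybrid_to_arm_pair(h: HybridRead) -> ArmPair:
    prox, dist = h.solution.ref_ordered()
    source = "linker" if h.source.startswith("linker") else "direct"
    return ArmPair(prox, dist, source)


def hybrid_overlap_fraction(p1: ArmPair, p2: ArmPair) -> tuple[float, float] | None:
    """Per-arm overlap fraction, or None unless both arms overlap >= 1 nt.

    The fraction for an arm is the overlap length divided by the union span
    of the two overlapping arms.  Pairs on different transcript pairings
    never overlap.
    """
    if p1.transcript_pair != p2.transcript_pair:
        return None
    fracs = []
    for a, b in ((p1.proximal, p2.proximal), (p1.distal, p2.distal)):
        ov = min(a.end, b.end) - max(a.start, b.start)
        if ov <= 0:
            return None
        union = max(a.end, b.end) - min(a.start, b.start)
        fracs.append(ov / union)
    return (fracs[0], fracs[1])


def _median_low(values: Sequence[int]) -> int:
    """Median keeping integer coordinates: lower middle value for even n."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def cluster_arm_pairs(
    pairs: Sequence[ArmPair],
    min_fraction: float = MIN_OVERLAP_FRACTION,
    id_prefix: str = "DX",
) -> list[Duplex]:
    """Connected-component clustering of arm pairs into duplexes.

    Output is deterministic and invariant to input order: duplexes are
    sorted by coordinates and numbered in that order.
    """
    graph = nx.Graph()
    graph.add_nodes_from(range(len(pairs)))
    by_tx: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, p in enumerate(pairs):
        by_tx[p.transcript_pair].append(i)
    for group in by_tx.values():
        for ai in range(len(group)):
            for bi in range(ai + 1, len(group)):
                i, j = group[ai], group[bi]
                fr = hybrid_overlap_fraction(pairs[i], pairs[j])
                if fr is not None and fr[0] >= min_fraction and fr[1] >= min_fraction:
                    graph.add_edge(i, j, weight=min(fr))

    duplexes: list[Duplex] = []
    for comp in nx.connected_components(graph):
        members = [pairs[i] for i in comp]
        prox = TranscriptInterval(
            members[0].proximal.transcript_id,
            _median_low([m.proximal.start for m in members]),
            _median_low([m.proximal.end for m in members]),
        )
        dist = TranscriptInterval(
            members[0].distal.transcript_id,
            _median_low([m.distal.start for m in members]),
            _median_low([m.distal.end for m in members]),
        )
        duplexes.append(
            Duplex(
                duplex_id="",
                proximal=prox,
                distal=dist,
                support=len(members),
                sources=frozenset(m.source for m in members),
            )
        )
    duplexes.sort(
        key=lambda d: (
            d.proximal.transcript_id,
            d.distal.transcript_id,
            d.proximal.start,
            d.distal.start,
            d.proximal.end,
            d.distal.end,
            d.support,
        )
    )
    for i, d in enumerate(duplexes, 1):
        d.duplex_id = f"{id_prefix}{i:06d}"
    return duplexes


def cluster_hybrids(
    hybrids: Sequence[HybridRead], min_fraction: float = MIN_OVERLAP_FRACTION
) -> list[Duplex]:
    """Cluster deduplicated hybrid reads into duplexes."""
    return cluster_arm_pairs([hybrid_to_arm_pair(h) for h in hybrids], min_fraction)


def merge_atlases(
    duplex_sets: Iterable[Sequence[ArmPair | Duplex]],
    min_fraction: float = MIN_OVERLAP_FRACTION,
) -> list[Duplex]:
    """Re-cluster the union of several evidence sets into one atlas.

    Inputs may be arm pairs or duplexes (each contributing one node tagged
    with its source); support counts nodes, and sources are unioned over
    the members of each merged duplex.
    """
    pool: list[ArmPair] = []
    for dset in duplex_sets:
        for item in dset:
            pool.append(item.as_arm_pair() if isinstance(item, Duplex) else item)
    return cluster_arm_pairs(pool, min_fraction, id_prefix="AT")


def duplexes_to_frame(duplexes: Sequence[Duplex]) -> pd.DataFrame:
    """BEDPE-like table of a duplex atlas."""
    rows = []
    for d in duplexes:
        rows.append(
            {
                "duplex_id": d.duplex_id,
                "prox_tx": d.proximal.transcript_id,
                "prox_start": d.proximal.start,
                "prox_end": d.proximal.end,
                "dist_tx": d.distal.transcript_id,
                "dist_start": d.distal.start,
                "dist_end": d.distal.end,
                "support": d.support,
                "sources": ",".join(sorted(d.sources)),
                "span": d.span if d.span is not None else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "duplex_id", "prox_tx", "prox_start", "prox_end",
            "dist_tx", "dist_start", "dist_end", "support", "sources", "span",
        ],
    )


def write_duplex_bed(duplexes: Sequence[Duplex], path: str) -> None:
    """Two-block BED12-style export of intra-transcript duplexes."""
    with open(path, "w") as fh:
        for d in duplexes:
            if d.proximal.transcript_id != d.distal.transcript_id:
                continue
            chrom = d.proximal.transcript_id
            start, end = d.proximal.start, d.distal.end
            sizes = f"{len(d.proximal)},{len(d.distal)}"
            starts = f"0,{d.distal.start - start}"
            fh.write(
                f"{chrom}\t{start}\t{end}\t{d.duplex_id}\t{d.support}\t+"
                f"\t{start}\t{end}\t0,0,0\t2\t{sizes}\t{starts}\n"
            )


def contact_matrix(
    duplexes: Sequence[Duplex], transcript_id: str, length: int, bin_size: int = 1
) -> np.ndarray:
    """Support-weighted arm-vs-arm contact matrix for one transcript."""
    n = (length + bin_size - 1) // bin_size
    mat = np.zeros((n, n), dtype=float)
    for d in duplexes:
        if (
            d.proximal.transcript_id != transcript_id
            or d.distal.transcript_id != transcript_id
        ):
            continue
        p0, p1 = d.proximal.start // bin_size, (d.proximal.end - 1) // bin_size + 1
        d0, d1 = d.distal.start // bin_size, (d.distal.end - 1) // bin_size + 1
        mat[p0:p1, d0:d1] += d.support
    return mat


def arc_table(duplexes: Sequence[Duplex], transcript_id: str) -> pd.DataFrame:
    """(start, end, count) arcs joining arm midpoints on one transcript."""
    rows = []
    for d in duplexes:
        if (
            d.proximal.transcript_id != transcript_id
            or d.distal.transcript_id != transcript_id
        ):
            continue
        rows.append(
            {
                "start": (d.proximal.start + d.proximal.end) // 2,
                "end": (d.distal.start + d.distal.end) // 2,
                "count": d.support,
            }
        )
    return pd.DataFrame(rows, columns=["start", "end", "count"])
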