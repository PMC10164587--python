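"""Partial (local) alignment of reads to a transcriptome reference.

Hybrid reads map non-contiguously: each arm aligns to a different part of
the reference.  The first step of hybrid identification is therefore to
enumerate *all* partial alignments of a read.  The built-in aligner is an
ungapped seed-and-extend search: exact k-mer seeds (tile size 11) against a
reference index sampled every 5 positions, extended to maximal exact-match
segments, reporting segments with at least ``min_score`` (default 15)
matching nucleotides.  Because any exact segment of length >= tile + step - 1
= 15 must contain a sampled reference k-mer at a matching offset, the search
is exhaustive for reported segments — a property the test suite verifies
against a full diagonal scan.

Gapped arms can be supplied instead from an external aligner via PSL or
BLAST-8 tabular import; coordinates are normalised to 0-based half-open.

Significance is a Karlin–Altschul e-value, e = K * m * n * exp(-lambda * S),
with the ungapped nucleotide scoring +1/-2 (lambda = 1.3327, K = 0.621) and
S the segment score; for exact segments S equals the segment length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

TILE_SIZE = 11
STEP_SIZE = 5
MIN_SCORE = 15

# Karlin-Altschul parameters for ungapped +1/-2 scoring, uniform composition
KA_LAMBDA = 1.3327
KA_K = 0.621


@dataclass(frozen=True)
class PartialAlignment:
    """One ungapped local alignment of a read segment to a transcript."""

    read_id: str
    q_start: int
    q_end: int
    transcript_id: str
    t_start: int
    t_end: int
    matches: int
    e_value: float

    def __post_init__(self) -> None:
        if self.q_end - self.q_start != self.t_end - self.t_start:
            raise ValueError("ungapped alignment must have equal q and t spans")
        if self.e_value < 0:
            raise ValueError("negative e-value")

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


def karlin_altschul_evalue(score: float, query_len: int, db_len: int) -> float:
    return KA_K * query_len * db_len * math.exp(-KA_LAMBDA * score)


class ReferenceIndex:
    """k-mer index over a set of transcript sequences.

    Reference k-mers are sampled every ``step`` positions (plus the final
    window so transcript tails are not lost); query k-mers are probed at
    every position.
    """

    def __init__(
        self,
        sequences: Mapping[str, str],
        tile: int = TILE_SIZE,
        step: int = STEP_SIZE,
    ):
        if not sequences:
            raise ValueError("empty reference index")
        self.tile = tile
        self.step = step
        self.names: list[str] = list(sequences)
        self.seqs: list[str] = [sequences[n] for n in self.names]
        self.total_len = sum(len(s) for s in self.seqs)
        index: dict[str, list[tuple[int, int]]] = {}
        for ti, seq in enumerate(self.seqs):
            last = len(seq) - tile
            pos = 0
            while pos <= last:
                kmer = seq[pos : pos + tile]
                if "N" not in kmer:
                    index.setdefault(kmer, []).append((ti, pos))
                pos += step
            # cover the tail window
            if last > 0 and last % step != 0:
                kmer = seq[last:]
                if "N" not in kmer:
                    index.setdefault(kmer, []).append((ti, last))
        self._index = index


def partial_align(
    read_id: str,
    read_sequence: str,
    index: ReferenceIndex,
    min_score: int = MIN_SCORE,
) -> list[PartialAlignment]:
    """All maximal exact-match segments of the read vs the reference.

    Returns segments with at least ``min_score`` matches, each with a
    Karlin-Altschul e-value.  Reads shorter than the tile size yield no
    alignments.
    """
    tile = index.tile
    L = len(read_sequence)
    if L < tile:
        return []
    seen: set[tuple[int, int, int]] = set()  # (transcript_idx, q_start, t_start) maximal
    out: list[PartialAlignment] = []
    lookup = index._index.get
    for qpos in range(L - tile + 1):
        hits = lookup(read_sequence[qpos : qpos + tile])
        if not hits:
            continue
        for ti, tpos in hits:
            seq = index.seqs[ti]
            # extend left
            q0, t0 = qpos, tpos
            while q0 > 0 and t0 > 0 and read_sequence[q0 - 1] == seq[t0 - 1]:
                q0 -= 1
                t0 -= 1
            key = (ti, q0, t0)
            if key in seen:
                continue
            seen.add(key)
            # extend right
            q1, t1 = qpos + tile, tpos + tile
            n = len(seq)
            while q1 < L and t1 < n and read_sequence[q1] == seq[t1]:
                q1 += 1
                t1 += 1
            length = q1 - q0
            if length < min_score:
                continue
            out.append(
                PartialAlignment(
                    read_id=read_id,
                    q_start=q0,
                    q_end=q1,
                    transcript_id=index.names[ti],
                    t_start=t0,
                    t_end=t1,
                    matches=length,
                    e_value=karlin_altschul_evalue(length, L, index.total_len),
                )
            )
    out.sort(key=lambda a: (a.q_start, a.q_end, a.transcript_id, a.t_start))
    return out


def read_psl(path: str | Path) -> list[PartialAlignment]:
    """Import partial alignments from a PSL file (headerless or with header).

    Only single-block, ungapped records are usable under the ungapped
    contract; gapped records are skipped with a logged count.  PSL
    coordinates are already 0-based half-open.  Scores use matches minus
    twice the mismatches; the database size is taken from tSize.
    """
    out: list[PartialAlignment] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 21 or not parts[0].isdigit():
                continue  # header / psLayout banner
            matches, mismatches = int(parts[0]), int(parts[1])
            q_gaps, t_gaps = int(parts[5]), int(parts[7])
            if q_gaps or t_gaps:
                skipped += 1
                continue
            q_name, q_size = parts[9], int(parts[10])
            q_start, q_end = int(parts[11]), int(parts[12])
            t_name, t_size = parts[13], int(parts[14])
            t_start, t_end = int(parts[15]), int(parts[16])
            score = matches - 2 * mismatches
            out.append(
                PartialAlignment(
                    read_id=q_name,
                    q_start=q_start,
                    q_end=q_end,
                    transcript_id=t_name,
                    t_start=t_start,
                    t_end=t_end,
                    matches=matches,
                    e_value=karlin_altschul_evalue(score, q_size, t_size),
                )
            )
    if skipped:
        log.info("read_psl: skipped %d gapped records", skipped)
    return out


def read_blast8(path: str | Path) -> list[PartialAlignment]:
    """Import from BLAST-8 / outfmt-6 tabular (1-based inclusive coords).

    The file's own e-value column is kept.  Records with gaps or on the
    minus strand (sstart > send) are skipped: the reference is a plus-strand
    transcriptome.
    """
    out: list[PartialAlignment] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            qseqid, sseqid = f[0], f[1]
            length, mismatch, gapopen = int(f[3]), int(f[4]), int(f[5])
            qstart, qend, sstart, send = int(f[6]), int(f[7]), int(f[8]), int(f[9])
            evalue = float(f[10])
            if gapopen or sstart > send:
                skipped += 1
                continue
            out.append(
                PartialAlignment(
                    read_id=qseqid,
                    q_start=qstart - 1,
                    q_end=qend,
                    transcript_id=sseqid,
                    t_start=sstart - 1,
                    t_end=send,
                    matches=length - mismatch,
                    e_value=evalue,
                )
            )
    if skipped:
        log.info("read_blast8: skipped %d gapped/minus-strand records", skipped)
    return out
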