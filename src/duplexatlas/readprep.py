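"""Linker detection, arm splitting, in-silico stitching and UMI handling.

Reads from a duplex-ligation library fall into three classes: reads carrying
the bridging linker adapter (full-length, or with one or two nucleotides
degraded from its 3' end), reads formed by direct proximity ligation of the
two duplex arms, and contiguous reads spanning a short stem-loop.  This
module handles the linker class: it locates the (possibly truncated) linker,
splits the flanking arms, and can stitch the arms back together to emulate a
direct-ligation read.

The linker nucleotide sequence is experiment-specific and must be supplied
by the caller; there is no default.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

log = logging.getLogger(__name__)

LINKER_STATUSES = ("none", "full", "trunc1", "trunc2")

DEFAULT_MIN_FLANK = 12


@dataclass
class PreparedRead:
    """A read after UMI extraction and linker search.

    ``arms`` is ``((prox_seq, prox_offset), (dist_seq, dist_offset))`` with
    offsets into the UMI-trimmed sequence; present only when a linker was
    found and both flanks pass the minimum-length filter.  ``rejected`` marks
    linker-containing reads with a too-short flank.
    """

    read_id: str
    umi: str
    sequence: str
    linker_status: str = "none"
    linker_pos: int = -1
    linker_len: int = 0
    arms: tuple[tuple[str, int], tuple[str, int]] | None = None
    rejected: bool = False


def find_linker(sequence: str, linker_seq: str, max_trunc: int = 2) -> tuple[str, int]:
    """Locate the linker adapter, allowing up to ``max_trunc`` nt lost 3'.

    The full linker is searched first, then progressively 3'-truncated
    variants; the longest matching variant wins and the leftmost occurrence
    is reported.  Returns ``(status, position)`` or ``("none", -1)``.
    """
    if len(linker_seq) <= max_trunc:
        raise ValueError("linker must be longer than max_trunc")
    if not sequence:
        return ("none", -1)
    for trunc in range(0, max_trunc + 1):
        variant = linker_seq[: len(linker_seq) - trunc] if trunc else linker_seq
        pos = sequence.find(variant)
        if pos != -1:
            status = "full" if trunc == 0 else f"trunc{trunc}"
            return (status, pos)
    return ("none", -1)


def split_arms(
    read: PreparedRead, linker_seq: str, min_flank: int = DEFAULT_MIN_FLANK
) -> PreparedRead:
    """Split the sequences flanking the matched linker into the two arms.

    Reads where either flank is shorter than ``min_flank`` are flagged
    ``rejected`` (status retained, arms absent) rather than erroring.
    """
    if read.linker_status == "none":
        raise ValueError("split_arms requires a linker match")
    trunc = {"full": 0, "trunc1": 1, "trunc2": 2}[read.linker_status]
    linker_len = len(linker_seq) - trunc
    pos = read.linker_pos
    prox = read.sequence[:pos]
    dist = read.sequence[pos + linker_len :]
    read.linker_len = linker_len
    if len(prox) < min_flank or len(dist) < min_flank:
        read.rejected = True
        read.arms = None
    else:
        read.arms = ((prox, 0), (dist, pos + linker_len))
    return read


def stitch_arms(read: PreparedRead) -> str:
    """Concatenate proximal + distal arm, removing the intervening linker."""
    if read.arms is None:
        raise ValueError(f"{read.read_id}: no arms to stitch")
    (prox, _), (dist, _) = read.arms
    return prox + dist


def stitch_junction(read: PreparedRead) -> int:
    """Read offset of the stitched junction (length of the proximal arm)."""
    if read.arms is None:
        raise ValueError(f"{read.read_id}: no arms")
    return len(read.arms[0][0])


@dataclass(frozen=True)
class UmiScheme:
    """Where the UMI lives: a 5' prefix of the read, or a header tag."""

    length: int = 5
    source: str = "sequence"  # "sequence" or "header"
    header_tag: str = "rbc:"


def extract_umi(read_id: str, sequence: str, scheme: UmiScheme) -> tuple[str, str, str] | None:
    """Return ``(umi, read_id, remaining_sequence)`` or None if undecodable.

    With a sequence scheme the UMI is the 5' prefix; reads shorter than the
    UMI are dropped (None).  With a header scheme the UMI follows
    ``scheme.header_tag`` in the read id and the sequence is unchanged.
    """
    if scheme.source == "header":
        for token in read_id.replace("_", " ").split():
            if token.startswith(scheme.header_tag):
                return token[len(scheme.header_tag) :], read_id, sequence
        return None
    if len(sequence) < scheme.length:
        return None
    return sequence[: scheme.length], read_id, sequence[scheme.length :]


def prepare_reads(
    reads: Iterable[tuple[str, str]],
    linker_seq: str | None,
    umi_scheme: UmiScheme | None = None,
    min_flank: int = DEFAULT_MIN_FLANK,
    max_trunc: int = 2,
) -> Iterator[PreparedRead]:
    """Run UMI extraction + linker search/splitting over (id, seq) pairs.

    With ``linker_seq`` None, reads pass through with status "none" (pure
    direct-ligation processing).  Per-status counts are logged.
    """
    umi_scheme = umi_scheme or UmiScheme()
    counts: Counter[str] = Counter()
    for read_id, seq in reads:
        parsed = extract_umi(read_id, seq, umi_scheme)
        if parsed is None:
            counts["umi_dropped"] += 1
            continue
        umi, read_id, seq = parsed
        prepared = PreparedRead(read_id=read_id, umi=umi, sequence=seq)
        if linker_seq:
            status, pos = find_linker(seq, linker_seq, max_trunc=max_trunc)
            prepared.linker_status = status
            prepared.linker_pos = pos
            if status != "none":
                prepared = split_arms(prepared, linker_seq, min_flank=min_flank)
        key = prepared.linker_status + ("_rejected" if prepared.rejected else "")
        counts[key] += 1
        yield prepared
    log.info("read preparation counts: %s", dict(counts))
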