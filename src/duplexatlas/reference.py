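"""Reference transcriptome loading and region annotation.

Transcripts are plus-strand transcriptome sequences with optional region
annotation (5' UTR, CDS, 3' UTR).  All coordinates are 0-based half-open;
GTF input (1-based inclusive) is converted on read.  Interval annotation
uses a fixed region ranking that prefers the 3' UTR over the CDS, matching
the strong 3' UTR binding preference of double-stranded RNA binding
proteins such as Staufen1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

log = logging.getLogger(__name__)

REGION_KINDS = ("UTR5", "CDS", "UTR3", "noncoding")

#: tie-break rank when an interval overlaps several regions equally;
#: higher wins.  The 3' UTR outranks the CDS.
REGION_RANK = {"UTR3": 3, "CDS": 2, "UTR5": 1, "noncoding": 0}

_ALPHABET = set("ACGTUN")


def normalise_sequence(seq: str) -> str:
    """Uppercase and store on the DNA alphabet (U -> T); reject junk."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class TranscriptInterval:
    """A half-open interval on a transcript."""

    transcript_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.transcript_id}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "TranscriptInterval") -> int:
        if self.transcript_id != other.transcript_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TranscriptRecord:
    """A reference sequence with named regions.

    ``regions`` is a sorted list of ``(kind, start, end)`` tuples with
    non-overlapping half-open intervals contained in the sequence.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    regions: list[tuple[str, int, int]] = field(default_factory=list)
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        self.sequence = normalise_sequence(self.sequence)
        if len(self.sequence) < 1:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        if not self.regions:
            self.regions = [("noncoding", 0, len(self.sequence))]
        self.regions = sorted(self.regions, key=lambda r: (r[1], r[2]))
        prev_end = 0
        for kind, start, end in self.regions:
            if kind not in REGION_KINDS:
                raise ValueError(f"{self.transcript_id}: unknown region kind {kind!r}")
            if start < 0 or end > len(self.sequence) or start >= end:
                raise ValueError(
                    f"{self.transcript_id}: region {kind} [{start}, {end}) outside "
                    f"sequence bounds [0, {len(self.sequence)})"
                )
            if start < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping regions")
            prev_end = end

    def __len__(self) -> int:
        return len(self.sequence)

    def region_interval(self, kind: str) -> TranscriptInterval | None:
        """First region of ``kind``, as an interval, or None."""
        for k, s, e in self.regions:
            if k == kind:
                return TranscriptInterval(self.transcript_id, s, e)
        return None


def _parse_region_tsv(path: Path) -> dict[str, list[tuple[str, int, int]]]:
    """4-column TSV: transcript_id, region_kind, start, end (0-based half-open)."""
    out: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "transcript_id":  # optional header
                continue
            tx, kind, start, end = parts[0], parts[1], int(parts[2]), int(parts[3])
            out.setdefault(tx, []).append((kind, start, end))
    return out


_GTF_FEATURE_MAP = {
    "five_prime_utr": "UTR5",
    "UTR5": "UTR5",
    "CDS": "CDS",
    "three_prime_utr": "UTR3",
    "UTR3": "UTR3",
}


def _parse_gtf(path: Path) -> dict[str, list[tuple[str, int, int]]]:
    """Extract per-transcript region annotation from a GTF file.

    Feature coordinates are interpreted in *transcript* space (the reference
    here is a transcriptome, as used for hybrid alignment).  GTF is 1-based
    inclusive and converted to 0-based half-open.  Features of the same kind
    split across lines (e.g. CDS over two exons) are merged when contiguous.
    """
    raw: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            feature = f[2]
            kind = _GTF_FEATURE_MAP.get(feature)
            if kind is None:
                continue
            attrs = f[8]
            tx = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("transcript_id"):
                    tx = chunk.split(" ", 1)[1].strip().strip('"')
                    break
            if tx is None:
                continue
            start, end = int(f[3]) - 1, int(f[4])
            raw.setdefault(tx, []).append((kind, start, end))
    # merge contiguous same-kind pieces
    merged: dict[str, list[tuple[str, int, int]]] = {}
    for tx, regions in raw.items():
        regions.sort(key=lambda r: r[1])
        out: list[tuple[str, int, int]] = []
        for kind, s, e in regions:
            if out and out[-1][0] == kind and out[-1][2] >= s:
                out[-1] = (kind, out[-1][1], max(out[-1][2], e))
            else:
                out.append((kind, s, e))
        merged[tx] = [tuple(r) for r in out]
    return merged


def load_reference(
    fasta_path: str | Path, annotation_path: str | Path | None = None
) -> dict[str, TranscriptRecord]:
    """Load a transcriptome FASTA plus optional region annotation.

    ``annotation_path`` may be a GTF (detected by extension .gtf/.gff) or a
    4-column region TSV.  Transcripts without annotation get a single
    full-length "noncoding" region.  FASTA headers are split on whitespace;
    an optional second token ``gene=<id>`` sets the gene id (defaults to the
    transcript id).
    """
    fasta_path = Path(fasta_path)
    annotation: Mapping[str, list[tuple[str, int, int]]] = {}
    if annotation_path is not None:
        annotation_path = Path(annotation_path)
        if annotation_path.suffix.lower() in {".gtf", ".gff", ".gff3"}:
            annotation = _parse_gtf(annotation_path)
        else:
            annotation = _parse_region_tsv(annotation_path)

    records: dict[str, TranscriptRecord] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        tx = rec.id
        if tx in records:
            raise ValueError(f"duplicate transcript_id in FASTA: {tx}")
        gene = tx
        for token in rec.description.split()[1:]:
            if token.startswith("gene="):
                gene = token[5:]
        regions = annotation.get(tx, [])
        try:
            records[tx] = TranscriptRecord(
                transcript_id=tx, gene_id=gene, sequence=str(rec.seq), regions=list(regions)
            )
        except ValueError as exc:
            raise ValueError(f"transcript {tx}: {exc}") from exc
    log.info("loaded %d transcripts (%d annotated)", len(records), len(annotation))
    return records


def annotate_interval(
    interval: TranscriptInterval, records: Mapping[str, TranscriptRecord]
) -> str:
    """Region kind with the largest overlap; ties resolved UTR3 > CDS > UTR5.

    Any part of the interval not covered by an annotated region counts as
    "noncoding" coverage.
    """
    rec = records.get(interval.transcript_id)
    if rec is None:
        raise KeyError(f"unknown transcript: {interval.transcript_id}")
    cover: dict[str, int] = {}
    covered = 0
    for kind, s, e in rec.regions:
        ov = max(0, min(interval.end, e) - max(interval.start, s))
        if ov:
            cover[kind] = cover.get(kind, 0) + ov
            covered += ov
    uncovered = len(interval) - covered
    if uncovered:
        cover["noncoding"] = cover.get("noncoding", 0) + uncovered
    return max(cover, key=lambda k: (cover[k], REGION_RANK[k]))


def write_reference(
    records: Iterable[TranscriptRecord],
    fasta_path: str | Path,
    region_tsv_path: str | Path | None = None,
) -> None:
    """Write records back to FASTA (+ region TSV); inverse of load_reference."""
    records = list(records)
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.transcript_id} gene={rec.gene_id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    if region_tsv_path is not None:
        with open(region_tsv_path, "w") as fh:
            fh.write("transcript_id\tregion_kind\tstart\tend\n")
            for rec in records:
                for kind, s, e in rec.regions:
                    fh.write(f"{rec.transcript_id}\t{kind}\t{s}\t{e}\n")
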