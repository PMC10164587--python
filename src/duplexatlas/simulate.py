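"""Synthetic ground-truth data for end-to-end testing.

Generates a small transcriptome with planted complementary duplexes and
emits the three read types a duplex-ligation library produces: reads with
a (possibly 3'-truncated) linker adapter between the arms, reads from
direct proximity ligation of the arms, and contiguous reads spanning a
short-loop stem-loop.  Planted duplexes record their exact arm
coordinates so recovery can be scored; reads carry UMIs and optional PCR
duplicates with occasional single-base UMI errors.

Default parameters reflect the regime the method is designed for: reads
of 75-100 nt with hybrid arms of at least 25 nt (the documented working
range for reliable hybrid reconstruction), a bimodal duplex-span
distribution with long-range (mean 252 nt) and short-range (mean 18 nt)
components, and stem-loops with stems of 8-15 bp and loops of 4-10 nt.
Sequences are rejection-sampled against 13-mer reuse to keep the
transcriptome non-repetitive, so arm placements are unique by design.
Reads are error-free; linker detection and alignment scoring operate on
exact matches, so sequencing-error modelling is orthogonal to what these
fixtures test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .metabolism import MetabolismRecord
from .reference import TranscriptInterval, TranscriptRecord

#: arbitrary documented 19-nt linker used by the generator (the adapter in
#: any real library is experiment-specific and must be configured)
DEFAULT_LINKER = "CTGTAGGCACCATCAATAC"

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


@dataclass(frozen=True)
class SimulationConfig:
    n_transcripts: int = 50
    length_range: tuple[int, int] = (1000, 3000)
    gc_fraction: float = 0.5
    n_duplexes: int = 500
    n_hairpins: int = 50
    #: bimodal span mixture: (weight, mean, sd) per component
    span_mixture: tuple[tuple[float, float, float], ...] = (
        (0.53, 252.0, 80.0),
        (0.47, 18.0, 6.0),
    )
    min_span: int = 12
    inter_fraction: float = 0.1
    arm_length_range: tuple[int, int] = (25, 35)
    hairpin_stem_range: tuple[int, int] = (8, 15)
    hairpin_loop_range: tuple[int, int] = (4, 10)
    read_length_range: tuple[int, int] = (75, 100)
    linker: str = DEFAULT_LINKER
    #: fractions of linker / direct / stem-loop reads
    read_type_fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    #: probabilities of emitting the linker intact / minus 1 nt / minus 2 nt
    linker_trunc_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)
    umi_length: int = 6
    pcr_duplication_rate: float = 0.2
    umi_error_rate: float = 0.1
    max_stemloop_loop: int = 10
    kmer_uniqueness: int = 13

    def __post_init__(self) -> None:
        if abs(sum(self.read_type_fractions) - 1.0) > 1e-9:
            raise ValueError("read type fractions must sum to 1")
        if self.arm_length_range[0] < 1 or self.length_range[0] < 1:
            raise ValueError("lengths must be positive")


@dataclass(frozen=True)
class PlantedDuplex:
    duplex_id: str
    proximal: TranscriptInterval
    distal: TranscriptInterval
    kind: str  # "ligation" | "hairpin"

    @property
    def intra(self) -> bool:
        return self.proximal.transcript_id == self.distal.transcript_id

    @property
    def span(self) -> int | None:
        if not self.intra:
            return None
        return self.distal.start - self.proximal.end


@dataclass(frozen=True)
class ReadProvenance:
    read_id: str
    duplex_id: str
    read_type: str  # "linker" | "direct" | "stemloop"
    linker_trunc: int
    prox_t_start: int
    dist_t_start: int
    is_duplicate: bool = False


@dataclass
class GroundTruth:
    duplexes: list[PlantedDuplex] = field(default_factory=list)
    reads: dict[str, ReadProvenance] = field(default_factory=dict)

    def duplex(self, duplex_id: str) -> PlantedDuplex:
        return next(d for d in self.duplexes if d.duplex_id == duplex_id)


def _random_sequence(
    length: int, gc: float, rng: np.random.Generator, used_kmers: set[str], k: int
) -> str:
    """Random sequence avoiding k-mer reuse across the transcriptome."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chars: list[str] = []
    for _ in range(length):
        for _attempt in range(6):
            c = str(rng.choice(_BASES, p=p))
            if len(chars) + 1 < k:
                chars.append(c)
                break
            kmer = "".join(chars[-(k - 1) :]) + c
            if kmer not in used_kmers:
                used_kmers.add(kmer)
                chars.append(c)
                break
        else:
            chars.append(c)  # accept a rare repeat rather than loop forever
    return "".join(chars)


def _sample_span(config: SimulationConfig, rng: np.random.Generator) -> int:
    weights = np.array([w for w, _, _ in config.span_mixture])
    idx = rng.choice(len(weights), p=weights / weights.sum())
    _, mu, sd = config.span_mixture[idx]
    return max(config.min_span, int(round(rng.normal(mu, sd))))


def simulate_transcriptome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, TranscriptRecord], GroundTruth]:
    """Build a non-repetitive transcriptome with planted duplexes.

    Planting replaces the distal-arm locus with the reverse complement of
    the proximal arm, so planted arms form perfect antiparallel helices.
    Ligation duplexes draw spans from the bimodal mixture; hairpin
    duplexes use short stems (8-15 bp) and loops (4-10 nt) and feed the
    stem-loop read type.  Arm loci never overlap each other.
    """
    used_kmers: set[str] = set()
    records: dict[str, TranscriptRecord] = {}
    seqs: dict[str, list[str]] = {}
    for i in range(config.n_transcripts):
        tx = f"TX{i + 1:04d}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = _random_sequence(length, config.gc_fraction, rng, used_kmers, config.kmer_uniqueness)
        u5 = max(1, length // 10)
        cds = length // 2
        regions = [("UTR5", 0, u5), ("CDS", u5, u5 + cds), ("UTR3", u5 + cds, length)]
        seqs[tx] = list(seq)
        records[tx] = TranscriptRecord(
            transcript_id=tx, gene_id=f"G{i + 1:04d}", sequence=seq, regions=regions
        )

    truth = GroundTruth()
    if not records:
        return records, truth
    used: dict[str, list[tuple[int, int]]] = {tx: [] for tx in records}

    def reserve(tx: str, start: int, end: int) -> bool:
        for s, e in used[tx]:
            if min(e, end) > max(s, start):
                return False
        used[tx].append((start, end))
        return True

    tx_ids = list(records)

    def plant(did: str, kind: str) -> PlantedDuplex | None:
        for _attempt in range(50):
            if kind == "hairpin":
                arm = int(rng.integers(config.hairpin_stem_range[0], config.hairpin_stem_range[1] + 1))
                span = int(rng.integers(config.hairpin_loop_range[0], config.hairpin_loop_range[1] + 1))
                inter = False
            else:
                arm = int(rng.integers(config.arm_length_range[0], config.arm_length_range[1] + 1))
                span = _sample_span(config, rng)
                inter = rng.random() < config.inter_fraction
            if inter:
                t1, t2 = rng.choice(len(tx_ids), size=2, replace=False)
                tx1, tx2 = tx_ids[t1], tx_ids[t2]
                n1, n2 = len(records[tx1]), len(records[tx2])
                if n1 < arm + 60 or n2 < arm + 60:
                    continue
                p_start = int(rng.integers(0, n1 - arm - 50))
                d_start = int(rng.integers(0, n2 - arm - 50))
                if not reserve(tx1, p_start, p_start + arm):
                    continue
                if not reserve(tx2, d_start, d_start + arm):
                    used[tx1].remove((p_start, p_start + arm))
                    continue
                prox = TranscriptInterval(tx1, p_start, p_start + arm)
                dist = TranscriptInterval(tx2, d_start, d_start + arm)
            else:
                tx1 = tx_ids[int(rng.integers(len(tx_ids)))]
                n1 = len(records[tx1])
                total = arm + span + arm
                if n1 < total + 60:
                    continue
                p_start = int(rng.integers(0, n1 - total - 50))
                d_start = p_start + arm + span
                # reserve only the arm loci: unrelated duplexes may nest
                # inside the intervening span
                if not reserve(tx1, p_start, p_start + arm):
                    continue
                if not reserve(tx1, d_start, d_start + arm):
                    used[tx1].remove((p_start, p_start + arm))
                    continue
                prox = TranscriptInterval(tx1, p_start, p_start + arm)
                dist = TranscriptInterval(tx1, d_start, d_start + arm)
            arm_seq = "".join(seqs[prox.transcript_id][prox.start : prox.end])
            seqs[dist.transcript_id][dist.start : dist.end] = list(revcomp(arm_seq))
            return PlantedDuplex(duplex_id=did, proximal=prox, distal=dist, kind=kind)
        return None

    for j in range(config.n_duplexes):
        d = plant(f"DUP{j + 1:05d}", "ligation")
        if d is not None:
            truth.duplexes.append(d)
    for j in range(config.n_hairpins):
        d = plant(f"HP{j + 1:05d}", "hairpin")
        if d is not None:
            truth.duplexes.append(d)

    for tx in records:
        rec = records[tx]
        records[tx] = TranscriptRecord(
            transcript_id=tx,
            gene_id=rec.gene_id,
            sequence="".join(seqs[tx]),
            regions=list(rec.regions),
        )
    return records, truth


def _random_umi(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


def simulate_reads(
    records: dict[str, TranscriptRecord],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_reads: int = 2000,
    read_types: tuple[float, float, float] | None = None,
) -> list[tuple[str, str]]:
    """Emit (read_id, sequence) pairs with a 5' UMI for planted duplexes.

    Read provenance (source duplex, type, arm reference starts) is stored
    in ``truth.reads``.  PCR duplicates are appended after the unique
    molecules at the configured rate, occasionally with a single-base UMI
    error.
    """
    fractions = read_types if read_types is not None else config.read_type_fractions
    ligation = [d for d in truth.duplexes if d.kind == "ligation"]
    hairpins = [
        d
        for d in truth.duplexes
        if d.intra and d.span is not None and d.span <= config.max_stemloop_loop
    ]
    reads: list[tuple[str, str]] = []
    rmin, rmax = config.read_length_range
    counter = 0
    for _ in range(n_reads):
        choice = rng.random()
        if choice < fractions[0] and ligation:
            rtype = "linker"
            dup = ligation[int(rng.integers(len(ligation)))]
        elif choice < fractions[0] + fractions[1] and ligation:
            rtype = "direct"
            dup = ligation[int(rng.integers(len(ligation)))]
        elif hairpins:
            rtype = "stemloop"
            dup = hairpins[int(rng.integers(len(hairpins)))]
        else:
            continue
        counter += 1
        read_id = f"R{counter:07d}"
        prox, dist = dup.proximal, dup.distal
        seq1 = records[prox.transcript_id].sequence
        seq2 = records[dist.transcript_id].sequence
        trunc = 0
        if rtype == "stemloop":
            a = int(rng.integers(0, 15))
            b = int(rng.integers(0, 15))
            start = max(0, prox.start - a)
            end = min(len(seq1), dist.end + b)
            body = seq1[start:end]
            prov_prox, prov_dist = start, dist.start
        else:
            total = int(rng.integers(rmin, rmax + 1))
            arm_len = len(prox)
            max_ext = min(10, (dup.span or 12) - 2) if dup.intra else 10
            e1 = int(rng.integers(0, max(1, max_ext + 1)))
            l1 = arm_len + e1
            if rtype == "linker":
                trunc = int(rng.choice(3, p=np.array(config.linker_trunc_probs)))
                linker = config.linker[: len(config.linker) - trunc] if trunc else config.linker
                l2 = max(12, total - len(linker) - l1)
            else:
                linker = ""
                l2 = max(25, total - l1)
            arm1 = seq1[prox.start : min(len(seq1), prox.start + l1)]
            arm2 = seq2[dist.start : min(len(seq2), dist.start + l2)]
            body = arm1 + linker + arm2
            prov_prox, prov_dist = prox.start, dist.start
        umi = _random_umi(config.umi_length, rng)
        reads.append((read_id, umi + body))
        truth.reads[read_id] = ReadProvenance(
            read_id=read_id,
            duplex_id=dup.duplex_id,
            read_type=rtype,
            linker_trunc=trunc,
            prox_t_start=prov_prox,
            dist_t_start=prov_dist,
        )

    # PCR duplicates
    dups: list[tuple[str, str]] = []
    for read_id, seq in reads:
        while rng.random() < config.pcr_duplication_rate:
            counter += 1
            dup_id = f"R{counter:07d}"
            umi, body = seq[: config.umi_length], seq[config.umi_length :]
            if rng.random() < config.umi_error_rate:
                pos = int(rng.integers(len(umi)))
                alt = str(rng.choice([b for b in "ACGT" if b != umi[pos]]))
                umi = umi[:pos] + alt + umi[pos + 1 :]
            dups.append((dup_id, umi + body))
            truth.reads[dup_id] = replace(
                truth.reads[read_id], read_id=dup_id, is_duplicate=True
            )
    return reads + dups


@dataclass(frozen=True)
class StemloopStudy:
    """A panel of 3' UTRs with peaks, half of them carrying planted hairpins."""

    records: dict[str, TranscriptRecord]
    peaks: list[tuple[str, str, int]]  # (peak_id, transcript_id, start)
    hairpin_peaks: set[str]
    planted: dict[str, tuple[int, int, int]]  # peak_id -> (stem_len, loop_len, arm_offset)


def simulate_stemloop_study(
    n_utrs: int = 200,
    hairpin_fraction: float = 0.5,
    utr_length: int = 160,
    cds_length: int = 60,
    stem_range: tuple[int, int] = (8, 15),
    loop_range: tuple[int, int] = (4, 10),
    peak_offset: int = 45,
    arm_delay_range: tuple[int, int] = (5, 9),
    gc_fraction: float = 0.35,
    stem_gc_fraction: float = 0.6,
    rng: np.random.Generator | None = None,
) -> StemloopStudy:
    """Synthetic crosslink-peak panel for the stem-loop derivation workflow.

    One transcript (CDS + 3' UTR) per gene with one peak inside the UTR;
    in ``hairpin_fraction`` of genes a perfect hairpin (stem, short loop,
    reverse-complement stem) is planted a few nt downstream of the peak
    start, emulating crosslinking immediately upstream of a bound stem.
    The background emulates the AU-rich composition of mammalian 3' UTRs
    (default 35% GC) while planted stems are GC-enriched (60%), as real
    3' UTR stem-loops are relative to their flanks; loops are drawn from
    A/C so they stay unpaired.
    """
    rng = rng or np.random.default_rng()
    used: set[str] = set()
    records: dict[str, TranscriptRecord] = {}
    peaks: list[tuple[str, str, int]] = []
    hairpin_peaks: set[str] = set()
    planted: dict[str, tuple[int, int, int]] = {}
    n_hairpin = int(round(n_utrs * hairpin_fraction))
    for i in range(n_utrs):
        tx = f"UT{i + 1:04d}"
        length = cds_length + utr_length
        seq = list(_random_sequence(length, gc_fraction, rng, used, 13))
        peak_pos = cds_length + peak_offset  # transcript coordinate of the peak start
        peak_id = f"PK{i + 1:04d}"
        if i < n_hairpin:
            stem = int(rng.integers(stem_range[0], stem_range[1] + 1))
            loop = int(rng.integers(loop_range[0], loop_range[1] + 1))
            delay = int(rng.integers(arm_delay_range[0], arm_delay_range[1] + 1))
            start = peak_pos + delay
            p = np.array(
                [
                    (1 - stem_gc_fraction) / 2, stem_gc_fraction / 2,
                    stem_gc_fraction / 2, (1 - stem_gc_fraction) / 2,
                ]
            )
            arm_seq = "".join(rng.choice(_BASES, size=stem, p=p))
            seq[start : start + stem] = list(arm_seq)
            # unstructured loop: A/C only, so the loop cannot pair with
            # itself and cannot extend the stem
            loop_seq = rng.choice(np.array(["A", "C"]), size=loop)
            seq[start + stem : start + stem + loop] = list(loop_seq)
            seq[start + stem + loop : start + 2 * stem + loop] = list(revcomp(arm_seq))
            hairpin_peaks.add(peak_id)
            planted[peak_id] = (stem, loop, delay)
        records[tx] = TranscriptRecord(
            transcript_id=tx,
            gene_id=f"GU{i + 1:04d}",
            sequence="".join(seq),
            regions=[("CDS", 0, cds_length), ("UTR3", cds_length, length)],
        )
        peaks.append((peak_id, tx, peak_pos))
    return StemloopStudy(
        records=records, peaks=peaks, hairpin_peaks=hairpin_peaks, planted=planted
    )


def simulate_rates(
    n_genes: int,
    cluster_spec: list[tuple[float, tuple[float, float, float], tuple[float, float, float]]]
    | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[MetabolismRecord], dict[str, int]]:
    """Draw per-gene metabolism rates from lognormal cluster components.

    ``cluster_spec`` lists (fraction, log10 means, log10 sds) per cluster
    for (synthesis, processing, degradation); the default mirrors three
    well-separated regimes (high-degradation, low-everything,
    high-synthesis/low-degradation).  Returns records plus true labels.
    """
    rng = rng or np.random.default_rng()
    if cluster_spec is None:
        cluster_spec = [
            (0.30, (0.6, 0.5, 0.8), (0.12, 0.12, 0.12)),
            (0.40, (0.0, -0.1, 0.0), (0.12, 0.12, 0.12)),
            (0.30, (1.2, 1.1, -0.8), (0.12, 0.12, 0.12)),
        ]
    fracs = np.array([f for f, _, _ in cluster_spec])
    fracs = fracs / fracs.sum()
    records: list[MetabolismRecord] = []
    labels: dict[str, int] = {}
    for i in range(n_genes):
        c = int(rng.choice(len(cluster_spec), p=fracs))
        _, mus, sds = cluster_spec[c]
        syn, proc, deg = (10 ** rng.normal(m, s) for m, s in zip(mus, sds))
        gene = f"G{i + 1:05d}"
        records.append(
            MetabolismRecord(
                gene_id=gene,
                synthesis=syn,
                processing=proc,
                degradation=deg,
                copy_number=float(10 ** rng.normal(1.0, 0.5)),
            )
        )
        labels[gene] = c
    return records, labels


def write_fastq(reads: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
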