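"""Integration of duplex atlases with RNA metabolism rates.

Genes carrying 3' UTR duplexes are related to their synthesis, processing
and degradation rates: expression-matched background sets, k-medoid (PAM)
clustering of log-scaled rates, a compaction score (intron-corrected
duplex span over intron-corrected 3' UTR length) and the 3'-UTR-thirds
occupancy of the duplex span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .reference import TranscriptInterval

log = logging.getLogger(__name__)

RATE_COLUMNS = ("synthesis", "processing", "degradation")


@dataclass(frozen=True)
class MetabolismRecord:
    gene_id: str
    synthesis: float
    processing: float
    degradation: float
    copy_number: float = float("nan")


def load_rates(path: str | Path) -> list[MetabolismRecord]:
    """Read a rate table TSV: gene, synthesis, processing, degradation[, copy_number]."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    out = []
    for _, row in df.iterrows():
        out.append(
            MetabolismRecord(
                gene_id=str(row[cols.get("gene", cols.get("gene_id", df.columns[0]))]),
                synthesis=float(row[cols["synthesis"]]),
                processing=float(row[cols["processing"]]),
                degradation=float(row[cols["degradation"]]),
                copy_number=float(row[cols["copy_number"]]) if "copy_number" in cols else float("nan"),
            )
        )
    return out


def expression_match(
    genes_with_duplexes: Sequence[str],
    genes_without: Sequence[str],
    copy_numbers: dict[str, float],
) -> set[str]:
    """Expression-matched gene set for metabolism comparisons.

    The threshold is the 5th percentile (linear interpolation between
    order statistics) of copy number among duplex-bearing genes; genes from
    both groups strictly above it are kept.
    """
    if not genes_with_duplexes:
        raise ValueError("empty duplex-bearing gene set")
    ref = np.array([copy_numbers[g] for g in genes_with_duplexes], dtype=float)
    threshold = float(np.percentile(ref, 5))
    return {
        g
        for g in list(genes_with_duplexes) + list(genes_without)
        if copy_numbers.get(g, -np.inf) > threshold
    }


def _pam(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning Around Medoids with the deterministic BUILD + SWAP steps.

    Returns (medoid_indices, labels).  BUILD greedily minimises total
    distance; SWAP applies the best improving (medoid, point) exchange
    until convergence.  Euclidean distance; ties broken by lowest index,
    so the fit is order-stable.
    """
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        cur = D[:, medoids].min(axis=1)
        gains = np.array(
            [
                np.maximum(cur - D[:, j], 0).sum() if j not in medoids else -np.inf
                for j in range(n)
            ]
        )
        medoids.append(int(np.argmax(gains)))
    medoids_arr = np.array(sorted(medoids))
    for _ in range(max_iter):
        best_delta, best_swap = 0.0, None
        cost = D[:, medoids_arr].min(axis=1).sum()
        for mi, m in enumerate(medoids_arr):
            for h in range(n):
                if h in medoids_arr:
                    continue
                trial = medoids_arr.copy()
                trial[mi] = h
                delta = D[:, trial].min(axis=1).sum() - cost
                if delta < best_delta - 1e-12:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids_arr[best_swap[0]] = best_swap[1]
        medoids_arr = np.array(sorted(medoids_arr))
    labels = np.argmin(D[:, medoids_arr], axis=1)
    return medoids_arr, labels


@dataclass
class MetabolismClustering:
    assignments: dict[str, str]          # gene -> "A"/"B"/...
    silhouettes: dict[int, float]
    chosen_k: int
    cluster_means: pd.DataFrame          # z-scored rate means per cluster
    dropped: list[str]


def cluster_metabolism(
    records: Sequence[MetabolismRecord],
    k: int = 3,
    rng: np.random.Generator | None = None,
    k_range: Sequence[int] = range(2, 9),
) -> MetabolismClustering:
    """PAM clustering of log10 z-scored synthesis/processing/degradation.

    Silhouette widths are reported over ``k_range`` for reference but the
    partition uses ``k`` clusters (default 3).  Clusters are named A, B,
    C ... by mean degradation rate descending, so labels are reproducible.
    Records with non-positive rates are dropped with a log message.
    """
    rng = rng or np.random.default_rng()
    dropped = [
        r.gene_id
        for r in records
        if min(r.synthesis, r.processing, r.degradation) <= 0
    ]
    kept = [r for r in records if r.gene_id not in set(dropped)]
    if dropped:
        log.info("cluster_metabolism: dropped %d genes with non-positive rates", len(dropped))
    if len(kept) < k:
        raise ValueError("fewer records than clusters")
    X = np.log10(
        np.array([[r.synthesis, r.processing, r.degradation] for r in kept])
    )
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd

    silhouettes: dict[int, float] = {}
    for kk in k_range:
        if kk >= len(kept):
            continue
        _, labs = _pam(X, kk, rng)
        if len(set(labs.tolist())) > 1:
            silhouettes[kk] = float(silhouette_score(X, labs))
    _, labels = _pam(X, k, rng)
    if len(set(labels.tolist())) == 1:
        log.warning("cluster_metabolism: degenerate input, single cluster")

    deg_means = []
    for c in range(k):
        mask = labels == c
        deg_means.append((X[mask, 2].mean() if mask.any() else -np.inf, c))
    deg_means.sort(reverse=True)
    name = {c: chr(ord("A") + rank) for rank, (_, c) in enumerate(deg_means)}
    assignments = {r.gene_id: name[int(lab)] for r, lab in zip(kept, labels)}
    rows = []
    for rank, (_, c) in enumerate(deg_means):
        mask = labels == c
        rows.append(
            {
                "cluster": chr(ord("A") + rank),
                "n": int(mask.sum()),
                "synthesis": float(X[mask, 0].mean()),
                "processing": float(X[mask, 1].mean()),
                "degradation": float(X[mask, 2].mean()),
            }
        )
    return MetabolismClustering(
        assignments=assignments,
        silhouettes=silhouettes,
        chosen_k=k,
        cluster_means=pd.DataFrame(rows),
        dropped=dropped,
    )


@dataclass(frozen=True)
class CompactionResult:
    gene_id: str
    duplex_span_corrected: int
    utr3_length_corrected: int
    compaction: float
    thirds_spanned: int


def _intron_overlap(start: int, end: int, introns: Iterable[tuple[int, int]]) -> int:
    return sum(max(0, min(end, e) - max(start, s)) for s, e in introns)


def compaction_score(
    gene_id: str,
    duplex_proximal: TranscriptInterval,
    duplex_distal: TranscriptInterval,
    utr3: TranscriptInterval,
    introns: Sequence[tuple[int, int]] = (),
) -> CompactionResult:
    """Intron-corrected duplex span over intron-corrected 3' UTR length.

    The duplex span here is the full extent from the proximal arm start to
    the distal arm end; introns inside the span and inside the UTR are
    subtracted from numerator and denominator respectively.
    """
    if duplex_proximal.transcript_id != utr3.transcript_id:
        raise ValueError("duplex and UTR on different transcripts")
    span_start, span_end = duplex_proximal.start, duplex_distal.end
    if span_start < utr3.start or span_end > utr3.end:
        raise ValueError(f"{gene_id}: duplex outside the 3' UTR")
    span_corr = (span_end - span_start) - _intron_overlap(span_start, span_end, introns)
    utr_corr = len(utr3) - _intron_overlap(utr3.start, utr3.end, introns)
    if utr_corr <= 0:
        raise ValueError(f"{gene_id}: non-positive corrected UTR length")
    if span_corr <= 0:
        raise ValueError(f"{gene_id}: non-positive corrected span")
    return CompactionResult(
        gene_id=gene_id,
        duplex_span_corrected=span_corr,
        utr3_length_corrected=utr_corr,
        compaction=span_corr / utr_corr,
        thirds_spanned=thirds_spanned(duplex_proximal, duplex_distal, utr3),
    )


def thirds_spanned(
    duplex_proximal: TranscriptInterval,
    duplex_distal: TranscriptInterval,
    utr3: TranscriptInterval,
) -> int:
    """How many thirds of the 3' UTR the duplex extent intersects (1-3).

    The UTR is split into three equal parts with the remainder assigned to
    the last third.
    """
    span_start, span_end = duplex_proximal.start, duplex_distal.end
    if span_start < utr3.start or span_end > utr3.end:
        raise ValueError("duplex outside the 3' UTR")
    L = len(utr3)
    third = L // 3
    bounds = [
        (utr3.start, utr3.start + third),
        (utr3.start + third, utr3.start + 2 * third),
        (utr3.start + 2 * third, utr3.end),
    ]
    return sum(
        1 for s, e in bounds if min(span_end, e) - max(span_start, s) > 0
    )


def cluster_group_summary(
    assignments: dict[str, str], measures: pd.DataFrame, value_column: str
) -> pd.DataFrame:
    """Per-cluster summary of an external per-gene measure.

    Joins a user-provided table (e.g. translation potential) on its first
    column (gene id) against cluster assignments and reports count,
    median and mean per cluster — a plain join + grouped summary, no
    bespoke computation.
    """
    gene_col = measures.columns[0]
    df = measures[[gene_col, value_column]].copy()
    df["cluster"] = df[gene_col].map(assignments)
    df = df.dropna(subset=["cluster"])
    return (
        df.groupby("cluster")[value_column]
        .agg(["count", "median", "mean"])
        .reset_index()
    )
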