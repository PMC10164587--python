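"""Derivation of short-range bound stem-loops from crosslink peaks.

Stem-loops with short loops survive RNase digestion as contiguous
(non-hybrid) reads and so escape proximity-ligation detection.  They can
nevertheless be recovered computationally: crosslinking favours unpaired
nucleotides immediately upstream of a bound stem, so the windowed pairing
probability downstream of a crosslink peak shows a characteristic
"M"-shaped paired-unpaired-paired pattern.  The workflow is:

1. compute the pairing-probability profile of each 3' UTR (window 100 nt)
   and a dinucleotide-shuffled control profile;
2. extract the -100..+100 nt profile around each peak start and k-means
   cluster the +10..+75 nt region, choosing k by mean silhouette;
3. keep clusters whose metaprofile shows the M shape, delineate proximal
   and distal arm regions from the local minima of the metaprofile;
4. fold the two arm regions of each peak against each other, trim
   unpaired flanks, and keep duplexes with at least 8 base pairs (shorter
   stems are below the binding threshold of the Staufen double-stranded
   RNA binding domain).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .duplexfold import DuplexStructure, duplex_mfe
from .partition import PairingProfile, pairing_probabilities
from .reference import TranscriptInterval, TranscriptRecord
from .shuffle import dinucleotide_shuffle

log = logging.getLogger(__name__)

FLANK = 100                   # profile window: -FLANK..+FLANK around peak start
CLUSTER_REGION = (10, 75)     # inclusive offsets used for clustering
MIN_STEM_PAIRS = 8
SMOOTH_WIDTH = 5


@dataclass
class PeakProfile:
    """Paired-probability context of one crosslink peak (length 201)."""

    peak_id: str
    transcript_id: str
    peak_start: int
    prob_window: np.ndarray
    cluster_id: int | None = None

    def region(self, lo: int = CLUSTER_REGION[0], hi: int = CLUSTER_REGION[1]) -> np.ndarray:
        return self.prob_window[FLANK + lo : FLANK + hi + 1]


@dataclass
class DerivedDuplex:
    peak_id: str
    proximal: TranscriptInterval
    distal: TranscriptInterval
    structure: DuplexStructure
    loop_length: int
    passes_filter: bool


def extract_peak_profile(
    peak_id: str, transcript_id: str, peak_start: int, prob: np.ndarray
) -> PeakProfile:
    """Cut the -100..+100 window around a peak start, NaN-padding the ends."""
    window = np.full(2 * FLANK + 1, np.nan)
    lo = peak_start - FLANK
    for off in range(2 * FLANK + 1):
        pos = lo + off
        if 0 <= pos < len(prob):
            window[off] = prob[pos]
    return PeakProfile(peak_id, transcript_id, peak_start, window)


def build_metaprofile(profiles: Sequence[PeakProfile]) -> tuple[np.ndarray, np.ndarray]:
    """Per-position NaN-ignoring mean and standard error across peaks."""
    if not profiles:
        raise ValueError("no profiles")
    mat = np.vstack([p.prob_window for p in profiles])
    with warnings.catch_warnings():
        # positions covered by no or one profile legitimately yield NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        n = np.sum(~np.isnan(mat), axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    return mean, sem


def _smooth(v: np.ndarray, width: int = SMOOTH_WIDTH) -> np.ndarray:
    kernel = np.ones(width) / width
    padded = np.pad(v, width // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def _local_maxima(v: np.ndarray) -> list[int]:
    """Interior local maxima, plus window edges when monotone into them."""
    out = [i for i in range(1, len(v) - 1) if v[i] > v[i - 1] and v[i] >= v[i + 1]]
    if len(v) > 1 and v[0] > v[1]:
        out.insert(0, 0)
    if len(v) > 1 and v[-1] > v[-2]:
        out.append(len(v) - 1)
    return sorted(out)


def _local_minima(v: np.ndarray) -> list[int]:
    return [i for i in range(1, len(v) - 1) if v[i] < v[i - 1] and v[i] <= v[i + 1]]


#: minimum drop (in pairing probability) from the lower of the two maxima
#: to the separating minimum for the pattern to count as a stem-loop
#: signature; averaging unstructured profiles produces only shallow
#: undulations, well below this
M_SHAPE_PROMINENCE = 0.1


def detect_m_shape(
    region_profile: np.ndarray, prominence: float = M_SHAPE_PROMINENCE
) -> bool:
    """Paired-unpaired-paired pattern test on the +10..+75 region profile.

    True iff the smoothed profile has at least two local maxima above the
    region mean separated by a local minimum below it, with the dip at
    least ``prominence`` below the lower of the two maxima.
    """
    v = np.asarray(region_profile, dtype=float)
    v = np.where(np.isnan(v), np.nanmean(v), v)
    s = _smooth(v)
    mean = s.mean()
    maxima = [i for i in _local_maxima(s) if s[i] > mean]
    if len(maxima) < 2:
        return False
    minima = _local_minima(s)
    for a_idx in range(len(maxima) - 1):
        for b_idx in range(a_idx + 1, len(maxima)):
            a, b = maxima[a_idx], maxima[b_idx]
            for m in minima:
                if (
                    a < m < b
                    and s[m] < mean
                    and min(s[a], s[b]) - s[m] >= prominence
                ):
                    return True
    return False


@dataclass
class ProfileClustering:
    assignments: dict[str, int]
    chosen_k: int
    silhouettes: dict[int, float]
    metaprofiles: dict[int, np.ndarray]  # cluster -> mean 201-profile
    m_shaped: dict[int, bool]
    kept: list[PeakProfile] = field(default_factory=list)


def cluster_peak_profiles(
    profiles: Sequence[PeakProfile],
    k_range: Sequence[int] = range(2, 9),
    rng: np.random.Generator | None = None,
    max_nan_fraction: float = 0.2,
) -> ProfileClustering:
    """k-means clustering of the +10..+75 region, k chosen by silhouette.

    Profiles with more than 20% missing values in the region are dropped;
    remaining NaNs are imputed with the position mean.  Clusters are
    relabelled by mean region probability descending (cluster 0 = most
    paired).  Identical profiles (zero variance) force a single cluster.
    """
    rng = rng or np.random.default_rng()
    kept = [p for p in profiles if np.isnan(p.region()).mean() <= max_nan_fraction]
    if not kept:
        raise ValueError("no usable profiles")
    X = np.vstack([p.region() for p in kept])
    col_mean = np.nanmean(X, axis=0)
    nan_pos = np.isnan(X)
    X[nan_pos] = np.take(col_mean, np.where(nan_pos)[1])
    # light smoothing suppresses single-position noise while keeping the
    # paired-unpaired-paired geometry that distinguishes the clusters
    X = np.vstack([_smooth(row, 3) for row in X])

    def finish(labels: np.ndarray, k: int, sils: dict[int, float]) -> ProfileClustering:
        by_mean = [
            (X[labels == c].mean(), c) for c in range(k) if np.any(labels == c)
        ]
        by_mean.sort(reverse=True)
        relabel = {old: new for new, (_, old) in enumerate(by_mean)}
        assignments = {}
        metas: dict[int, np.ndarray] = {}
        mshape: dict[int, bool] = {}
        for p, lab in zip(kept, labels):
            p.cluster_id = relabel[lab]
            assignments[p.peak_id] = p.cluster_id
        for c in sorted(set(relabel.values())):
            members = [p for p in kept if p.cluster_id == c]
            mean, _ = build_metaprofile(members)
            metas[c] = mean
            region = mean[FLANK + CLUSTER_REGION[0] : FLANK + CLUSTER_REGION[1] + 1]
            mshape[c] = detect_m_shape(region)
        return ProfileClustering(
            assignments=assignments,
            chosen_k=k,
            silhouettes=sils,
            metaprofiles=metas,
            m_shaped=mshape,
            kept=kept,
        )

    if np.allclose(X, X[0]):
        return finish(np.zeros(len(kept), dtype=int), 1, {})

    ks = [k for k in k_range if k < len(kept)]
    if not ks:
        return finish(np.zeros(len(kept), dtype=int), 1, {})
    sils: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(X)
        labels_by_k[k] = labels
        if len(set(labels)) < 2:
            sils[k] = -1.0
        else:
            sils[k] = float(silhouette_score(X, labels))
    best_k = max(sils, key=lambda k: sils[k])
    return finish(labels_by_k[best_k], best_k, sils)


#: outer padding (nt) added to the delineated arm regions before folding;
#: unpaired flanks are trimmed afterwards, so padding only guards against
#: metaprofile averaging clipping the arm extremities
ARM_REGION_PAD = 5


def delineate_arms(
    cluster_metaprofile: np.ndarray,
    prominence: float = M_SHAPE_PROMINENCE,
    pad: int = ARM_REGION_PAD,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Arm regions (inclusive offsets downstream of the peak start).

    Works on the +0..+100 part of a cluster metaprofile.  The two maxima
    of the M shape are chosen as the pair with the most prominent
    separating minimum (same criterion as :func:`detect_m_shape`); that
    minimum ends the proximal arm (a boundary minimum belongs to the
    proximal arm), the distal arm ends where the profile falls back to
    the mean (or at the next local minimum), and the proximal arm starts
    where the profile begins its rise to the first maximum.  Regions are
    padded outward by ``pad`` nt — unpaired flanks are trimmed after
    folding.  Raises ValueError for profiles without a usable M geometry.
    """
    down = np.asarray(cluster_metaprofile[FLANK : 2 * FLANK + 1], dtype=float)
    down = np.where(np.isnan(down), np.nanmean(down), down)
    s = _smooth(down)
    mean = s.mean()
    maxima = [i for i in _local_maxima(s) if s[i] > mean]
    minima = _local_minima(s)
    best = None  # (prominence, m1, dip, m2)
    for ai in range(len(maxima) - 1):
        for bi in range(ai + 1, len(maxima)):
            a, b = maxima[ai], maxima[bi]
            between = [m for m in minima if a < m < b and s[m] < mean]
            if not between:
                continue
            dip = min(between, key=lambda m: s[m])
            prom = min(s[a], s[b]) - s[dip]
            if prom >= prominence and (best is None or prom > best[0]):
                best = (prom, a, dip, b)
    if best is None:
        raise ValueError("metaprofile lacks an M geometry; cluster rejected")
    _, m1, first_min, m2 = best
    # distal arm end: first local minimum or mean crossing after m2
    second_min = None
    for i in range(m2 + 1, len(s)):
        if i in minima or s[i] < mean:
            second_min = i
            break
    if second_min is None:
        raise ValueError("no minimum after the distal maximum; cluster rejected")
    # rise start: last position before m1 at which the profile stops falling
    rise = 0
    for i in range(m1 - 1, 0, -1):
        if s[i - 1] >= s[i]:
            rise = i
            break
    prox = (max(0, rise - pad), first_min)
    dist = (first_min + 1, min(len(s) - 1, second_min + pad))
    return prox, dist


def derive_duplex(
    peak: PeakProfile,
    prox_region: tuple[int, int],
    dist_region: tuple[int, int],
    sequence: str,
    min_stem_pairs: int = MIN_STEM_PAIRS,
    contiguous: bool = True,
    model=None,
) -> DerivedDuplex | None:
    """Fold the two arm regions of one peak and trim unpaired flanks.

    Regions are inclusive offsets relative to the peak start on the given
    (transcript or 3' UTR) sequence; they are clipped to the sequence.
    Returns None when a region is empty after clipping or no pairing
    forms.  ``passes_filter`` requires a helix of >= ``min_stem_pairs``
    contiguously stacked pairs — the binding threshold refers to a
    physical stem; ``contiguous=False`` counts total pairs instead.
    """
    n = len(sequence)
    p0 = max(0, peak.peak_start + prox_region[0])
    p1 = min(n, peak.peak_start + prox_region[1] + 1)
    d0 = max(0, peak.peak_start + dist_region[0])
    d1 = min(n, peak.peak_start + dist_region[1] + 1)
    if p1 <= p0 or d1 <= d0:
        return None
    arm1, arm2 = sequence[p0:p1], sequence[d0:d1]
    structure = duplex_mfe(arm1, arm2, model=model)
    if not structure.pairing:
        return None
    pairs = sorted(structure.pairing)
    i_lo, i_hi = pairs[0][0], pairs[-1][0]
    j_lo = min(j for _, j in pairs)
    j_hi = max(j for _, j in pairs)
    prox_iv = TranscriptInterval(peak.transcript_id, p0 + i_lo, p0 + i_hi + 1)
    dist_iv = TranscriptInterval(peak.transcript_id, d0 + j_lo, d0 + j_hi + 1)
    if contiguous:
        longest = run = 1
        for (a1, b1), (a2, b2) in zip(pairs, pairs[1:]):
            run = run + 1 if (a2 == a1 + 1 and b2 == b1 - 1) else 1
            longest = max(longest, run)
        passes = longest >= min_stem_pairs
    else:
        passes = structure.n_pairs >= min_stem_pairs
    return DerivedDuplex(
        peak_id=peak.peak_id,
        proximal=prox_iv,
        distal=dist_iv,
        structure=structure,
        loop_length=dist_iv.start - prox_iv.end,
        passes_filter=passes,
    )


@dataclass
class DerivationResult:
    duplexes: list[DerivedDuplex]
    profiles: list[PeakProfile]
    clustering: ProfileClustering | None
    control_metaprofile: np.ndarray | None
    metaprofile: np.ndarray | None
    counts: Counter


def run_derivation(
    peaks: Sequence[tuple[str, str, int]],
    records: Mapping[str, TranscriptRecord],
    representative: Mapping[str, str] | None = None,
    window: int = 100,
    window_step: int = 10,
    n_control_shuffles: int = 20,
    min_stem_pairs: int = MIN_STEM_PAIRS,
    rng: np.random.Generator | None = None,
    model=None,
) -> DerivationResult:
    """End-to-end stem-loop derivation from crosslink peaks on 3' UTRs.

    ``peaks`` are (peak_id, transcript_id, start) with starts in transcript
    coordinates; only peaks inside the representative transcript's 3' UTR
    are used (``representative`` maps gene -> transcript; by default the
    gene's longest annotated 3' UTR wins).  Profiles are computed on the
    3' UTR sequence with the windowed partition function; the control
    metaprofile averages dinucleotide-shuffled UTRs.
    """
    rng = rng or np.random.default_rng()
    counts: Counter[str] = Counter()

    # representative 3' UTR per gene
    by_gene: dict[str, TranscriptRecord] = {}
    for rec in records.values():
        utr = rec.region_interval("UTR3")
        if utr is None:
            continue
        if representative is not None:
            if representative.get(rec.gene_id) == rec.transcript_id:
                by_gene[rec.gene_id] = rec
        else:
            cur = by_gene.get(rec.gene_id)
            if cur is None or len(utr) > len(cur.region_interval("UTR3")):
                by_gene[rec.gene_id] = rec
    rep_tx = {rec.transcript_id: rec for rec in by_gene.values()}

    # UTR profiles (computed once per transcript with peaks)
    needed = sorted({tx for _, tx, _ in peaks if tx in rep_tx})
    utr_prob: dict[str, np.ndarray] = {}
    utr_seq: dict[str, str] = {}
    utr_start: dict[str, int] = {}
    control_profiles: list[np.ndarray] = []
    for tx in needed:
        rec = rep_tx[tx]
        utr = rec.region_interval("UTR3")
        seq = rec.sequence[utr.start : utr.end]
        utr_seq[tx] = seq
        utr_start[tx] = utr.start
        utr_prob[tx] = pairing_probabilities(seq, window=window, step=window_step).prob
        ctrl = np.zeros(len(seq))
        for _ in range(n_control_shuffles):
            shuf = dinucleotide_shuffle(seq, rng)
            ctrl += pairing_probabilities(shuf, window=window, step=window_step).prob
        control_profiles.append(ctrl / max(n_control_shuffles, 1))

    profiles: list[PeakProfile] = []
    control_peak_profiles: list[PeakProfile] = []
    for peak_id, tx, start in peaks:
        if tx not in rep_tx:
            counts["skipped_not_representative"] += 1
            continue
        rec = rep_tx[tx]
        utr = rec.region_interval("UTR3")
        if not (utr.start <= start < utr.end):
            counts["skipped_outside_utr3"] += 1
            continue
        rel = start - utr.start
        profiles.append(extract_peak_profile(peak_id, tx, rel, utr_prob[tx]))
        idx = needed.index(tx)
        control_peak_profiles.append(
            extract_peak_profile(peak_id, tx, rel, control_profiles[idx])
        )
    counts["peaks_profiled"] = len(profiles)
    if not profiles:
        return DerivationResult([], [], None, None, None, counts)

    metaprofile, _ = build_metaprofile(profiles)
    control_meta, _ = build_metaprofile(control_peak_profiles)

    clustering = cluster_peak_profiles(profiles, rng=rng)
    duplexes: list[DerivedDuplex] = []
    for cid, is_m in sorted(clustering.m_shaped.items()):
        members = [p for p in clustering.kept if p.cluster_id == cid]
        if not is_m:
            counts["peaks_in_no_structure_clusters"] += len(members)
            continue
        try:
            prox_region, dist_region = delineate_arms(clustering.metaprofiles[cid])
        except ValueError:
            counts["clusters_rejected_no_minima"] += 1
            continue
        for p in members:
            dd = derive_duplex(
                p, prox_region, dist_region, utr_seq[p.transcript_id],
                min_stem_pairs=min_stem_pairs, model=model,
            )
            if dd is None:
                counts["no_duplex"] += 1
                continue
            # lift from UTR coordinates back to transcript coordinates
            off = utr_start[p.transcript_id]
            dd.proximal = TranscriptInterval(
                p.transcript_id, dd.proximal.start + off, dd.proximal.end + off
            )
            dd.distal = TranscriptInterval(
                p.transcript_id, dd.distal.start + off, dd.distal.end + off
            )
            duplexes.append(dd)
    counts["derived"] = len(duplexes)
    counts["derived_passing"] = sum(d.passes_filter for d in duplexes)
    log.info("stem-loop derivation: %s", dict(counts))
    return DerivationResult(
        duplexes=duplexes,
        profiles=profiles,
        clustering=clustering,
        control_metaprofile=control_meta,
        metaprofile=metaprofile,
        counts=counts,
    )
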