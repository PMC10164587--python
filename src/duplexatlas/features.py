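"""Structural classification of duplexes and span statistics.

Duplex architecture — bulges (single unpaired nucleotides on one arm
within a stem), internal loops, symmetry of loop elements between the two
arms, base-pair composition and contiguous stem length — distinguishes
duplexes selected by double-stranded RBPs from the global population.
Span distributions are summarised with a small univariate Gaussian
mixture fitted by EM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .duplexfold import DuplexStructure

SPAN_SHORT_MAX = 25   # short-range: span < 25 nt
SPAN_MEDIUM_MAX = 100  # medium-range: 25 <= span <= 100; long-range: > 100

SYMMETRY_CLASSES = ("perfect", "symmetric", "asymmetric_no_bulge", "asymmetric_with_bulge")


@dataclass(frozen=True)
class LoopElement:
    kind: str  # "bulge" | "internal_loop"
    arm1_len: int
    arm2_len: int
    stem_position: int  # index of the pair preceding the gap


@dataclass(frozen=True)
class DuplexFeatures:
    n_pairs: int
    percent_paired: float
    au_pair_pct: float
    gc_pct: float
    n_bulges: int
    n_internal_loops: int
    longest_stem_segment: int
    symmetry_class: str
    span_class: str | None = None


def annotate_loops(structure: DuplexStructure) -> list[LoopElement]:
    """Bulges and internal loops between consecutive pairs of the stem.

    A gap with unpaired nucleotides on exactly one arm and length 1 is a
    bulge; anything larger, or unpaired on both arms, is an internal loop.
    """
    if not structure.pairing:
        raise ValueError("empty pairing")
    pairs = sorted(structure.pairing)
    out: list[LoopElement] = []
    for idx, ((i1, j1), (i2, j2)) in enumerate(zip(pairs, pairs[1:])):
        g1 = i2 - i1 - 1
        g2 = j1 - j2 - 1  # arm2 indices decrease along the stem
        if g1 == 0 and g2 == 0:
            continue
        if (g1 == 1 and g2 == 0) or (g1 == 0 and g2 == 1):
            kind = "bulge"
        else:
            kind = "internal_loop"
        out.append(LoopElement(kind=kind, arm1_len=g1, arm2_len=g2, stem_position=idx))
    return out


def classify_symmetry(structure: DuplexStructure) -> str:
    """Symmetry of the loop architecture.

    perfect: an uninterrupted helix.  symmetric: every inter-pair gap has
    identically-sized unpaired stretches on both arms.  Otherwise
    asymmetric, subdivided by whether at least one bulge is present.
    """
    loops = annotate_loops(structure)
    if not loops:
        return "perfect"
    if all(lp.arm1_len == lp.arm2_len for lp in loops):
        return "symmetric"
    if any(lp.kind == "bulge" for lp in loops):
        return "asymmetric_with_bulge"
    return "asymmetric_no_bulge"


def span_classify(span: int | None, derived: bool = False) -> str:
    """Span class of an intra-transcript duplex.

    Derived (stem-loop) duplexes keep their own class regardless of span.
    """
    if derived:
        return "derived"
    if span is None:
        raise ValueError("span undefined for inter-transcript duplexes")
    if span < SPAN_SHORT_MAX:
        return "short"
    if span <= SPAN_MEDIUM_MAX:
        return "medium"
    return "long"


def composition(structure: DuplexStructure) -> tuple[float, float, float, int, int]:
    """(au_pair_pct, gc_pct, percent_paired, n_pairs, longest_stem_segment)."""
    pairs = sorted(structure.pairing)
    if not pairs:
        return (0.0, 0.0, 0.0, 0, 0)
    a1 = structure.arm1_seq.upper().replace("U", "T")
    a2 = structure.arm2_seq.upper().replace("U", "T")
    n = len(pairs)
    au = sum(1 for i, j in pairs if {a1[i], a2[j]} == {"A", "T"})
    gc = sum(1 for i, j in pairs if {a1[i], a2[j]} == {"G", "C"})
    longest = run = 1
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if i2 == i1 + 1 and j2 == j1 - 1:
            run += 1
            longest = max(longest, run)
        else:
            run = 1
    percent_paired = 100.0 * 2 * n / (len(a1) + len(a2))
    return (100.0 * au / n, 100.0 * gc / n, percent_paired, n, longest)


def duplex_features(
    structure: DuplexStructure, span: int | None = None, derived: bool = False
) -> DuplexFeatures:
    """Full structural feature record for one duplex."""
    au, gc, pp, n, longest = composition(structure)
    loops = annotate_loops(structure) if structure.pairing else []
    return DuplexFeatures(
        n_pairs=n,
        percent_paired=pp,
        au_pair_pct=au,
        gc_pct=gc,
        n_bulges=sum(1 for lp in loops if lp.kind == "bulge"),
        n_internal_loops=sum(1 for lp in loops if lp.kind == "internal_loop"),
        longest_stem_segment=longest,
        symmetry_class=classify_symmetry(structure) if structure.pairing else "perfect",
        span_class=span_classify(span, derived) if (derived or span is not None) else None,
    )


@dataclass
class GaussianMixture1D:
    """EM fit of a univariate Gaussian mixture; components sorted by mean
    descending.  ``loglik_trace`` records the log-likelihood after every EM
    iteration (it is non-decreasing)."""

    weights: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray
    loglik_trace: list[float]

    @property
    def components(self) -> list[tuple[float, float, float]]:
        return [
            (float(w), float(m), float(s))
            for w, m, s in zip(self.weights, self.means, self.sigmas)
        ]


_SIGMA_FLOOR = 1e-3


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [x[rng.integers(len(x))]]
    for _ in range(k - 1):
        d2 = np.min([(x - c) ** 2 for c in centers], axis=0)
        if d2.sum() == 0:
            centers.append(x[rng.integers(len(x))])
        else:
            centers.append(x[rng.choice(len(x), p=d2 / d2.sum())])
    return np.array(centers, dtype=float)


def fit_span_mixture(
    spans: Sequence[float],
    k: int = 2,
    rng: np.random.Generator | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> GaussianMixture1D:
    """Fit a k-component Gaussian mixture to duplex spans by EM.

    Initialisation is k-means++ under the supplied generator, so fits are
    reproducible with a seeded rng.  Degenerate input (all values equal)
    collapses to a single component with a floored standard deviation.
    """
    x = np.asarray(spans, dtype=float)
    if len(x) < 2 * k:
        raise ValueError(f"need at least {2 * k} observations for k={k}")
    rng = rng or np.random.default_rng()
    if np.ptp(x) == 0:
        return GaussianMixture1D(
            weights=np.array([1.0]),
            means=np.array([x[0]]),
            sigmas=np.array([_SIGMA_FLOOR]),
            loglik_trace=[],
        )
    mu = _kmeanspp_init(x, k, rng)
    sigma = np.full(k, max(x.std(), _SIGMA_FLOOR))
    w = np.full(k, 1.0 / k)
    trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        # E step
        log_comp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2 * np.pi * sigma[None, :] ** 2)
            - 0.5 * ((x[:, None] - mu[None, :]) / sigma[None, :]) ** 2
        )
        m = log_comp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
        resp = np.exp(log_comp - lse[:, None])
        ll = float(lse.sum())
        trace.append(ll)
        # M step
        nk = resp.sum(axis=0)
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(np.maximum(var, _SIGMA_FLOOR**2))
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
    order = np.argsort(-mu)
    return GaussianMixture1D(
        weights=w[order], means=mu[order], sigmas=sigma[order], loglik_trace=trace
    )
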