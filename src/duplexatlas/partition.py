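"""Windowed equilibrium base-pairing probabilities.

For each window slid over a sequence, an exact partition function is
computed over all secondary structures satisfying: Watson-Crick + G:U
pairs only, non-crossing, hairpin loops of at least 3 nt, and no lonely
pairs (every maximal helix >= 2 stacked pairs).  Structures are weighted
by exp(-E/RT) at 37 C with the additive simple energy model (G:C = -3,
A:U = -2, G:U = -1 kcal/mol per pair).  The per-nucleotide probability of
being paired is obtained with an inside-outside algorithm; a base's final
profile value is the mean over all windows covering it.

The inside recursion decomposes every structure uniquely by maximal
helices: ``ZH(i,j)`` sums structures on [i,j] where (i,j) is the outer
pair of a maximal helix descending inward, ``T`` extends a helix, and the
helix interior excludes the continuation pair so each helix is counted at
its maximal inward extent.  The outside pass mirrors these recursions to
yield exact pair probabilities in O(n^3) per window; the numba-compiled
kernel makes sliding a 100-nt window over transcript-scale sequences
practical.  Partition values are held in unscaled doubles, ample for
windows up to a few hundred nucleotides under this model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .energymodel import RT37

DEFAULT_WINDOW = 100

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}

#: Boltzmann weight matrix over base codes (A, C, G, U, N)
_WEIGHTS = np.zeros((5, 5))
for _a, _b, _e in (
    (0, 3, -2.0), (3, 0, -2.0),  # A:U
    (2, 1, -3.0), (1, 2, -3.0),  # G:C
    (2, 3, -1.0), (3, 2, -1.0),  # G:U
):
    _WEIGHTS[_a, _b] = np.exp(-_e / RT37)

MIN_HAIRPIN = 3


def encode(sequence: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in sequence.upper()], dtype=np.int8)


@njit(cache=True)
def _window_pair_probs(codes, wmat):  # pragma: no cover - exercised via wrapper
    n = codes.shape[0]
    prob = np.zeros(n)
    if n < 2 * 2 + MIN_HAIRPIN:
        return prob

    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + MIN_HAIRPIN + 1, n):
            W[i, j] = wmat[codes[i], codes[j]]

    T = np.zeros((n, n))
    ZH = np.zeros((n, n))
    Z = np.zeros((n, n))  # Z[i,j] for segment [i..j]; empty handled inline

    for ell in range(1, n + 1):
        for i in range(0, n - ell + 1):
            j = i + ell - 1
            # helix extension T and maximal-helix ZH
            if W[i, j] > 0.0:
                a, b = i + 1, j - 1
                L = b - a + 1
                if L >= MIN_HAIRPIN:
                    iw = Z[a, b] - ZH[a, b] if L > 0 else 1.0
                else:
                    iw = 0.0
                tin = T[a, b] if a <= b else 0.0
                T[i, j] = W[i, j] * (iw + tin)
                ZH[i, j] = W[i, j] * (T[a, b] if a <= b else 0.0)
            # segment partition
            z = Z[i, j - 1] if j - 1 >= i else 1.0
            for k in range(i, j + 1):
                if ZH[k, j] > 0.0:
                    left = Z[i, k - 1] if k - 1 >= i else 1.0
                    z += left * ZH[k, j]
            Z[i, j] = z

    ztot = Z[0, n - 1]
    if ztot <= 0.0:
        return prob

    OZ = np.zeros((n, n))
    OH = np.zeros((n, n))
    OT = np.zeros((n, n))

    for ell in range(n, 0, -1):
        # outside of segment partitions
        for i in range(0, n - ell + 1):
            j = i + ell - 1
            v = 1.0 if (i == 0 and j == n - 1) else 0.0
            if j + 1 <= n - 1:
                v += OZ[i, j + 1]
            for b2 in range(j + 1, n):
                if ZH[j + 1, b2] > 0.0:
                    v += OZ[i, b2] * ZH[j + 1, b2]
            if ell >= MIN_HAIRPIN and i >= 1 and j + 1 <= n - 1:
                v += OT[i - 1, j + 1] * W[i - 1, j + 1]
            OZ[i, j] = v
        # outside of maximal helices and helix tails
        for i in range(0, n - ell + 1):
            j = i + ell - 1
            h = 0.0
            for a in range(0, i + 1):
                left = Z[a, i - 1] if i - 1 >= a else 1.0
                h += OZ[a, j] * left
            if ell >= MIN_HAIRPIN and i >= 1 and j + 1 <= n - 1:
                h -= OT[i - 1, j + 1] * W[i - 1, j + 1]
            OH[i, j] = h
            if i >= 1 and j + 1 <= n - 1 and W[i - 1, j + 1] > 0.0:
                OT[i, j] = W[i - 1, j + 1] * (OH[i - 1, j + 1] + OT[i - 1, j + 1])

    for i in range(n):
        for j in range(i + 1, n):
            if ZH[i, j] > 0.0 or T[i, j] > 0.0:
                wpq = (OH[i, j] * ZH[i, j] + OT[i, j] * T[i, j]) / ztot
                if wpq > 0.0:
                    prob[i] += wpq
                    prob[j] += wpq
    return prob


@dataclass
class PairingProfile:
    """Per-nucleotide paired probability over a sequence."""

    sequence: str
    window: int
    prob: np.ndarray
    control_prob: np.ndarray | None = None


def pairing_probabilities(
    sequence: str, window: int = DEFAULT_WINDOW, step: int = 1
) -> PairingProfile:
    """Windowed paired-probability profile of a sequence.

    Windows of length ``window`` (or the whole sequence if shorter) are
    slid with the given ``step``; the final window is anchored at the 3'
    end so every base is covered.  Each base's probability is the mean over
    windows covering it.  N bases never pair.
    """
    if len(sequence) < 1:
        raise ValueError("empty sequence")
    codes = encode(sequence)
    n = len(codes)
    w = min(window, n)
    starts = list(range(0, n - w + 1, step))
    if starts[-1] != n - w:
        starts.append(n - w)
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for s in starts:
        p = _window_pair_probs(codes[s : s + w], _WEIGHTS)
        acc[s : s + w] += p
        cnt[s : s + w] += 1
    return PairingProfile(sequence=sequence, window=window, prob=acc / cnt)
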