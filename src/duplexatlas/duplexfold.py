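"""Intermolecular minimum-free-energy duplex prediction.

Predicts the best base-pairing between two arm sequences, considering only
intermolecular pairs (no folding within an arm), disallowing pseudoknots
(pairings are non-crossing) and disallowing lonely pairs: every helix must
contain at least two stacked pairs.  The recursion is a two-state dynamic
programme over (arm1 position, reversed-arm2 position): state D1 holds
structures whose final helix currently has a single pair (and must be
extended by stacking before it can close or be followed by a loop), state
D2 holds structures whose final helix is already >= 2 pairs.  Interior
loops and bulges cost an affine penalty (init + per-nt), which a standard
gap matrix handles in O(m*n).

A duplex is reported only when its free energy is negative; otherwise the
result is the empty pairing with energy 0.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field

from .energymodel import DEFAULT_MODEL, can_pair

_INF = float("inf")


@dataclass
class DuplexStructure:
    """Predicted intermolecular pairing between two arms.

    ``pairing`` holds (i, j) pairs with i an arm1 index and j an arm2
    index; i increases while j decreases (antiparallel helix).  Energies
    are kcal/mol.
    """

    arm1_seq: str
    arm2_seq: str
    pairing: list[tuple[int, int]] = field(default_factory=list)
    energy: float = 0.0

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    @property
    def dot_bracket(self) -> tuple[str, str]:
        b1 = ["."] * len(self.arm1_seq)
        b2 = ["."] * len(self.arm2_seq)
        for i, j in self.pairing:
            b1[i] = "("
            b2[j] = ")"
        return "".join(b1), "".join(b2)

    def __str__(self) -> str:
        b1, b2 = self.dot_bracket
        return f"{b1}&{b2}\t({self.energy:.2f})"


def _normalise(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"non-RNA characters in arm sequence: {sorted(bad)}")
    return s


def duplex_mfe(arm1: str, arm2: str, model=None) -> DuplexStructure:
    """Minimum-free-energy intermolecular duplex between two arms.

    ``model`` is an energy model (see :mod:`duplexatlas.energymodel`);
    defaults to the nearest-neighbour model.  Arms are limited to 2000 nt.
    """
    model = model or DEFAULT_MODEL
    x = _normalise(arm1)
    y = _normalise(arm2)
    if not x or not y:
        raise ValueError("arms must be non-empty")
    if len(x) > 2000 or len(y) > 2000:
        raise ValueError("arms longer than 2000 nt are not supported")
    m, n = len(x), len(y)
    yr = y[::-1]  # reversed arm2: pairs then advance in both strands

    init_loop = model.loop(1, 0) - getattr(model, "loop_per_nt", 1.0)
    ext = getattr(model, "loop_per_nt", 1.0)

    D1 = [[_INF] * n for _ in range(m)]
    D2 = [[_INF] * n for _ in range(m)]
    G = [[_INF] * n for _ in range(m)]
    # back pointers: D1: 0 start, 1 via G[i-2][k-1], 2 via G[i-1][k-2]
    #                D2: 1 from D1 diag, 2 from D2 diag
    #                G:  0 D2 here, 1 from G[i-1][k], 2 from G[i][k-1]
    P1 = [[-1] * n for _ in range(m)]
    P2 = [[-1] * n for _ in range(m)]
    PG = [[-1] * n for _ in range(m)]

    for i in range(m):
        for k in range(n):
            if can_pair(x[i], yr[k]):
                e = model.pair(x[i], yr[k])
                # D1: open a new helix -- fresh start or after a loop
                best, ptr = 0.0, 0
                if i >= 2 and k >= 1 and G[i - 2][k - 1] < _INF:
                    cand = G[i - 2][k - 1] + ext + init_loop
                    if cand < best:
                        best, ptr = cand, 1
                if i >= 1 and k >= 2 and G[i - 1][k - 2] < _INF:
                    cand = G[i - 1][k - 2] + ext + init_loop
                    if cand < best:
                        best, ptr = cand, 2
                D1[i][k] = e + best
                P1[i][k] = ptr
                # D2: stack on the previous pair
                if i >= 1 and k >= 1 and can_pair(x[i - 1], yr[k - 1]):
                    st = model.stack((x[i - 1], yr[k - 1]), (x[i], yr[k]))
                    prev1, prev2 = D1[i - 1][k - 1], D2[i - 1][k - 1]
                    if prev1 < _INF or prev2 < _INF:
                        if prev1 <= prev2:
                            D2[i][k] = e + st + prev1
                            P2[i][k] = 1
                        else:
                            D2[i][k] = e + st + prev2
                            P2[i][k] = 2
            # G: best valid helix end reachable with per-nt extension
            g, gp = D2[i][k], 0
            if i >= 1 and G[i - 1][k] + ext < g:
                g, gp = G[i - 1][k] + ext, 1
            if k >= 1 and G[i][k - 1] + ext < g:
                g, gp = G[i][k - 1] + ext, 2
            G[i][k] = g
            PG[i][k] = gp

    best_e, best_ik = _INF, None
    for i in range(m):
        for k in range(n):
            if D2[i][k] < best_e:
                best_e, best_ik = D2[i][k], (i, k)
    total = best_e + getattr(model, "initiation", 0.0)
    if best_ik is None or total >= 0:
        return DuplexStructure(arm1_seq=arm1, arm2_seq=arm2, pairing=[], energy=0.0)

    # traceback
    pairs: list[tuple[int, int]] = []
    state, i, k = 2, *best_ik
    while True:
        if state == 2:
            pairs.append((i, k))
            ptr = P2[i][k]
            state = 1 if ptr == 1 else 2
            i, k = i - 1, k - 1
        elif state == 1:
            pairs.append((i, k))
            ptr = P1[i][k]
            if ptr == 0:
                break
            if ptr == 1:
                i, k = i - 2, k - 1
            else:
                i, k = i - 1, k - 2
            # walk the gap matrix back to its D2 cell
            while PG[i][k] != 0:
                if PG[i][k] == 1:
                    i -= 1
                else:
                    k -= 1
            state = 2

    pairing = sorted((i, n - 1 - k) for i, k in pairs)
    return DuplexStructure(arm1_seq=arm1, arm2_seq=arm2, pairing=pairing, energy=total)


def normalised_energy(structure: DuplexStructure) -> float | None:
    """Energy per paired residue (both arms' residues); None if unpaired."""
    if not structure.pairing:
        return None
    return structure.energy / (2 * structure.n_pairs)


def rnaduplex_available() -> bool:
    return shutil.which("RNAduplex") is not None


def duplex_mfe_external(arm1: str, arm2: str) -> DuplexStructure:
    """Pass-through to the ViennaRNA RNAduplex binary (full Turner model).

    Used as an optional external engine; output is parsed into the same
    structure record.  Requires RNAduplex on PATH.
    """
    rna1 = arm1.upper().replace("T", "U")
    rna2 = arm2.upper().replace("T", "U")
    proc = subprocess.run(
        ["RNAduplex", "--noLP"],
        input=f"{rna1}\n{rna2}\n",
        capture_output=True,
        text=True,
        check=True,
    )
    line = proc.stdout.strip().splitlines()[-1]
    # format: .((((&)))). 2,5 : 1,4 (-5.40)
    fields = line.split()
    db = fields[0]
    b1, b2 = db.split("&")
    i_rng = fields[1].split(",")
    j_rng = fields[3].split(",")
    energy = float(fields[-1].strip("()"))
    i0 = int(i_rng[0]) - 1
    j0 = int(j_rng[0]) - 1
    open_idx = [i0 + p for p, c in enumerate(b1) if c == "("]
    close_idx = [j0 + p for p, c in enumerate(b2) if c == ")"]
    pairing = list(zip(open_idx, reversed(close_idx)))
    return DuplexStructure(arm1_seq=arm1, arm2_seq=arm2, pairing=pairing, energy=energy)
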