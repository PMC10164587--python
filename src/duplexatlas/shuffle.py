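"""Dinucleotide-preserving sequence shuffling and shuffled-control energies.

Hybridisation energies are only meaningful against a null that preserves
local sequence composition, because stacking depends on adjacent
nucleotides.  The Euler-path (Altschul-Erikson) shuffle generates random
sequences with exactly the same dinucleotide count multiset and the same
first and last nucleotide, sampled uniformly over all such sequences.
"""

from __future__ import annotations

import numpy as np

from .duplexfold import duplex_mfe


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Uniform dinucleotide-preserving shuffle (Altschul-Erikson).

    Sequences shorter than 2 nt are returned unchanged.  The result starts
    and ends with the same nucleotides as the input, and every one of the 16
    dinucleotide counts is preserved.
    """
    if len(sequence) < 2:
        return sequence
    s = sequence
    last = s[-1]
    # multigraph of dinucleotide edges
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    vertices = sorted(edges.keys() | {last})

    while True:
        # choose a random candidate last edge for every vertex except the end
        last_edge: dict[str, str] = {}
        for v in vertices:
            if v == last:
                continue
            outs = edges.get(v, [])
            if outs:
                last_edge[v] = outs[rng.integers(len(outs))]
        # the chosen last edges must lead every vertex to the end vertex
        ok = True
        for v in last_edge:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break

    walk_lists: dict[str, list[str]] = {}
    for v in vertices:
        outs = list(edges.get(v, []))
        if v in last_edge:
            outs.remove(last_edge[v])
        perm = rng.permutation(len(outs))
        shuffled = [outs[i] for i in perm]
        if v in last_edge:
            shuffled.append(last_edge[v])
        walk_lists[v] = shuffled

    out = [s[0]]
    pos = {v: 0 for v in vertices}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = walk_lists[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def control_energy(
    arm1: str,
    arm2: str,
    rng: np.random.Generator,
    n_iter: int = 100,
    model=None,
) -> float:
    """Mean duplex MFE over ``n_iter`` independent shuffles of both arms."""
    total = 0.0
    for _ in range(n_iter):
        s1 = dinucleotide_shuffle(arm1, rng)
        s2 = dinucleotide_shuffle(arm2, rng)
        total += duplex_mfe(s1, s2, model=model).energy
    return total / n_iter
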