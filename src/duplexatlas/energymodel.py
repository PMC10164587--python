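"""Energy models for RNA base-pairing.

Two built-in models are provided:

* ``SimpleEnergyModel`` — additive per-pair scores (G:C = -3, A:U = -2,
  G:U = -1 kcal/mol) with a +1 kcal/mol penalty per unpaired interior
  nucleotide and no stacking terms.  It is fully enumerable, which makes
  exhaustive oracles practical, and is the model used by the partition
  function.

* ``NearestNeighborModel`` — a Turner-style stacking subset: measured
  Watson-Crick/Watson-Crick stack free energies at 37 C, an approximate
  constant for wobble-containing stacks, affine interior-loop/bulge
  penalties and a duplex initiation term.  Intended for realistic energy
  *scales*; all comparative analyses in this package are rank-based and do
  not depend on exact Turner-2004 replication.

Only Watson-Crick (A:U, G:C) and G:U wobble pairs are allowed; N never
pairs.  Temperature is fixed at 37 C.
"""

from __future__ import annotations

from dataclasses import dataclass

#: gas constant x 310.15 K, kcal/mol
RT37 = 0.0019872 * 310.15

_PAIR_OK = {
    ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "T"), ("T", "G"),
}

_PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -2.0, ("T", "A"): -2.0,
    ("G", "T"): -1.0, ("T", "G"): -1.0,
}


def can_pair(x: str, y: str) -> bool:
    return (x, y) in _PAIR_OK


def pair_energy_simple(x: str, y: str) -> float:
    """Simple-model pair energy (0 if the bases cannot pair)."""
    return _PAIR_ENERGY.get((x, y), 0.0)


@dataclass(frozen=True)
class SimpleEnergyModel:
    """Additive pair scores with linear loop penalties."""

    loop_per_nt: float = 1.0

    name = "simple"

    def pair(self, x: str, y: str) -> float:
        return _PAIR_ENERGY.get((x, y), 0.0)

    def stack(self, pair1: tuple[str, str], pair2: tuple[str, str]) -> float:
        return 0.0

    def loop(self, n1: int, n2: int) -> float:
        return self.loop_per_nt * (n1 + n2)

    initiation: float = 0.0


# Watson-Crick stack free energies at 37 C (kcal/mol), 5'->3' top strand.
# Key: ((top_i, bottom_i), (top_i+1, bottom_i+1)) on the DNA-alphabet
# encoding (T stands for U).
_WC_STACKS = {
    (("A", "T"), ("A", "T")): -0.93,
    (("A", "T"), ("T", "A")): -1.10,
    (("T", "A"), ("A", "T")): -1.33,
    (("T", "A"), ("T", "A")): -0.93,
    (("C", "G"), ("T", "A")): -2.08,
    (("C", "G"), ("A", "T")): -2.11,
    (("G", "C"), ("T", "A")): -2.24,
    (("G", "C"), ("A", "T")): -2.35,
    (("C", "G"), ("G", "C")): -2.36,
    (("G", "C"), ("G", "C")): -3.26,
    (("G", "C"), ("C", "G")): -3.42,
    (("C", "G"), ("C", "G")): -3.26,
    (("A", "T"), ("C", "G")): -2.24,
    (("A", "T"), ("G", "C")): -2.08,
    (("T", "A"), ("C", "G")): -2.35,
    (("T", "A"), ("G", "C")): -2.11,
}

#: stacks involving at least one G:U wobble — single documented constant
_WOBBLE_STACK = -1.0


@dataclass(frozen=True)
class NearestNeighborModel:
    """Stacking free energies with affine loop penalties.

    ``loop_init`` opens an interior loop or bulge, ``loop_per_nt`` extends
    it; ``initiation`` is the intermolecular duplex initiation penalty.
    """

    loop_init: float = 2.0
    loop_per_nt: float = 0.5
    initiation: float = 4.1

    name = "nearest_neighbour"

    def pair(self, x: str, y: str) -> float:
        return 0.0

    def stack(self, pair1: tuple[str, str], pair2: tuple[str, str]) -> float:
        e = _WC_STACKS.get((pair1, pair2))
        if e is not None:
            return e
        if pair1 in _PAIR_OK and pair2 in _PAIR_OK:
            return _WOBBLE_STACK
        return 0.0

    def loop(self, n1: int, n2: int) -> float:
        if n1 == 0 and n2 == 0:
            return 0.0
        return self.loop_init + self.loop_per_nt * (n1 + n2)


DEFAULT_MODEL = NearestNeighborModel()
SIMPLE_MODEL = SimpleEnergyModel()


def get_model(name: str):
    if name == "simple":
        return SIMPLE_MODEL
    if name in ("nearest_neighbour", "nearest-neighbour", "nn"):
        return DEFAULT_MODEL
    raise ValueError(f"unknown energy model {name!r}")
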