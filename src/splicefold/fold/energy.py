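"""Reduced nearest-neighbor energy model for nested RNA secondary structure.

The model scores a structure by loop decomposition: stacking energies for
adjacent base pairs, logarithmic hairpin / bulge / interior loop penalties,
an affine multiloop cost, and an optional per-paired-nucleotide SHAPE
pseudo-energy of the Deigan form ``m * ln(reactivity + 1) + b``.

It deliberately omits dangles, coaxial stacking and terminal-pair penalties
so that the same closed-form loop energies can be evaluated both by the
dynamic-programming engine and by exhaustive enumeration on short
sequences, which is how the engine is validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGUN"
A, C, G, U, N = range(5)

_CODE = {"A": A, "C": C, "G": G, "U": U, "T": U, "N": N}

# pair-type indices used by the stacking table
PAIR_NAMES = ("CG", "GC", "GU", "UG", "AU", "UA")
_PAIR_INDEX = {
    (C, G): 0,
    (G, C): 1,
    (G, U): 2,
    (U, G): 3,
    (A, U): 4,
    (U, A): 5,
}

#: intrinsic strength (kcal/mol) of each pair type; stacking energy of two
#: adjacent pairs is minus the sum of their strengths.
PAIR_WEIGHT = np.array([1.7, 1.6, 0.5, 0.6, 1.1, 1.0])

MIN_HAIRPIN = 3  # minimum unpaired nucleotides closed by a hairpin


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to integer codes (T treated as U, anything
    outside ACGU treated as N, which never pairs)."""
    return np.array([_CODE.get(ch, N) for ch in seq.upper()], dtype=np.int8)


def pair_table() -> np.ndarray:
    """5x5 table mapping (base_i, base_j) -> pair-type index or -1."""
    t = np.full((5, 5), -1, dtype=np.int8)
    for (a, b), k in _PAIR_INDEX.items():
        t[a, b] = k
    return t


def stack_table() -> np.ndarray:
    """Stacking energy (kcal/mol) indexed by [outer pair type, inner pair type]."""
    w = PAIR_WEIGHT
    return -(w[:, None] + w[None, :])


@dataclass(frozen=True)
class EnergyModel:
    """Parameters of the reduced nearest-neighbor model at 37 degC.

    Attributes
    ----------
    kT : Boltzmann factor at 310.15 K, kcal/mol.
    hairpin_a, loop_log : hairpin penalty ``a + c*ln(size/3)``.
    bulge_a, interior_a : affine part of bulge / interior loop penalties,
        both extended by ``loop_log * ln(total unpaired)``.
    ml_a, ml_b, ml_c : multiloop closure, per-branch and per-unpaired costs.
    maxloop : largest total unpaired size of an interior/bulge loop.
    shape_m, shape_b : Deigan slope/intercept (kcal/mol) applied per paired
        nucleotide as ``m*ln(r+1)+b``; masked positions contribute zero.
    """

    kT: float = 0.6156
    hairpin_a: float = 5.0
    loop_log: float = 1.077
    bulge_a: float = 3.2
    interior_a: float = 1.3
    ml_a: float = 3.4
    ml_b: float = 0.4
    ml_c: float = 0.1
    maxloop: int = 30
    shape_m: float = 1.8
    shape_b: float = -0.6
    pair_tab: np.ndarray = field(default_factory=pair_table, repr=False)
    stack_tab: np.ndarray = field(default_factory=stack_table, repr=False)

    def params_array(self) -> np.ndarray:
        """Scalar parameters packed for the numba kernels."""
        return np.array(
            [
                self.kT,
                self.hairpin_a,
                self.loop_log,
                self.bulge_a,
                self.interior_a,
                self.ml_a,
                self.ml_b,
                self.ml_c,
                float(self.maxloop),
            ]
        )

    # -- closed-form loop energies (shared definition for DP and oracle) ----

    def hairpin_energy(self, size: int) -> float:
        if size < MIN_HAIRPIN:
            return math.inf
        if size == MIN_HAIRPIN:
            return self.hairpin_a
        return self.hairpin_a + self.loop_log * math.log(size / MIN_HAIRPIN)

    def interior_energy(self, l1: int, l2: int, pt_out: int, pt_in: int) -> float:
        """Energy of the loop between an outer and inner pair with l1/l2
        unpaired on the 5'/3' sides (l1 == l2 == 0 is a stack)."""
        total = l1 + l2
        if total == 0:
            return float(self.stack_tab[pt_out, pt_in])
        if total > self.maxloop:
            return math.inf
        if l1 == 0 or l2 == 0:
            return self.bulge_a + self.loop_log * math.log(total)
        return self.interior_a + self.loop_log * math.log(total)

    def shape_pseudo_energy(
        self, reactivity: np.ndarray | None, mask: np.ndarray | None, n: int
    ) -> np.ndarray:
        """Per-nucleotide pairing pseudo-energy from SHAPE reactivity."""
        pe = np.zeros(n)
        if reactivity is None:
            return pe
        r = np.asarray(reactivity, dtype=float)
        ok = np.isfinite(r)
        if mask is not None:
            ok &= ~np.asarray(mask, dtype=bool)
        pe[ok] = self.shape_m * np.log(np.clip(r[ok], 0.0, None) + 1.0) + self.shape_b
        return pe


DEFAULT_MODEL = EnergyModel()


def structure_energy(
    codes: np.ndarray,
    pairs,
    model: EnergyModel = DEFAULT_MODEL,
    pe: np.ndarray | None = None,
) -> float:
    """Free energy of a nested structure by direct loop decomposition.

    Returns ``inf`` for structures the model forbids (non-pairable bases,
    hairpins under the minimum loop, interior loops over ``maxloop``).
    Used as the independent scoring path for the enumeration oracle.
    """
    n = len(codes)
    partner = np.full(n, -1, dtype=int)
    for i, j in pairs:
        partner[i], partner[j] = j, i
    total = 0.0
    for i, j in pairs:
        pt = model.pair_tab[codes[i], codes[j]]
        if pt < 0 or j - i <= MIN_HAIRPIN:
            return math.inf
        if pe is not None:
            total += pe[i] + pe[j]
        children = []
        unpaired = 0
        k = i + 1
        while k < j:
            if partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        if not children:
            total += model.hairpin_energy(j - i - 1)
        elif len(children) == 1:
            (k, l) = children[0]
            pt_in = model.pair_tab[codes[k], codes[l]]
            total += model.interior_energy(k - i - 1, j - l - 1, pt, pt_in)
        else:
            total += model.ml_a + model.ml_b * (len(children) + 1) + model.ml_c * unpaired
        if not math.isfinite(total):
            return math.inf
    return total


def pairs_to_dotbracket(n: int, pairs) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db)


def dotbracket_to_pairs(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs = []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)
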