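"""Exhaustive-enumeration reference for short sequences.

Enumerates every nested structure (minimum hairpin loop of 3, optional
maximum pairing distance), scores each with
:func:`splicefold.fold.energy.structure_energy`, and derives the exact
minimum free energy, Boltzmann pair frequencies and ensemble diversity.
Feasible up to roughly 18 nt; the dynamic-programming engine is validated
against it.
"""

from __future__ import annotations

import math

import numpy as np

from .energy import DEFAULT_MODEL, MIN_HAIRPIN, EnergyModel, structure_energy


def enumerate_structures(codes: np.ndarray, model: EnergyModel = DEFAULT_MODEL,
                         max_dist: int | None = None) -> list[tuple[tuple[int, int], ...]]:
    """All nested structures over ``codes`` as tuples of (i, j) pairs."""
    n = len(codes)
    pair_tab = model.pair_tab
    memo: dict[tuple[int, int], list] = {}

    def rec(i: int, j: int):
        if (i, j) in memo:
            return memo[(i, j)]
        if j - i < MIN_HAIRPIN + 1:
            memo[(i, j)] = [()]
            return memo[(i, j)]
        out = list(rec(i + 1, j))  # i unpaired
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if max_dist is not None and k - i > max_dist:
                break
            if pair_tab[codes[i], codes[k]] < 0:
                continue
            for inner in rec(i + 1, k - 1):
                for rest in rec(k + 1, j):
                    out.append(((i, k),) + inner + rest)
        memo[(i, j)] = out
        return out

    return rec(0, n - 1)


def boltzmann_stats(codes: np.ndarray, model: EnergyModel = DEFAULT_MODEL,
                    pe: np.ndarray | None = None, max_dist: int | None = None):
    """Exact ensemble statistics by enumeration.

    Returns ``(mfe, pair_prob, unpaired_prob, ensemble_diversity)`` where
    ``pair_prob`` is the n x n Boltzmann-weighted pair frequency matrix.
    """
    n = len(codes)
    structures = enumerate_structures(codes, model, max_dist)
    energies = np.array([structure_energy(codes, s, model, pe) for s in structures])
    finite = np.isfinite(energies)
    energies = energies[finite]
    structures = [s for s, ok in zip(structures, finite) if ok]
    mfe = float(energies.min()) if len(energies) else 0.0
    weights = np.exp(-(energies - mfe) / model.kT)
    z = weights.sum()
    p = np.zeros((n, n))
    for s, w in zip(structures, weights):
        for (i, j) in s:
            p[i, j] += w
    p /= z
    q = 1.0 - (p + p.T).sum(axis=1)
    ed = float(np.sum(np.triu(p) * (1.0 - np.triu(p))))
    return mfe if len(energies) else 0.0, p, q, ed


def mfe_by_enumeration(codes: np.ndarray, model: EnergyModel = DEFAULT_MODEL,
                       pe: np.ndarray | None = None, max_dist: int | None = None) -> float:
    best = 0.0
    for s in enumerate_structures(codes, model, max_dist):
        e = structure_energy(codes, s, model, pe)
        if e < best:
            best = e
    return best if math.isfinite(best) else 0.0
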