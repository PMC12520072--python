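"""Public folding interface: MFE structures, pair probabilities under
pairing-distance constraints, per-base accessibility and ensemble diversity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .energy import DEFAULT_MODEL, EnergyModel, encode, pairs_to_dotbracket


def _reactivity_arrays(reactivity, n):
    """Accept None, a plain array (NaN = no data) or anything exposing
    ``values``/``mask`` attributes (e.g. a ReactivityProfile)."""
    if reactivity is None:
        return None, None
    if hasattr(reactivity, "values") and hasattr(reactivity, "mask"):
        vals = np.asarray(reactivity.values, dtype=float)
        mask = np.asarray(reactivity.mask, dtype=bool)
    else:
        vals = np.asarray(reactivity, dtype=float)
        mask = ~np.isfinite(vals)
    if len(vals) != n:
        raise ValueError(f"reactivity length {len(vals)} != sequence length {n}")
    return vals, mask


def _prepare(seq, reactivity, model):
    codes = encode(seq).astype(np.int64)
    n = len(codes)
    vals, mask = _reactivity_arrays(reactivity, n)
    pe = model.shape_pseudo_energy(vals, mask, n)
    return codes, pe


@dataclass
class SecondaryStructure:
    """A nested secondary structure with its free energy (kcal/mol)."""

    length: int
    pairs: list[tuple[int, int]]
    energy: float

    @property
    def dotbracket(self) -> str:
        return pairs_to_dotbracket(self.length, self.pairs)

    @property
    def partner(self) -> np.ndarray:
        part = np.full(self.length, -1, dtype=int)
        for i, j in self.pairs:
            part[i], part[j] = j, i
        return part


@dataclass
class PairProbabilityMatrix:
    """Base-pair probabilities p_ij (upper triangular) from the partition
    function, with the pairing-distance constraint that produced them."""

    p: np.ndarray
    max_dist: int | None = None

    @property
    def unpaired(self) -> np.ndarray:
        """q_i = 1 - sum_j p_ij."""
        return 1.0 - (self.p + self.p.T).sum(axis=1)

    @property
    def ensemble_diversity(self) -> float:
        up = np.triu(self.p)
        return float(np.sum(up * (1.0 - up)))


def mfe_fold(seq: str, reactivity=None, max_dist: int | None = None,
             model: EnergyModel = DEFAULT_MODEL) -> SecondaryStructure:
    """Minimum free energy structure, optionally SHAPE-directed.

    ``reactivity`` may be a per-nucleotide array (NaN where there is no
    data) or a ReactivityProfile; pseudo-energies follow the Deigan form.
    ``max_dist`` caps the pairing span j - i.  Sequences shorter than 5 nt
    return the open chain at zero energy.
    """
    n = len(seq)
    if n < 5:
        return SecondaryStructure(n, [], 0.0)
    codes, pe = _prepare(seq, reactivity, model)
    md = 0 if max_dist is None else int(max_dist)
    V, WM, W = _kernels.mfe_fill(codes, pe, model.pair_tab, model.stack_tab,
                                 model.params_array(), md)
    partner = _kernels.mfe_traceback(codes, pe, model.pair_tab, model.stack_tab,
                                     model.params_array(), md, V, WM, W)
    pairs = [(int(i), int(partner[i])) for i in range(n) if partner[i] > i]
    return SecondaryStructure(n, pairs, float(W[n]))


def pair_probabilities(seq: str, reactivity=None, max_dist: int | None = None,
                       model: EnergyModel = DEFAULT_MODEL) -> PairProbabilityMatrix:
    """McCaskill base-pair probabilities over the same energy model."""
    n = len(seq)
    if n < 5:
        return PairProbabilityMatrix(np.zeros((n, n)), max_dist)
    codes, pe = _prepare(seq, reactivity, model)
    md = 0 if max_dist is None else int(max_dist)
    params = model.params_array()
    sc = 1.0
    if n > 60:
        # rescale so the scaled partition function stays within float64
        _, _, W = _kernels.mfe_fill(codes, pe, model.pair_tab, model.stack_tab,
                                    params, md)
        mfe = min(0.0, float(W[n]))
        sc = float(np.exp(1.1 * mfe / (n * model.kT)))
    QB, QM, QM1, Qp, Qs = _kernels.partition_fill(
        codes, pe, model.pair_tab, model.stack_tab, params, md, sc)
    P = _kernels.pair_probabilities_fill(
        codes, pe, model.pair_tab, model.stack_tab, params, md, sc,
        QB, QM, QM1, Qp, Qs)
    return PairProbabilityMatrix(P, max_dist)


def partition_accessibility(seq: str, reactivity=None,
                            max_dist_range=range(27, 35),
                            model: EnergyModel = DEFAULT_MODEL) -> np.ndarray:
    """Per-base unpaired probability averaged over a window of pairing-
    distance constraints (default spans 27 through 34)."""
    dists = list(max_dist_range)
    if not dists:
        raise ValueError("max_dist_range must be nonempty")
    acc = np.zeros(len(seq))
    for d in dists:
        acc += pair_probabilities(seq, reactivity, d, model).unpaired
    return acc / len(dists)


def ensemble_diversity(seq: str, reactivity=None, max_dist: int | None = None,
                       model: EnergyModel = DEFAULT_MODEL) -> float:
    """Sum of p_ij (1 - p_ij) over all pairs."""
    return pair_probabilities(seq, reactivity, max_dist, model).ensemble_diversity


def count_paired_bases(structure: SecondaryStructure, start: int, end: int) -> float:
    """Hairpin-content metric: paired bases within [start, end] (inclusive
    indices into the folded sequence) divided by two.

    A base whose partner lies outside the region still counts as paired,
    so a pair straddling the boundary contributes 0.5.
    """
    if start < 0 or end >= structure.length or start > end:
        raise ValueError("region outside structure coordinates")
    n_paired = 0
    for i, j in structure.pairs:
        if start <= i <= end:
            n_paired += 1
        if start <= j <= end:
            n_paired += 1
    return n_paired / 2.0
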