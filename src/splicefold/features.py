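"""Sequence-level features of 3' splice sites.

Upstream GC content, cryptic-to-canonical distance, per-position nucleotide
probabilities (logo-ready), and a pluggable 3' splice-site strength score
over the MaxEnt window (last 20 intronic + first 3 exonic bases).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coords import rel_positions, rel_to_index

_BASES = "ACGU"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGUTN", "UGCAAN")

SS_WINDOW_POSITIONS = list(range(-20, 0)) + [1, 2, 3]  # 23-mer


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SpliceRegion:
    """A sequence window anchored at one 3' splice site, on the sense strand.

    ``site_index`` is the string index of the acceptor G, so
    ``sequence[site_index-1:site_index+1] == "AG"`` and the first exonic
    base sits at ``site_index + 1``.  ``partner_offset`` is the signed
    distance (in nt, partner G index minus this G index) to the paired
    cryptic/canonical site; None for control junctions without one.
    """

    junction_id: str
    klass: str  # MT | WT | control
    site_role: str  # cryptic | canonical
    sequence: str
    site_index: int
    intron_length: int
    partner_offset: int | None = None

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("T", "U")
        if self.sequence[self.site_index - 1 : self.site_index + 1] != "AG":
            raise ValueError(
                f"{self.junction_id}: acceptor dinucleotide at site_index is not AG")

    def rel_index(self, pos: int) -> int:
        return rel_to_index(self.site_index, pos)

    def window(self, lo: int, hi: int) -> str:
        """Sequence between site-relative positions lo..hi inclusive."""
        a = self.rel_index(lo)
        b = self.rel_index(hi)
        if a < 0 or b >= len(self.sequence):
            raise ValueError(f"{self.junction_id}: window {lo}..{hi} outside region")
        return self.sequence[a : b + 1]

    def reanchored(self) -> "SpliceRegion":
        """The same window anchored at the partner site (cryptic <-> canonical)."""
        if self.partner_offset is None:
            raise ValueError(f"{self.junction_id}: no partner site")
        return SpliceRegion(
            junction_id=self.junction_id,
            klass=self.klass,
            site_role="canonical" if self.site_role == "cryptic" else "cryptic",
            sequence=self.sequence,
            site_index=self.site_index + self.partner_offset,
            intron_length=self.intron_length,
            partner_offset=-self.partner_offset,
        )


@dataclass
class CompositionProfile:
    """Per-position nucleotide probabilities across a set of regions."""

    positions: list
    probs: np.ndarray  # (len(positions), 4), columns A C G U
    n_sequences: int

    def __post_init__(self):
        if self.n_sequences <= 0:
            raise ValueError("empty region set")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums[sums > 0], 1.0, atol=1e-9):
            raise ValueError("per-position probabilities must sum to 1")

    def prob(self, base: str) -> np.ndarray:
        return self.probs[:, _BASE_IDX[base.upper().replace("T", "U")]]


@dataclass
class SpliceSiteScore:
    score: float
    window: str
    units: str = "bits"


def gc_content_upstream(region: SpliceRegion, window: int = 150) -> float:
    """(G+C) fraction over the ``window`` nt upstream of the acceptor
    (positions -window..-1); ambiguous bases are excluded entirely."""
    seq = region.window(-window, -1)
    gc = sum(1 for ch in seq if ch in "GC")
    known = sum(1 for ch in seq if ch in "ACGU")
    if known == 0:
        raise ValueError(f"{region.junction_id}: no unambiguous bases upstream")
    return gc / known


def at_content_upstream(region: SpliceRegion, window: int = 150) -> float:
    seq = region.window(-window, -1)
    au = sum(1 for ch in seq if ch in "AU")
    known = sum(1 for ch in seq if ch in "ACGU")
    return au / known


def cryptic_canonical_distance(region: SpliceRegion) -> tuple[int, str]:
    """Absolute distance between the cryptic and canonical acceptor, with
    the cryptic site's side relative to the canonical ('upstream' means 5'
    of the canonical acceptor in transcript orientation)."""
    if region.partner_offset is None:
        raise ValueError(f"{region.junction_id}: control region has no cryptic site")
    off = region.partner_offset
    if region.site_role == "canonical":
        side = "upstream" if off < 0 else "downstream"  # partner is the cryptic site
    else:
        side = "upstream" if off > 0 else "downstream"  # this site is the cryptic one
    return abs(off), side


def positional_nucleotide_probability(regions, flank: int) -> CompositionProfile:
    """Per-position base probabilities over -flank..+flank (no position 0)."""
    if not regions:
        raise ValueError("empty region set")
    positions = rel_positions(flank)
    counts = np.zeros((len(positions), 4))
    known = np.zeros(len(positions))
    for reg in regions:
        seq = reg.window(-flank, flank)
        for row, ch in enumerate(seq):
            k = _BASE_IDX.get(ch)
            if k is not None:
                counts[row, k] += 1
                known[row] += 1
    probs = np.zeros_like(counts)
    ok = known > 0
    probs[ok] = counts[ok] / known[ok, None]
    return CompositionProfile(positions, probs, len(regions))


def extract_3ss_window(region: SpliceRegion) -> str:
    """The 23-mer scored by 3'SS strength models: positions -20..-1, +1..+3."""
    return region.window(-20, 3)


class SpliceSiteModel:
    """First-order (dinucleotide-dependent) log-odds model of 3'SS strength.

    Trained on 23-mer windows of annotated acceptors against a background
    model (uniform by default, or trained on supplied background windows).
    The score is additive over positions in log2 units; ambiguous bases
    contribute zero, and a position whose predecessor is ambiguous falls
    back to the positional marginal.  Genuine MaxEntScan-style scorers can
    replace this class; only ``score_window`` is required.
    """

    WINDOW = 23

    def __init__(self, pseudocount: float = 0.5):
        self.pseudocount = pseudocount
        self.marginal: np.ndarray | None = None  # (23, 4)
        self.conditional: np.ndarray | None = None  # (23, 4, 4), [pos, prev, base]
        self.bg_marginal = np.full((self.WINDOW, 4), 0.25)
        self.bg_conditional = np.full((self.WINDOW, 4, 4), 0.25)

    @staticmethod
    def _tabulate(windows, w, pc):
        marg = np.full((w, 4), pc)
        cond = np.full((w, 4, 4), pc)
        for win in windows:
            win = win.upper().replace("T", "U")
            if len(win) != w:
                raise ValueError(f"training window must be {w} nt, got {len(win)}")
            prev = None
            for i, ch in enumerate(win):
                k = _BASE_IDX.get(ch)
                if k is not None:
                    marg[i, k] += 1
                    if prev is not None:
                        cond[i, prev, k] += 1
                prev = k
        marg /= marg.sum(axis=1, keepdims=True)
        cond /= cond.sum(axis=2, keepdims=True)
        return marg, cond

    def fit(self, windows, background_windows=None) -> "SpliceSiteModel":
        if not windows:
            raise ValueError("no training windows")
        self.marginal, self.conditional = self._tabulate(windows, self.WINDOW, self.pseudocount)
        if background_windows:
            self.bg_marginal, self.bg_conditional = self._tabulate(
                background_windows, self.WINDOW, self.pseudocount)
        return self

    def position_scores(self, window: str) -> np.ndarray:
        """Per-position log2-odds contributions (sums to the total score)."""
        if self.marginal is None:
            raise ValueError("model is not trained")
        window = window.upper().replace("T", "U")
        if len(window) != self.WINDOW:
            raise ValueError(f"window must be {self.WINDOW} nt, got {len(window)}")
        out = np.zeros(self.WINDOW)
        prev = None
        for i, ch in enumerate(window):
            k = _BASE_IDX.get(ch)
            if k is None:
                prev = None
                continue
            if i == 0 or prev is None:
                num, den = self.marginal[i, k], self.bg_marginal[i, k]
            else:
                num, den = self.conditional[i, prev, k], self.bg_conditional[i, prev, k]
            out[i] = math.log2(num / den)
            prev = k
        return out

    def score_window(self, window: str) -> SpliceSiteScore:
        return SpliceSiteScore(float(self.position_scores(window).sum()), window)


def score_3ss(window: str, model: SpliceSiteModel) -> SpliceSiteScore:
    """Log-odds strength of a 23-mer acceptor window under a trained model."""
    return model.score_window(window)
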