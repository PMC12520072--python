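"""SHAPE-MaP reactivity computation and NAG-motif statistics.

Starts from per-nucleotide mutation counts in the modified (5NIA) and
untreated (DMSO) channels: raw reactivity is the mutation-rate difference,
with Poisson standard errors combined in quadrature.  Profiles are
normalized with the community-standard box-plot rule and clamped to the
0-4 range, replicates are merged after a correlation check, and the
accessibility pattern at the NAG acceptor motif (low N, high A) is
summarized per junction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .coords import rel_to_index


@dataclass
class MutationCountProfile:
    """Per-nucleotide mutation counts around one splice site.

    Positions are site-relative (-3 = N, -2 = A, -1 = G, +1 = first exonic
    base; no position 0)."""

    junction_id: str
    positions: np.ndarray
    mod_mut: np.ndarray
    mod_depth: np.ndarray
    unt_mut: np.ndarray
    unt_depth: np.ndarray
    replicate: int = 0

    def __post_init__(self):
        for name in ("positions", "mod_mut", "mod_depth", "unt_mut", "unt_depth"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if np.any(self.mod_mut > self.mod_depth) or np.any(self.unt_mut > self.unt_depth):
            raise ValueError(f"{self.junction_id}: mutation count exceeds depth")
        if np.any(self.mod_mut < 0) or np.any(self.unt_mut < 0):
            raise ValueError(f"{self.junction_id}: negative counts")


@dataclass
class ReactivityProfile:
    """Per-nucleotide reactivity with standard errors and a no-data mask.

    ``mask`` is True where there is no usable measurement.  After
    normalization all unmasked values lie in [0, 4] and ``scale`` records
    the divisor applied."""

    junction_id: str
    positions: np.ndarray
    values: np.ndarray
    se: np.ndarray
    mask: np.ndarray
    depth: np.ndarray | None = None
    normalized: bool = False
    scale: float | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions)
        self.values = np.asarray(self.values, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=float)

    def value_at(self, pos: int) -> float:
        idx = np.nonzero(self.positions == pos)[0]
        if len(idx) == 0:
            raise KeyError(f"{self.junction_id}: position {pos} not covered")
        if self.mask[idx[0]]:
            raise ValueError(f"{self.junction_id}: position {pos} has no data")
        return float(self.values[idx[0]])

    @property
    def unmasked_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def values_with_nan(self) -> np.ndarray:
        out = self.values.copy()
        out[self.mask] = np.nan
        return out


@dataclass
class NagStats:
    """Reactivity pattern at the NAG acceptor motif."""

    junction_id: str
    r_n: float
    r_a: float
    r_g: float
    region_median: float
    magnitude: float  # r_a - r_n by default (ratio available)
    n_region: int


def compute_raw_reactivity(profile: MutationCountProfile,
                           min_depth: int = 1000) -> ReactivityProfile:
    """Raw reactivity = modified mutation rate - untreated mutation rate.

    Standard error combines the Poisson errors of both channels in
    quadrature; positions where either channel is below ``min_depth`` are
    masked."""
    mod_d = profile.mod_depth.astype(float)
    unt_d = profile.unt_depth.astype(float)
    mask = (mod_d < min_depth) | (unt_d < min_depth)
    if mask.all():
        raise ValueError(f"{profile.junction_id}: all positions below min_depth")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = profile.mod_mut / mod_d - profile.unt_mut / unt_d
        se = np.sqrt(profile.mod_mut / mod_d**2 + profile.unt_mut / unt_d**2)
    raw[mask] = np.nan
    se[mask] = np.nan
    depth = np.minimum(mod_d, unt_d)
    return ReactivityProfile(profile.junction_id, profile.positions.copy(),
                             raw, se, mask, depth=depth)


def normalize_reactivity(raw: ReactivityProfile, max_value: float = 4.0) -> ReactivityProfile:
    """Box-plot normalization, then clamping to [0, ``max_value``].

    Outliers above Q3 + 1.5 IQR are excluded (or the top 10%, whichever
    removes fewer values); the remaining values are divided by the mean of
    their top decile; negatives clamp to 0 and values above ``max_value``
    clamp down.  The divisor is recorded as ``scale``."""
    vals = raw.unmasked_values
    if len(vals) < 20:
        raise ValueError(f"{raw.junction_id}: need >= 20 unmasked positions")
    order = np.sort(vals)
    q1, q3 = np.percentile(vals, [25, 75])
    n_iqr = int(np.sum(vals > q3 + 1.5 * (q3 - q1)))
    n_top = max(1, int(round(0.1 * len(vals))))
    n_excl = min(n_iqr, n_top)
    kept = order[: len(order) - n_excl] if n_excl else order
    k = max(1, int(round(0.1 * len(kept))))
    normalizer = float(kept[-k:].mean())
    if normalizer <= 0:
        raise ValueError(f"{raw.junction_id}: degenerate profile, normalizer <= 0")
    values = np.clip(raw.values / normalizer, 0.0, max_value)
    values[raw.mask] = np.nan
    return ReactivityProfile(raw.junction_id, raw.positions.copy(), values,
                             raw.se / normalizer, raw.mask.copy(),
                             depth=None if raw.depth is None else raw.depth.copy(),
                             normalized=True, scale=normalizer)


def merge_replicates(profiles, min_rho: float = 0.7) -> ReactivityProfile:
    """Merge raw technical replicates, then normalize.

    Replicates whose pairwise Spearman correlation (on co-measured
    positions) all reach ``min_rho`` are combined by a depth-weighted
    average of raw rates; otherwise the deepest replicate is kept and a
    warning emitted."""
    if not profiles:
        raise ValueError("no replicates")
    if len(profiles) == 1:
        return normalize_reactivity(profiles[0])
    base = profiles[0].positions
    for p in profiles[1:]:
        if not np.array_equal(p.positions, base):
            raise ValueError("replicates cover different positions")
    consistent = True
    for a in range(len(profiles)):
        for b in range(a + 1, len(profiles)):
            ok = ~(profiles[a].mask | profiles[b].mask)
            if ok.sum() < 10:
                consistent = False
                break
            rho = stats.spearmanr(profiles[a].values[ok], profiles[b].values[ok]).statistic
            if not np.isfinite(rho) or rho < min_rho:
                consistent = False
                break
        if not consistent:
            break
    if not consistent:
        warnings.warn("replicates poorly correlated; keeping the deepest one")
        depths = [np.nansum(p.depth) if p.depth is not None else 0.0 for p in profiles]
        return normalize_reactivity(profiles[int(np.argmax(depths))])
    n = len(base)
    wsum = np.zeros(n)
    vsum = np.zeros(n)
    sesq = np.zeros(n)
    for p in profiles:
        w = p.depth if p.depth is not None else np.ones(n)
        ok = ~p.mask
        wsum[ok] += w[ok]
        vsum[ok] += w[ok] * p.values[ok]
        sesq[ok] += (w[ok] * p.se[ok]) ** 2
    mask = wsum <= 0
    values = np.full(n, np.nan)
    se = np.full(n, np.nan)
    values[~mask] = vsum[~mask] / wsum[~mask]
    se[~mask] = np.sqrt(sesq[~mask]) / wsum[~mask]
    merged = ReactivityProfile(profiles[0].junction_id, base.copy(), values, se,
                               mask, depth=wsum)
    return normalize_reactivity(merged)


def nag_motif_stats(profile: ReactivityProfile, flank: int = 150,
                    magnitude: str = "difference") -> NagStats:
    """Reactivities at N (-3), A (-2), G (-1) and the median over the
    +/- flank reference window (motif positions included).

    ``magnitude`` is the A-vs-N contrast: 'difference' (r_A - r_N) or
    'ratio' (r_A / r_N)."""
    r_n = profile.value_at(-3)
    r_a = profile.value_at(-2)
    r_g = profile.value_at(-1)
    span = (profile.positions >= -flank) & (profile.positions <= flank) & ~profile.mask
    n_region = int(span.sum())
    if n_region == 0:
        raise ValueError(f"{profile.junction_id}: no data in the reference window")
    med = float(np.median(profile.values[span]))
    if magnitude == "difference":
        mag = r_a - r_n
    elif magnitude == "ratio":
        mag = r_a / r_n if r_n != 0 else float("inf")
    else:
        raise ValueError("magnitude must be 'difference' or 'ratio'")
    return NagStats(profile.junction_id, r_n, r_a, r_g, med, mag, n_region)


def find_control_nags(sequence: str, site_index: int, min_dist: int = 10,
                      other_sites=()) -> list[int]:
    """Array indices of the G of AG dinucleotides at least ``min_dist`` nt
    from the acceptor (and from any other annotated site)."""
    seq = sequence.upper().replace("T", "U")
    keep = []
    anchors = [site_index, *other_sites]
    for t in range(1, len(seq)):
        if seq[t] == "G" and seq[t - 1] == "A":
            if all(abs(t - a) >= min_dist for a in anchors):
                keep.append(t)
    return keep


def normalize_to_control_nags(profile: ReactivityProfile, control_indices,
                              halfwidth: int = 10):
    """Splice-site reactivity relative to non-splice-site AG motifs.

    ``control_indices`` are array indices (into ``profile.values``) of the
    G of control AG motifs.  The mean reactivity of the control motifs is
    computed per motif offset (-halfwidth..+halfwidth around the G, in the
    same no-zero convention as splice-site positions), and the splice-site
    profile is divided by the control mean at the matching offset.

    Returns ``(offsets, normalized, control_mean)``; offsets without
    control coverage or with zero control mean are NaN."""
    if len(control_indices) == 0:
        raise ValueError(f"{profile.junction_id}: no control NAG motifs found")
    offsets = list(range(-halfwidth, 0)) + list(range(1, halfwidth + 1))
    n = len(profile.values)
    site_arr_index = int(np.nonzero(profile.positions == -1)[0][0])
    ctrl_sum = np.zeros(len(offsets))
    ctrl_n = np.zeros(len(offsets))
    for g_idx in control_indices:
        for row, off in enumerate(offsets):
            t = rel_to_index(int(g_idx), off)
            if 0 <= t < n and not profile.mask[t]:
                ctrl_sum[row] += profile.values[t]
                ctrl_n[row] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ctrl_mean = np.where(ctrl_n > 0, ctrl_sum / np.maximum(ctrl_n, 1), np.nan)
    normalized = np.full(len(offsets), np.nan)
    for row, off in enumerate(offsets):
        t = rel_to_index(site_arr_index, off)
        if 0 <= t < n and not profile.mask[t] and ctrl_mean[row] and np.isfinite(ctrl_mean[row]):
            normalized[row] = profile.values[t] / ctrl_mean[row]
    return np.array(offsets), normalized, ctrl_mean
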