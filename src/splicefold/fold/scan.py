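"""Scanning-window structure statistics.

A ScanFold-style analysis: slide a fixed window along the sequence, fold
each window (SHAPE-directed when reactivities are supplied), compare its
MFE against dinucleotide-shuffled versions of the same window to obtain a
thermodynamic z-score, and compute the window's ensemble diversity from
the partition function.  Shuffled windows are folded without reactivity
restraints, because shuffling destroys the sequence-reactivity register;
the z-score is meant to measure sequence-encoded stability.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .api import mfe_fold, pair_probabilities, _reactivity_arrays
from .energy import DEFAULT_MODEL, EnergyModel


def dinucleotide_shuffle(seq: str, seed=None, rng: np.random.Generator | None = None) -> str:
    """Altschul-Erikson shuffle: a uniform random sequence with exactly the
    original dinucleotide (and hence mononucleotide) counts.

    Implemented as a random Eulerian path on the dinucleotide transition
    multigraph: each vertex other than the terminal character gets a random
    'last' out-edge, the last-edge graph is checked for connectivity to the
    terminal vertex, remaining edges are permuted, and the path is walked.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if len(seq) < 2:
        return seq
    chars = list(seq)
    start, end = chars[0], chars[-1]
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(chars, chars[1:]):
        edges[a].append(b)
    verts = sorted(edges)
    if all(len(set(edges[v])) == 1 and edges[v][0] == v for v in verts):
        return seq  # homopolymer (or single repeated transition)
    for _ in range(10000):
        last = {}
        for v in verts:
            if v == end:
                continue
            last[v] = edges[v][rng.integers(len(edges[v]))]
        # every vertex with out-edges must reach `end` through last edges
        ok = True
        for v in verts:
            if v == end:
                continue
            seen = set()
            cur = v
            while cur != end:
                if cur in seen or cur not in last:
                    ok = False
                    break
                seen.add(cur)
                cur = last[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - effectively unreachable
        return seq
    order: dict[str, list[str]] = {}
    for v in verts:
        rest = list(edges[v])
        if v != end:
            rest.remove(last[v])
        idx = rng.permutation(len(rest))
        shuffled = [rest[k] for k in idx]
        if v != end:
            shuffled.append(last[v])
        order[v] = shuffled
    out = [start]
    pos = defaultdict(int)
    cur = start
    for _ in range(len(chars) - 1):
        nxt = order[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


@dataclass
class ScanWindowResult:
    """Structure statistics of one scanning window."""

    start: int
    end: int  # exclusive
    mfe: float
    shuffled_mean: float
    shuffled_sd: float
    zscore: float  # NaN when the shuffle distribution is degenerate
    ensemble_diversity: float

    @property
    def z_defined(self) -> bool:
        return bool(np.isfinite(self.zscore))


def scan_zscore_ed(seq: str, reactivity=None, window: int = 200, step: int = 20,
                   n_shuffles: int = 50, seed=None,
                   model: EnergyModel = DEFAULT_MODEL):
    """Windowed z-score / ensemble-diversity scan.

    Returns ``(results, per_base_z, per_base_ed)`` where the per-base
    arrays are means over all windows covering each base (NaN where no
    covering window has a defined value).
    """
    n = len(seq)
    if n < window:
        raise ValueError(f"sequence ({n} nt) shorter than window ({window} nt)")
    vals, mask = _reactivity_arrays(reactivity, n)
    rng = np.random.default_rng(seed)
    results: list[ScanWindowResult] = []
    z_sum = np.zeros(n)
    z_n = np.zeros(n)
    ed_sum = np.zeros(n)
    ed_n = np.zeros(n)
    for start in range(0, n - window + 1, step):
        stop = start + window
        sub = seq[start:stop]
        sub_react = None
        if vals is not None:
            sub_react = vals[start:stop].copy()
            sub_react[mask[start:stop]] = np.nan
        native = mfe_fold(sub, sub_react, model=model)
        shuffled = np.empty(n_shuffles)
        for k in range(n_shuffles):
            shuffled[k] = mfe_fold(dinucleotide_shuffle(sub, rng=rng), model=model).energy
        mu = float(shuffled.mean())
        sd = float(shuffled.std(ddof=1)) if n_shuffles > 1 else 0.0
        z = (native.energy - mu) / sd if sd > 0 else float("nan")
        ed = pair_probabilities(sub, sub_react, model=model).ensemble_diversity
        results.append(ScanWindowResult(start, stop, native.energy, mu, sd, z, ed))
        if np.isfinite(z):
            z_sum[start:stop] += z
            z_n[start:stop] += 1
        ed_sum[start:stop] += ed
        ed_n[start:stop] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        per_base_z = np.where(z_n > 0, z_sum / z_n, np.nan)
        per_base_ed = np.where(ed_n > 0, ed_sum / ed_n, np.nan)
    return results, per_base_z, per_base_ed
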