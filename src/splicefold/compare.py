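"""Group-level aggregation and statistical comparisons.

Per-position aggregates across junction classes, the bootstrap
subsampling comparison used when one group is much larger than the other
(the resistant pool is subsampled to the sensitive set's size, 1000
times), and Wilcoxon rank tests with Benjamini-Hochberg adjustment for
multi-group families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupProfile:
    """Per-position aggregate of a per-base metric across junctions."""

    label: str
    positions: np.ndarray
    mean: np.ndarray
    median: np.ndarray
    se: np.ndarray  # sd/sqrt(n); NaN where n < 2
    n: np.ndarray


@dataclass
class ComparisonReport:
    metric: str
    groups: tuple
    statistic: float
    pvalue: float
    adjusted_pvalue: float | None = None
    test: str = ""
    null_mean: float | None = None
    null_ci: tuple | None = None
    n_boot: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "groups": list(self.groups),
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "adjusted_pvalue": self.adjusted_pvalue,
            "test": self.test,
            "null_mean": self.null_mean,
            "null_ci": list(self.null_ci) if self.null_ci else None,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def aggregate_per_base(per_junction, label: str, positions=None) -> GroupProfile:
    """Aggregate aligned per-base arrays (NaN = missing) into a group profile.

    ``per_junction`` is a list of equal-length arrays (or objects exposing
    ``values_with_nan()`` / ``positions`` like a ReactivityProfile)."""
    if not per_junction:
        raise ValueError(f"empty class: {label}")
    rows = []
    for item in per_junction:
        if hasattr(item, "values_with_nan"):
            if positions is None:
                positions = np.asarray(item.positions)
            rows.append(item.values_with_nan())
        else:
            rows.append(np.asarray(item, dtype=float))
    mat = np.vstack(rows)
    if positions is None:
        positions = np.arange(mat.shape[1])
    n = np.sum(np.isfinite(mat), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        median = np.nanmedian(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    se = np.where(n >= 2, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    mean[n == 0] = np.nan
    median[n == 0] = np.nan
    return GroupProfile(label, np.asarray(positions), mean, median, se, n)


def bootstrap_compare(values_small, values_large, stat=np.mean,
                      n_boot: int = 1000, seed=None, replace: bool = False,
                      metric: str = "", groups=("small", "large")) -> ComparisonReport:
    """Subsampling bootstrap: is stat(values_small) unusual against random
    same-size subsets of values_large?

    Each of ``n_boot`` resamples draws |values_small| elements from
    ``values_large`` (without replacement by default) and the two-sided
    empirical p compares the observed statistic's deviation from the null
    mean against the null deviations, with add-one smoothing."""
    small = np.asarray(values_small, dtype=float)
    large = np.asarray(values_large, dtype=float)
    if len(large) < len(small) and not replace:
        raise ValueError("values_large must be at least as large as values_small")
    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    for b in range(n_boot):
        null[b] = stat(rng.choice(large, size=len(small), replace=replace))
    observed = float(stat(small))
    mu = float(null.mean())
    p = (1 + int(np.sum(np.abs(null - mu) >= abs(observed - mu)))) / (1 + n_boot)
    lo, hi = np.percentile(null, [2.5, 97.5])
    return ComparisonReport(metric=metric, groups=tuple(groups), statistic=observed,
                            pvalue=float(p), test="bootstrap_subsample",
                            null_mean=mu, null_ci=(float(lo), float(hi)),
                            n_boot=n_boot, seed=seed)


def _wilcoxon_two(a, b, paired: bool, exact_max: int = 25):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied; p = 1")
        return 0.0, 1.0, "degenerate"
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal lengths")
        d = a - b
        exact_ok = len(d) <= exact_max and not np.any(d == 0) and len(np.unique(np.abs(d))) == len(d)
        method = "exact" if exact_ok else "approx"
        res = stats.wilcoxon(a, b, method=method, correction=(method == "approx"))
        return float(res.statistic), float(res.pvalue), f"wilcoxon_signed_rank_{method}"
    ties = len(np.unique(pooled)) < len(pooled)
    exact_ok = max(len(a), len(b)) <= exact_max and not ties
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue), f"wilcoxon_rank_sum_{method}"


def rank_compare(groups, paired: bool = False, labels=None, metric: str = ""):
    """Wilcoxon comparison of two or more groups.

    Two groups give a single report (signed-rank when paired, rank-sum
    otherwise; exact null up to n = 25 without ties, normal approximation
    with continuity correction beyond).  More than two groups give all
    pairwise tests with Benjamini-Hochberg adjustment."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if len(groups) == 2:
        s, p, test = _wilcoxon_two(groups[0], groups[1], paired)
        return ComparisonReport(metric=metric, groups=(labels[0], labels[1]),
                                statistic=s, pvalue=p, adjusted_pvalue=p, test=test)
    reports = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            s, p, test = _wilcoxon_two(groups[i], groups[j], paired)
            reports.append(ComparisonReport(metric=metric, groups=(labels[i], labels[j]),
                                            statistic=s, pvalue=p, test=test))
    adj = bh_adjust([r.pvalue for r in reports])
    for r, q in zip(reports, adj):
        r.adjusted_pvalue = float(q)
    return reports


def bh_adjust(pvalues):
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(pvalues, method="fdr_bh")[1]
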