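"""Classification of cryptic 3' splice sites by SF3B1 sensitivity.

SF3B1-sensitive (MT) sites are alternative-acceptor events that pass the
significance filters (FDR < 0.1, |dPSI| > 0.05) in two or more independent
mutant datasets.  SF3B1-resistant (WT) sites are novel-acceptor junctions
observed in wild-type samples that pass the junction-extraction filters
(anchor >= 8 nt, intron length in [50, 500000]) and show no significant
change in any mutant dataset.  An overlap permutation test quantifies how
unlikely the observed cross-dataset sharing is under random junction sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

Key = tuple  # (chrom, strand, cryptic acceptor coordinate)


@dataclass
class EventRecord:
    """One alternative-3'SS event in one dataset (rMATS-A3SS-like)."""

    dataset_id: str
    gene: str
    chrom: str
    strand: str
    donor_pos: int
    canonical_acceptor: int
    cryptic_acceptor: int
    psi_wt: float
    psi_mut: float
    pvalue: float
    fdr: float
    dpsi: float
    inc_wt: tuple = ()  # per-replicate inclusion counts, wild-type
    skip_wt: tuple = ()
    inc_mut: tuple = ()
    skip_mut: tuple = ()
    junction_id: str = ""

    def key(self) -> Key:
        return (self.chrom, self.strand, self.cryptic_acceptor)


@dataclass
class JunctionRecord:
    """A splice junction from alignment (regtools-style), intron given as a
    0-based half-open span."""

    chrom: str
    strand: str
    intron_start: int
    intron_end: int
    read_count: int
    min_anchor: int
    annotation: str = "novel_acceptor"  # annotated/novel_acceptor/novel_donor/novel_pair

    @property
    def intron_length(self) -> int:
        return self.intron_end - self.intron_start

    @property
    def donor(self) -> int:
        return self.intron_start if self.strand == "+" else self.intron_end

    @property
    def acceptor(self) -> int:
        return self.intron_end if self.strand == "+" else self.intron_start

    def key(self) -> Key:
        return (self.chrom, self.strand, self.acceptor)


@dataclass
class TranscriptModel:
    """Annotated donors and acceptors, keyed by (chrom, strand, coordinate)."""

    donors: set = field(default_factory=set)
    acceptors: set = field(default_factory=set)
    chroms: set = field(default_factory=set)

    def add_junction(self, chrom: str, strand: str, donor: int, acceptor: int) -> None:
        self.donors.add((chrom, strand, donor))
        self.acceptors.add((chrom, strand, acceptor))
        self.chroms.add(chrom)

    @classmethod
    def from_gff3(cls, path) -> "TranscriptModel":
        """Build from the exon features of a GFF3/GTF file: for '+' strand
        an exon end is a candidate donor and an exon start a candidate
        acceptor (reversed on '-')."""
        model = cls()
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 8 or f[2].lower() != "exon":
                    continue
                chrom, start, end, strand = f[0], int(f[3]) - 1, int(f[4]), f[6]
                model.chroms.add(chrom)
                if strand == "+":
                    model.donors.add((chrom, strand, end))
                    model.acceptors.add((chrom, strand, start))
                else:
                    model.donors.add((chrom, strand, start))
                    model.acceptors.add((chrom, strand, end))
        return model


@dataclass
class ClassifiedSets:
    """Outcome of the classification stage."""

    sensitive: dict  # key -> set of supporting dataset ids
    resistant: set
    controls: set = field(default_factory=set)

    def __post_init__(self):
        overlap = set(self.sensitive) & self.resistant
        if overlap:
            raise ValueError(f"sensitive and resistant sets overlap: {sorted(overlap)[:3]}")


def _valid(x) -> bool:
    return x is not None and not (isinstance(x, float) and math.isnan(x))


def filter_significant_events(events, fdr_max: float = 0.1,
                              dpsi_min: float = 0.05):
    """Events with fdr < fdr_max and |dpsi| > dpsi_min, order preserved.

    The dPSI filter is two-sided: cryptic acceptors both gained and lost in
    the mutant count as significant.  Events with missing fdr or dpsi are
    dropped with a warning.
    """
    if not (0 < fdr_max <= 1 and 0 < dpsi_min <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    kept = []
    n_missing = 0
    for ev in events:
        if not (_valid(ev.fdr) and _valid(ev.dpsi)):
            n_missing += 1
            continue
        if ev.fdr < fdr_max and abs(ev.dpsi) > dpsi_min:
            kept.append(ev)
    if n_missing:
        warnings.warn(f"dropped {n_missing} events with missing fdr/dpsi")
    return kept


def intersect_across_datasets(filtered_per_dataset, min_datasets: int = 2) -> dict:
    """Sensitive keys: cryptic acceptors significant in >= min_datasets
    datasets.  Returns key -> set of supporting dataset ids."""
    support: dict = {}
    for events in filtered_per_dataset:
        for ev in events:
            support.setdefault(ev.key(), set()).add(ev.dataset_id)
    if min_datasets > len(filtered_per_dataset):
        warnings.warn("min_datasets exceeds the number of datasets; empty result")
        return {}
    return {k: ds for k, ds in support.items() if len(ds) >= min_datasets}


def extract_resistant_c3ss(junctions, annotation: TranscriptModel, sensitive,
                           anchor_min: int = 8, intron_min: int = 50,
                           intron_max: int = 500000, read_min: int = 1,
                           exclude_keys=None) -> set:
    """Resistant cryptic acceptors from wild-type junction records.

    A junction qualifies when it is a novel acceptor sharing an annotated
    donor, passes the anchor/intron-size/read filters, and its key is
    neither in the sensitive set nor in ``exclude_keys`` (typically the
    union of all per-dataset significant keys, so "resistant" means no
    detected change anywhere).
    """
    sensitive_keys = set(sensitive)
    exclude = set(exclude_keys) if exclude_keys else set()
    out = set()
    n_unknown = 0
    for jr in junctions:
        if jr.chrom not in annotation.chroms:
            n_unknown += 1
            continue
        if jr.min_anchor < anchor_min:
            continue
        if not (intron_min <= jr.intron_length <= intron_max):
            continue
        if jr.read_count < read_min:
            continue
        donor_key = (jr.chrom, jr.strand, jr.donor)
        acc_key = jr.key()
        if donor_key not in annotation.donors:
            continue
        if acc_key in annotation.acceptors:
            continue  # annotated acceptor, not cryptic
        if acc_key in sensitive_keys or acc_key in exclude:
            continue
        out.add(acc_key)
    if n_unknown:
        warnings.warn(f"dropped {n_unknown} junctions on unknown chromosomes")
    return out


def overlap_null_test(per_dataset_keys, universe, min_datasets: int = 2,
                      n_resample: int = 1000, seed=None):
    """Permutation test for cross-dataset sharing of junction keys.

    Draws, for each dataset, a random key set of the same size from the
    universe (without replacement) and counts keys shared by
    >= min_datasets sets.  Empirical p uses the add-one estimator
    (1 + #{null >= observed}) / (1 + n_resample).
    """
    universe = list(universe)
    sizes = [len(s) for s in per_dataset_keys]
    if any(sz > len(universe) for sz in sizes):
        raise ValueError("universe smaller than one of the key sets")

    def shared_count(sets):
        support: dict = {}
        for s in sets:
            for k in s:
                support[k] = support.get(k, 0) + 1
        return sum(1 for v in support.values() if v >= min_datasets)

    observed = shared_count(per_dataset_keys)
    rng = np.random.default_rng(seed)
    null = np.empty(n_resample, dtype=np.int64)
    n_univ = len(universe)
    for r in range(n_resample):
        draws = [rng.choice(n_univ, size=sz, replace=False) for sz in sizes]
        null[r] = shared_count(draws)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_resample)
    return observed, null, p
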