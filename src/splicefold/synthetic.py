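"""Synthetic multi-dataset splicing and chemical-probing data with planted
ground truth.

Emulates the inputs of the cryptic-3'SS analysis at desk scale so every
downstream stage can be tested end to end without sequencing data:

* splice-region sequences (450 nt flanking each side of the canonical
  acceptor) with a planted cryptic acceptor upstream.  MT-class (SF3B1-
  sensitive) cryptic sites sit in an extended polypyrimidine tract on both
  sides; WT-class (resistant) sites have a pyrimidine-rich tract upstream
  only and, by default, a stable planted stem that pairs the intron up to
  the N of the NAG while leaving the A and G in the loop — the structural
  contrast the analysis is designed to detect.
* per-dataset alternative-acceptor event tables with beta-binomial
  junction counts, a two-proportion test and Benjamini-Hochberg FDR.
* wild-type junction records plus a transcript model for the resistant-
  site extraction, including deliberately invalid distractors.
* SHAPE-MaP mutation-count profiles whose latent reactivities are
  conditioned on the MFE structure of the probed window.

Identical config + seed gives byte-identical outputs; independent RNG
substreams per stage let stages be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .classify import EventRecord, JunctionRecord, TranscriptModel
from .coords import rel_positions, rel_to_index
from .features import SpliceRegion
from .fold import mfe_fold
from .shape import MutationCountProfile

_BASES = np.array(list("ACGU"))


def _composition(upstream, downstream, halfwidth: int) -> np.ndarray:
    """Per-position base-probability profile around a cryptic site from
    constant upstream/downstream base probabilities (A, C, G, U order)."""
    rows = np.empty((2 * halfwidth, 4))
    rows[:halfwidth] = np.asarray(upstream, dtype=float)
    rows[halfwidth:] = np.asarray(downstream, dtype=float)
    return rows


#: extended polypyrimidine tract on both sides of the cryptic site
MT_UPSTREAM = (0.10, 0.30, 0.10, 0.50)
MT_DOWNSTREAM = (0.10, 0.30, 0.10, 0.50)
#: typical tract: pyrimidine-rich upstream, unbiased downstream
WT_UPSTREAM = (0.10, 0.30, 0.10, 0.50)
WT_DOWNSTREAM = (0.25, 0.25, 0.25, 0.25)
#: canonical-acceptor polypyrimidine tract
PPT = (0.05, 0.35, 0.05, 0.55)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the scale of the probing cohort (tens of junctions per
    class, three mutant datasets, triplicate libraries) and standard
    SHAPE-MaP characteristics (per-nt background mutation rate a few per
    thousand, modified-channel rates boosted proportionally to latent
    reactivity)."""

    n_sensitive: int = 30
    n_resistant: int = 30
    n_control: int = 15
    n_datasets: int = 3
    replicates_per_condition: int = 3
    read_depth_mean: float = 5000.0
    planted_dpsi: float = 0.3
    psi_base_sensitive: float = 0.05
    psi_base_resistant: float = 0.30
    psi_concentration: float = 10000.0  # beta-binomial concentration
    composition_mt: np.ndarray = None
    composition_wt: np.ndarray = None
    comp_halfwidth: int = 20
    cryptic_offset_range: tuple = (25, 60)  # nt upstream of the canonical G
    flank_length: int = 450
    plant_wt_structure: bool = True
    stem_len: int = 14
    wt_extra_stem_offsets: tuple = (-55, -95)  # cryptic-relative hairpin anchors
    mt_tract_span: tuple = (-130, 20)  # extended pyrimidine tract around MT sites
    mt_tract_probs: tuple = (0.15, 0.25, 0.10, 0.50)  # purine-poor, U-rich
    intron_length_range: tuple = (500, 5000)
    shape_depth: float = 10000.0
    shape_replicates: int = 2
    background_mut_rate: float = 0.002
    shape_scale: float = 0.03  # mutation-rate gain per unit latent reactivity
    paired_react_params: tuple = (1.0, 0.05)  # gamma (shape, scale), mean 0.05
    unpaired_react_params: tuple = (2.0, 0.25)  # gamma (shape, scale), mean 0.5
    probe_flank: int = 150
    seed: int = 0

    def __post_init__(self):
        if self.composition_mt is None:
            self.composition_mt = _composition(MT_UPSTREAM, MT_DOWNSTREAM, self.comp_halfwidth)
        if self.composition_wt is None:
            self.composition_wt = _composition(WT_UPSTREAM, WT_DOWNSTREAM, self.comp_halfwidth)
        self.validate()

    def validate(self):
        for name in ("composition_mt", "composition_wt"):
            comp = np.asarray(getattr(self, name), dtype=float)
            if comp.shape != (2 * self.comp_halfwidth, 4):
                raise ValueError(f"{name} must have shape (2*comp_halfwidth, 4)")
            if np.any(comp < 0) or np.any(comp > 1):
                raise ValueError(f"{name} probabilities must be in [0, 1]")
            if not np.allclose(comp.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
            setattr(self, name, comp)
        lo, hi = self.cryptic_offset_range
        if not (isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer))):
            raise ValueError("cryptic_offset_range bounds must be integers")
        if lo < 4 or hi < lo:
            raise ValueError("cryptic offsets must be >= 4 nt (cryptic AG must "
                             "not overlap the canonical motif)")
        if self.plant_wt_structure and lo < self.stem_len + 7:
            raise ValueError("planted stem needs cryptic offsets >= stem_len + 7")
        if self.plant_wt_structure:
            for o in self.wt_extra_stem_offsets:
                if o + self.flank_length - max(self.cryptic_offset_range) < 0:
                    raise ValueError("extra stems fall outside the region")
                if o + 2 * self.stem_len + 4 > -(self.stem_len + 2):
                    raise ValueError("extra stems overlap the splice-site stem")
        if self.flank_length < max(150, self.probe_flank):
            raise ValueError("flank_length must cover the analysis windows (>= 150)")
        if not 0 <= self.planted_dpsi <= 1:
            raise ValueError("planted_dpsi must be in [0, 1]")
        if not 0 <= self.background_mut_rate <= 1:
            raise ValueError("background_mut_rate must be in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream per stage, derived from the global seed."""
        streams = {"sequences": 1, "counts": 2, "junctions": 3, "shape": 4, "misc": 5}
        return np.random.default_rng(np.random.SeedSequence((self.seed, streams[stream])))


@dataclass
class JunctionTruth:
    """Planted ground truth for one junction."""

    junction_id: str
    klass: str  # MT | WT | control
    chrom: str
    strand: str
    region_start: int  # genomic coordinate of the region's first base
    canonical_index: int  # index of the canonical G within the region
    cryptic_index: int | None
    intron_length: int
    offset: int | None  # cryptic-to-canonical distance (nt, upstream)
    psi_wt: float
    psi_mut: float
    dpsi_per_dataset: dict = field(default_factory=dict)
    probe_start: int | None = None  # region index of the probed window start
    structure_pairs: list = field(default_factory=list)  # window-local pairs
    latent_reactivity: list = field(default_factory=list)
    paired_mask: list = field(default_factory=list)

    # genomic coordinates: regions are emitted in sense orientation on the
    # plus strand, and the acceptor coordinate is the intron-end boundary
    # of the half-open intron span (index of the first exonic base)

    @property
    def canonical_acceptor(self) -> int:
        return self.region_start + self.canonical_index + 1

    @property
    def cryptic_acceptor(self) -> int | None:
        if self.cryptic_index is None:
            return None
        return self.region_start + self.cryptic_index + 1

    @property
    def donor_pos(self) -> int:
        return self.canonical_acceptor - self.intron_length


@dataclass
class SyntheticTruth:
    junctions: list
    invalid_junction_keys: list = field(default_factory=list)

    def by_id(self) -> dict:
        return {t.junction_id: t for t in self.junctions}

    def sensitive_keys(self) -> set:
        return {(t.chrom, t.strand, t.cryptic_acceptor)
                for t in self.junctions if t.klass == "MT"}

    def resistant_keys(self) -> set:
        return {(t.chrom, t.strand, t.cryptic_acceptor)
                for t in self.junctions if t.klass == "WT"}

    def to_json(self, path) -> None:
        payload = {
            "junctions": [
                {**{k: v for k, v in asdict(t).items()},
                 "canonical_acceptor": t.canonical_acceptor,
                 "cryptic_acceptor": t.cryptic_acceptor}
                for t in self.junctions
            ],
            "invalid_junction_keys": [list(k) for k in self.invalid_junction_keys],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _draw(rng, probs, size):
    return rng.choice(4, size=size, p=np.asarray(probs, dtype=float))


def gen_junction_sequences(config: SyntheticConfig):
    """Generate splice-region sequences and planted truth.

    Each region spans ``flank_length`` nt on both sides of the canonical
    acceptor (anchored at the canonical G).  MT/WT regions carry a cryptic
    AG at a sampled upstream offset; control regions have candidate AGs
    scrubbed from the offset window.
    """
    rng = config.rng("sequences")
    flank = config.flank_length
    hw = config.comp_halfwidth
    length = 2 * flank
    can_idx = flank - 1  # canonical G; first exonic base at `flank`
    lo, hi = config.cryptic_offset_range
    regions: list[SpliceRegion] = []
    truths: list[JunctionTruth] = []
    classes = (["MT"] * config.n_sensitive + ["WT"] * config.n_resistant
               + ["control"] * config.n_control)
    counter = {"MT": 0, "WT": 0, "control": 0}
    for j, klass in enumerate(classes):
        jid = f"{klass}{counter[klass]:03d}"
        counter[klass] += 1
        base = rng.integers(0, 4, size=length)
        # canonical polypyrimidine tract (-20..-4)
        base[can_idx - 19 : can_idx - 2] = _draw(rng, PPT, 17)
        offset = None
        g = None
        if klass in ("MT", "WT"):
            for _ in range(1000):
                offset = int(rng.integers(lo, hi + 1))
                if offset >= 4:  # cryptic AG must not overlap the canonical motif
                    break
            g = can_idx - offset
            if klass == "MT":
                # extended polypyrimidine tract: purine-poor across the whole
                # structural analysis region, so the MT junction stays flexible
                a, b = config.mt_tract_span
                span = rel_to_index(g, b) - rel_to_index(g, a) + 1
                base[rel_to_index(g, a) : rel_to_index(g, b) + 1] = _draw(
                    rng, config.mt_tract_probs, span)
            comp = config.composition_mt if klass == "MT" else config.composition_wt
            for row in range(2 * hw):
                pos = row - hw if row < hw else row - hw + 1  # -hw..-1, +1..+hw
                idx = rel_to_index(g, pos)
                base[idx] = rng.choice(4, p=comp[row])
            if klass == "WT" and config.plant_wt_structure:
                sl = config.stem_len
                # splice-site stem: pairs the intron up to the N of the NAG;
                # the A and G stay in an unpairable A-rich loop
                arm = rng.choice(4, size=sl, p=[0.0, 0.6, 0.0, 0.4])  # C/U arm
                base[g - sl - 1 : g - 1] = arm
                base[g + 1 : g + 5] = 0  # A A A A loop tail
                base[g + 5 : g + 5 + sl] = np.array([3, 2, 1, 0])[arm][::-1]
                # structured scaffold: additional hairpins upstream in the
                # intron, so the resistant junction is stable over a broad
                # region rather than around one stem
                for o in config.wt_extra_stem_offsets:
                    left = g + o
                    arm = rng.choice(4, size=sl, p=[0.0, 0.6, 0.0, 0.4])
                    base[left : left + sl] = arm
                    base[left + sl : left + sl + 4] = 0  # loop
                    base[left + sl + 4 : left + 2 * sl + 4] = (
                        np.array([3, 2, 1, 0])[arm][::-1])
            base[g - 1] = 0  # cryptic A
            base[g] = 2  # cryptic G
        else:
            # scrub candidate cryptic AGs from the offset window
            for t in range(can_idx - hi - 5, can_idx - 2):
                if base[t] == 2 and base[t - 1] == 0:
                    base[t] = 1
        base[can_idx - 1] = 0  # canonical A
        base[can_idx] = 2  # canonical G
        seq = "".join(_BASES[base])
        intron_length = int(rng.integers(*config.intron_length_range))
        strand = "+"
        chrom = "chrS"
        region_start = 1_000_000 + j * 10_000
        regions.append(SpliceRegion(
            junction_id=jid, klass=klass, site_role="canonical", sequence=seq,
            site_index=can_idx, intron_length=intron_length,
            partner_offset=None if offset is None else -offset))
        psi_wt = {"MT": config.psi_base_sensitive, "WT": config.psi_base_resistant,
                  "control": 0.0}[klass]
        psi_mut = psi_wt + (config.planted_dpsi if klass == "MT" else 0.0)
        truths.append(JunctionTruth(
            junction_id=jid, klass=klass, chrom=chrom, strand=strand,
            region_start=region_start, canonical_index=can_idx,
            cryptic_index=g, intron_length=intron_length, offset=offset,
            psi_wt=psi_wt, psi_mut=psi_mut,
            dpsi_per_dataset={f"ds{d}": (config.planted_dpsi if klass == "MT" else 0.0)
                              for d in range(config.n_datasets)}))
    return regions, SyntheticTruth(truths)


def _beta_binomial(rng, n, psi, conc):
    if psi <= 0:
        return 0
    if psi >= 1:
        return int(n)
    p = rng.beta(psi * conc, (1 - psi) * conc)
    return int(rng.binomial(n, p))


def gen_splicing_counts(config: SyntheticConfig, truth: SyntheticTruth):
    """Per-dataset alternative-acceptor event tables.

    Junction-spanning inclusion (cryptic) and skipping (canonical) counts
    are beta-binomial around the true PSI; PSI is estimated from pooled
    replicate counts, the p-value comes from a two-proportion z-test and
    the FDR from Benjamini-Hochberg within each dataset."""
    rng = config.rng("counts")
    events_per_dataset = []
    for d in range(config.n_datasets):
        ds = f"ds{d}"
        recs = []
        pvals = []
        for t in truth.junctions:
            if t.cryptic_index is None:
                continue
            cond_counts = {}
            for cond, psi in (("wt", t.psi_wt), ("mut", t.psi_mut)):
                inc, skp = [], []
                for _ in range(config.replicates_per_condition):
                    n = int(rng.poisson(config.read_depth_mean))
                    k = _beta_binomial(rng, n, psi, config.psi_concentration)
                    inc.append(k)
                    skp.append(n - k)
                cond_counts[cond] = (tuple(inc), tuple(skp))
            inc_wt, skip_wt = cond_counts["wt"]
            inc_mut, skip_mut = cond_counts["mut"]
            tot_wt = sum(inc_wt) + sum(skip_wt)
            tot_mut = sum(inc_mut) + sum(skip_mut)
            psi_wt = sum(inc_wt) / tot_wt if tot_wt else float("nan")
            psi_mut = sum(inc_mut) / tot_mut if tot_mut else float("nan")
            if tot_wt and tot_mut and 0 < sum(inc_wt) + sum(inc_mut) < tot_wt + tot_mut:
                _, pval = proportions_ztest(
                    [sum(inc_mut), sum(inc_wt)], [tot_mut, tot_wt])
                pval = float(pval)
            else:
                pval = 1.0
            pvals.append(pval)
            recs.append(EventRecord(
                dataset_id=ds, gene=t.junction_id, chrom=t.chrom, strand=t.strand,
                donor_pos=t.donor_pos, canonical_acceptor=t.canonical_acceptor,
                cryptic_acceptor=t.cryptic_acceptor, psi_wt=psi_wt, psi_mut=psi_mut,
                pvalue=pval, fdr=float("nan"), dpsi=psi_mut - psi_wt,
                inc_wt=inc_wt, skip_wt=skip_wt, inc_mut=inc_mut, skip_mut=skip_mut,
                junction_id=t.junction_id))
        if recs:
            fdrs = multipletests(pvals, method="fdr_bh")[1]
            for rec, q in zip(recs, fdrs):
                rec.fdr = float(q)
        events_per_dataset.append(recs)
    return events_per_dataset


def gen_junction_records(config: SyntheticConfig, truth: SyntheticTruth):
    """Wild-type junction records plus the transcript model.

    Emits annotated donor->canonical junctions for every gene, novel-
    acceptor junctions for resistant (high use) and sensitive (trace use)
    cryptic sites, and distractors violating the anchor/intron filters
    whose keys are recorded as invalid in the truth."""
    rng = config.rng("junctions")
    annotation = TranscriptModel()
    junctions: list[JunctionRecord] = []
    invalid: list[tuple] = []
    for t in truth.junctions:
        can = t.canonical_acceptor
        donor = t.donor_pos
        annotation.add_junction(t.chrom, t.strand, donor, can)
        junctions.append(JunctionRecord(
            t.chrom, t.strand, donor, can, int(rng.poisson(200)) + 20,
            int(rng.integers(8, 50)), "annotated"))
        if t.cryptic_index is None:
            continue
        cry = t.cryptic_acceptor
        if t.klass == "WT":
            reads = int(rng.poisson(config.psi_base_resistant * 200)) + 10
            junctions.append(JunctionRecord(
                t.chrom, t.strand, donor, cry, reads,
                int(rng.integers(8, 50)), "novel_acceptor"))
        else:
            # sensitive cryptic sites are barely used in wild-type samples
            junctions.append(JunctionRecord(
                t.chrom, t.strand, donor, cry, int(rng.poisson(2)) + 1,
                int(rng.integers(8, 50)), "novel_acceptor"))
    # distractors: violate one junction-extraction filter each
    wt_truth = [t for t in truth.junctions if t.klass == "WT"]
    for t, (anchor, ilen) in zip(wt_truth[:3], ((7, None), (None, 49), (None, 600001))):
        acc = t.canonical_acceptor + 200 + (0 if anchor else ilen)
        a = anchor if anchor is not None else int(rng.integers(8, 50))
        length = ilen if ilen is not None else int(rng.integers(500, 5000))
        jr = JunctionRecord(t.chrom, t.strand, acc - length, acc, 50, a, "novel_acceptor")
        junctions.append(jr)
        invalid.append(jr.key())
        annotation.donors.add((t.chrom, t.strand, acc - length))
    truth.invalid_junction_keys = invalid
    return junctions, annotation


def gen_shape_profiles(config: SyntheticConfig, truth: SyntheticTruth, regions):
    """SHAPE-MaP mutation-count profiles conditioned on folded structure.

    The probed window is +/- probe_flank around the focal acceptor (the
    cryptic site for MT/WT junctions, the canonical site for controls).
    The window is folded without restraints to define the true structure;
    latent reactivities are gamma-distributed with a strictly higher
    unpaired mean; channel counts are binomial at depth ``shape_depth``.
    Rates above 1 are clipped.  Fills the truth's structure and latent
    fields; emits ``shape_replicates`` replicates per junction."""
    rng = config.rng("shape")
    by_id = {r.junction_id: r for r in regions}
    fl = config.probe_flank
    positions = np.array(rel_positions(fl))
    profiles: list[MutationCountProfile] = []
    pk, pth = config.paired_react_params
    uk, uth = config.unpaired_react_params
    if pk * pth >= uk * uth:
        raise ValueError("unpaired mean reactivity must exceed paired mean")
    for t in truth.junctions:
        region = by_id[t.junction_id]
        anchor = t.cryptic_index if t.cryptic_index is not None else t.canonical_index
        start = rel_to_index(anchor, -fl)
        stop = rel_to_index(anchor, fl)
        window = region.sequence[start : stop + 1]
        structure = mfe_fold(window)
        paired = structure.partner >= 0
        latent = np.where(
            paired,
            rng.gamma(pk, pth, size=len(window)),
            rng.gamma(uk, uth, size=len(window)),
        )
        t.probe_start = start
        t.structure_pairs = [list(p) for p in structure.pairs]
        t.latent_reactivity = [float(x) for x in latent]
        t.paired_mask = [bool(b) for b in paired]
        rate_mod = np.clip(config.background_mut_rate + config.shape_scale * latent, 0.0, 1.0)
        for rep in range(config.shape_replicates):
            mod_depth = rng.poisson(config.shape_depth, size=len(window))
            unt_depth = rng.poisson(config.shape_depth, size=len(window))
            mod_mut = rng.binomial(mod_depth, rate_mod)
            unt_mut = rng.binomial(unt_depth, config.background_mut_rate)
            profiles.append(MutationCountProfile(
                junction_id=t.junction_id, positions=positions.copy(),
                mod_mut=mod_mut, mod_depth=mod_depth,
                unt_mut=unt_mut, unt_depth=unt_depth, replicate=rep))
    return profiles
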