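"""Synthetic-data generator: determinism, planted composition, count model
and file round-trips."""

import numpy as np
import pytest

from splicefold import io
from splicefold.coords import rel_to_index
from splicefold.synthetic import (SyntheticConfig, gen_junction_records,
                                  gen_junction_sequences, gen_shape_profiles,
                                  gen_splicing_counts)


def test_same_seed_identical_output(tmp_path):
    """Identical config + seed gives byte-identical FASTA and event tables."""
    outs = []
    for run in range(2):
        cfg = SyntheticConfig(n_sensitive=4, n_resistant=4, n_control=2, seed=7)
        regions, truth = gen_junction_sequences(cfg)
        events = gen_splicing_counts(cfg, truth)
        fa = tmp_path / f"r{run}.fasta"
        ev = tmp_path / f"e{run}.tsv"
        io.write_regions_fasta(regions, fa)
        io.write_events_tsv(events[0], ev)
        outs.append((fa.read_bytes(), ev.read_bytes()))
    assert outs[0] == outs[1]


def test_flank_length_and_acceptor_anchoring():
    cfg = SyntheticConfig(n_sensitive=3, n_resistant=3, n_control=2, seed=1)
    regions, truth = gen_junction_sequences(cfg)
    for reg in regions:
        assert len(reg.sequence) == 900  # 450 nt flanking both sides
        assert reg.site_index == 449
        assert reg.sequence[448:450] == "AG"
        if reg.partner_offset is not None:
            g = reg.site_index + reg.partner_offset
            assert reg.sequence[g - 1 : g + 1] == "AG"


def test_truth_coordinates_inside_regions():
    cfg = SyntheticConfig(n_sensitive=3, n_resistant=3, n_control=1, seed=3)
    regions, truth = gen_junction_sequences(cfg)
    for t in truth.junctions:
        assert 0 <= t.canonical_index < 900
        if t.cryptic_index is not None:
            assert 0 <= t.cryptic_index < t.canonical_index
            lo, hi = cfg.cryptic_offset_range
            assert lo <= t.offset <= hi


def test_control_regions_have_no_candidate_cryptic_ag():
    cfg = SyntheticConfig(n_sensitive=0, n_resistant=0, n_control=20, seed=4)
    regions, _ = gen_junction_sequences(cfg)
    lo, hi = cfg.cryptic_offset_range
    for reg in regions:
        window = reg.sequence[reg.site_index - hi - 4 : reg.site_index - 2]
        assert "AG" not in window


def test_downstream_uridine_composition_margin():
    """With structure planting off, the MT class has the configured excess
    of U downstream of the cryptic site (0.5 vs 0.25), recovered within
    three binomial standard errors."""
    cfg = SyntheticConfig(n_sensitive=200, n_resistant=200, n_control=0,
                          plant_wt_structure=False, seed=5)
    regions, truth = gen_junction_sequences(cfg)
    by_id = truth.by_id()
    frac = {}
    for klass in ("MT", "WT"):
        n_u = n_tot = 0
        for reg in regions:
            if reg.klass != klass:
                continue
            g = by_id[reg.junction_id].cryptic_index
            window = reg.sequence[rel_to_index(g, 1) : rel_to_index(g, 20) + 1]
            n_u += window.count("U")
            n_tot += len(window)
        frac[klass] = n_u / n_tot
    diff = frac["MT"] - frac["WT"]
    n = 200 * 20
    se = np.sqrt(0.5 * 0.5 / n + 0.25 * 0.75 / n)
    assert abs(diff - 0.25) < 3 * se


def test_composition_validation():
    bad = np.full((40, 4), 0.3)
    with pytest.raises(ValueError, match="sum to 1"):
        SyntheticConfig(composition_mt=bad)
    with pytest.raises(ValueError):
        SyntheticConfig(cryptic_offset_range=(2, 10), plant_wt_structure=False)


def test_psi_formula_degenerate_cases(splicing_cohort):
    cfg, _, truth, events, _, _ = splicing_cohort
    for ev in events[0]:
        tot_wt = sum(ev.inc_wt) + sum(ev.skip_wt)
        assert ev.psi_wt == pytest.approx(sum(ev.inc_wt) / tot_wt)
        assert ev.dpsi == pytest.approx(ev.psi_mut - ev.psi_wt)
        assert 0 <= ev.pvalue <= 1 and 0 <= ev.fdr <= 1


def test_null_psi_estimates_concentrate():
    """With equal true PSI in both conditions and deep counts, the reported
    dPSI stays within 0.02 in at least 95% of events."""
    cfg = SyntheticConfig(n_sensitive=0, n_resistant=60, n_control=0,
                          read_depth_mean=10000.0, psi_base_resistant=0.5,
                          n_datasets=2, seed=6)
    _, truth = gen_junction_sequences(cfg)
    events = gen_splicing_counts(cfg, truth)
    dpsi = np.array([ev.dpsi for evs in events for ev in evs])
    assert np.mean(np.abs(dpsi) < 0.02) >= 0.95


def test_planted_dpsi_in_two_or_more_datasets():
    cfg = SyntheticConfig(n_sensitive=10, n_resistant=5, n_control=0, seed=8)
    _, truth = gen_junction_sequences(cfg)
    for t in truth.junctions:
        if t.klass == "MT":
            above = sum(1 for v in t.dpsi_per_dataset.values() if abs(v) > 0.05)
            assert above >= 2


def test_shape_counts_background_and_determinism():
    cfg = SyntheticConfig(n_sensitive=0, n_resistant=0, n_control=2,
                          background_mut_rate=0.0, shape_replicates=1, seed=9)
    regions, truth = gen_junction_sequences(cfg)
    profiles = gen_shape_profiles(cfg, truth, regions)
    for p in profiles:
        assert np.all(p.unt_mut == 0)  # zero background rate
    cfg2 = SyntheticConfig(n_sensitive=0, n_resistant=0, n_control=2,
                           background_mut_rate=0.0, shape_replicates=1, seed=9)
    regions2, truth2 = gen_junction_sequences(cfg2)
    profiles2 = gen_shape_profiles(cfg2, truth2, regions2)
    for a, b in zip(profiles, profiles2):
        assert np.array_equal(a.mod_mut, b.mod_mut)
        assert np.array_equal(a.unt_mut, b.unt_mut)


def test_latent_reactivity_recovery_at_high_depth():
    """At depth 50000 the recovered normalized reactivity separates paired
    from unpaired bases (Wilcoxon p < 1e-6 on a 300-nt window) and tracks
    the latent reactivity with correlation > 0.8."""
    from scipy import stats

    from splicefold.shape import compute_raw_reactivity, merge_replicates

    cfg = SyntheticConfig(n_sensitive=0, n_resistant=2, n_control=0,
                          shape_depth=50000.0, seed=11)
    regions, truth = gen_junction_sequences(cfg)
    profiles = gen_shape_profiles(cfg, truth, regions)
    t = truth.junctions[0]
    raws = [compute_raw_reactivity(p) for p in profiles if p.junction_id == t.junction_id]
    norm = merge_replicates(raws)
    latent = np.array(t.latent_reactivity)
    paired = np.array(t.paired_mask)
    ok = ~norm.mask
    r = np.corrcoef(latent[ok], norm.values[ok])[0, 1]
    assert r > 0.8
    p = stats.mannwhitneyu(norm.values[ok & ~paired], norm.values[ok & paired],
                           alternative="greater").pvalue
    assert p < 1e-6


def test_round_trips(tmp_path, splicing_cohort):
    """All emitted files round-trip through the module's readers."""
    cfg, regions, truth, events, junctions, annotation = splicing_cohort
    io.write_regions_fasta(regions, tmp_path / "r.fasta")
    back = io.read_regions_fasta(tmp_path / "r.fasta")
    assert [(r.junction_id, r.klass, r.sequence, r.site_index, r.partner_offset)
            for r in regions] == \
        [(r.junction_id, r.klass, r.sequence, r.site_index, r.partner_offset)
         for r in back]

    io.write_events_tsv(events[0], tmp_path / "e.tsv")
    ev_back = io.read_events_tsv(tmp_path / "e.tsv")
    assert [(e.key(), e.inc_wt, e.skip_mut) for e in events[0]] == \
        [(e.key(), e.inc_wt, e.skip_mut) for e in ev_back]
    assert np.allclose([e.fdr for e in events[0]], [e.fdr for e in ev_back])

    io.write_junctions_tsv(junctions, tmp_path / "j.tsv")
    j_back = io.read_junctions_tsv(tmp_path / "j.tsv")
    assert [(j.key(), j.read_count, j.min_anchor) for j in junctions] == \
        [(j.key(), j.read_count, j.min_anchor) for j in j_back]

    from splicefold.classify import TranscriptModel
    io.write_annotation_gff3(truth, tmp_path / "a.gff3")
    model = TranscriptModel.from_gff3(tmp_path / "a.gff3")
    for t in truth.junctions:
        assert (t.chrom, t.strand, t.donor_pos) in model.donors
        assert (t.chrom, t.strand, t.canonical_acceptor) in model.acceptors


def test_mutation_count_round_trip(tmp_path):
    cfg = SyntheticConfig(n_sensitive=1, n_resistant=1, n_control=0,
                          shape_replicates=2, seed=10)
    regions, truth = gen_junction_sequences(cfg)
    profiles = gen_shape_profiles(cfg, truth, regions)
    io.write_mutation_counts_tsv(profiles, tmp_path / "m.tsv")
    back = io.read_mutation_counts_tsv(tmp_path / "m.tsv")
    assert len(back) == len(profiles)
    for a, b in zip(profiles, back):
        assert a.junction_id == b.junction_id and a.replicate == b.replicate
        assert np.array_equal(a.mod_mut, b.mod_mut)
        assert np.array_equal(a.positions, b.positions)


def test_shape_file_round_trip(tmp_path):
    from splicefold.shape import ReactivityProfile
    from splicefold.coords import rel_positions

    vals = np.array([0.1, np.nan, 2.5, 0.0] * 10)
    mask = ~np.isfinite(vals)
    prof = ReactivityProfile("j", np.array(rel_positions(20)), vals,
                             np.zeros(40), mask, normalized=True)
    io.write_shape_file(prof, tmp_path / "j.shape")
    back = io.read_shape_file(tmp_path / "j.shape")
    assert np.array_equal(back.mask, mask)
    assert np.allclose(back.values[~mask], vals[~mask])
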