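"""Significance filtering, cross-dataset intersection, resistant-site
extraction and the overlap permutation test."""

import numpy as np
import pytest

from splicefold.classify import (EventRecord, JunctionRecord, TranscriptModel,
                                 extract_resistant_c3ss, filter_significant_events,
                                 intersect_across_datasets, overlap_null_test)


def make_event(ds="ds0", cryptic=500, fdr=0.01, dpsi=0.2, **kw):
    defaults = dict(dataset_id=ds, gene="g", chrom="chr1", strand="+",
                    donor_pos=100, canonical_acceptor=600, cryptic_acceptor=cryptic,
                    psi_wt=0.1, psi_mut=0.1 + dpsi, pvalue=fdr / 2, fdr=fdr, dpsi=dpsi)
    defaults.update(kw)
    return EventRecord(**defaults)


class TestFilter:
    def test_fdr_boundary_excludes(self):
        assert filter_significant_events([make_event(fdr=0.2, dpsi=0.3)]) == []
        assert filter_significant_events([make_event(fdr=0.1, dpsi=0.3)]) == []

    def test_dpsi_boundary_retains(self):
        ev = make_event(fdr=0.05, dpsi=0.06)
        assert filter_significant_events([ev]) == [ev]
        assert filter_significant_events([make_event(dpsi=0.05)]) == []

    def test_dpsi_is_two_sided(self):
        ev = make_event(dpsi=-0.3)
        assert filter_significant_events([ev]) == [ev]

    def test_empty_input(self):
        assert filter_significant_events([]) == []

    def test_missing_values_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            out = filter_significant_events([make_event(fdr=float("nan"))])
        assert out == []

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        events = [make_event(cryptic=i, fdr=float(rng.uniform(0, 0.3)),
                             dpsi=float(rng.uniform(-0.3, 0.3))) for i in range(50)]
        loose = {e.key() for e in filter_significant_events(events, 0.2, 0.02)}
        tight = {e.key() for e in filter_significant_events(events, 0.1, 0.05)}
        assert tight <= loose

    def test_idempotent(self):
        events = [make_event(cryptic=i, fdr=0.05, dpsi=0.2) for i in range(5)]
        once = filter_significant_events(events)
        assert filter_significant_events(once) == once


class TestIntersect:
    def events(self):
        # key 500 in ds0+ds1, key 501 only in ds0
        return [
            [make_event("ds0", 500), make_event("ds0", 501)],
            [make_event("ds1", 500)],
            [],
        ]

    def test_two_or_more_datasets(self):
        sens = intersect_across_datasets(self.events(), min_datasets=2)
        assert set(sens) == {("chr1", "+", 500)}
        assert sens[("chr1", "+", 500)] == {"ds0", "ds1"}

    def test_single_dataset_excluded(self):
        assert ("chr1", "+", 501) not in intersect_across_datasets(self.events(), 2)

    def test_min_one_is_union(self):
        sens = intersect_across_datasets(self.events(), min_datasets=1)
        assert set(sens) == {("chr1", "+", 500), ("chr1", "+", 501)}

    def test_too_many_required_warns_empty(self):
        with pytest.warns(UserWarning):
            assert intersect_across_datasets(self.events(), min_datasets=5) == {}

    def test_filter_intersect_idempotent(self):
        filtered = [filter_significant_events(ev) for ev in self.events()]
        sens1 = intersect_across_datasets(filtered, 2)
        refiltered = [filter_significant_events(ev) for ev in filtered]
        assert intersect_across_datasets(refiltered, 2) == sens1


class TestResistantExtraction:
    def setup_method(self):
        self.model = TranscriptModel()
        self.model.add_junction("chr1", "+", donor=1000, acceptor=2000)

    def jr(self, **kw):
        defaults = dict(chrom="chr1", strand="+", intron_start=1000,
                        intron_end=1970, read_count=20, min_anchor=12,
                        annotation="novel_acceptor")
        defaults.update(kw)
        return JunctionRecord(**defaults)

    def test_hand_fixture_yields_one_key(self):
        # novel acceptor 30 nt upstream of the annotated one, same donor
        out = extract_resistant_c3ss([self.jr()], self.model, sensitive=set())
        assert out == {("chr1", "+", 1970)}

    def test_anchor_below_eight_rejected(self):
        assert extract_resistant_c3ss([self.jr(min_anchor=7)], self.model, set()) == set()
        assert extract_resistant_c3ss([self.jr(min_anchor=8)], self.model, set()) != set()

    def test_intron_size_bounds(self):
        short = self.jr(intron_start=1970 - 49)
        assert extract_resistant_c3ss([short], self.model, set()) == set()
        self.model.donors.add(("chr1", "+", 1970 - 600001))
        long = self.jr(intron_start=1970 - 600001)
        assert extract_resistant_c3ss([long], self.model, set()) == set()

    def test_annotated_acceptor_not_cryptic(self):
        ann = self.jr(intron_end=2000)
        assert extract_resistant_c3ss([ann], self.model, set()) == set()

    def test_sensitive_and_excluded_keys_removed(self):
        key = ("chr1", "+", 1970)
        assert extract_resistant_c3ss([self.jr()], self.model, {key}) == set()
        assert extract_resistant_c3ss([self.jr()], self.model, set(),
                                      exclude_keys={key}) == set()

    def test_unknown_chrom_warns(self):
        with pytest.warns(UserWarning):
            out = extract_resistant_c3ss([self.jr(chrom="chrX")], self.model, set())
        assert out == set()


class TestOverlapNull:
    def test_maximal_overlap_add_one_p(self):
        keys = set(range(50))
        obs, null, p = overlap_null_test([keys, keys, keys], set(range(10000)),
                                         min_datasets=2, n_resample=100, seed=0)
        assert obs == 50
        assert p == pytest.approx(1 / 101)

    def test_universe_too_small(self):
        with pytest.raises(ValueError):
            overlap_null_test([set(range(50))], set(range(10)), n_resample=10)

    def test_null_reproducible(self):
        sets = [set(range(20)), set(range(10, 30))]
        _, null1, p1 = overlap_null_test(sets, set(range(200)), n_resample=50, seed=5)
        _, null2, p2 = overlap_null_test(sets, set(range(200)), n_resample=50, seed=5)
        assert np.array_equal(null1, null2) and p1 == p2


def test_noise_free_recovery(splicing_cohort):
    """On synthetic tables the filter+intersect stage recovers exactly the
    planted sensitive set, and the junction filters recover the resistant
    set while rejecting the planted invalid records."""
    cfg, regions, truth, events, junctions, annotation = splicing_cohort
    filtered = [filter_significant_events(ev) for ev in events]
    sensitive = intersect_across_datasets(filtered, 2)
    assert set(sensitive) == truth.sensitive_keys()
    all_sig = set().union(*({e.key() for e in f} for f in filtered))
    resistant = extract_resistant_c3ss(junctions, annotation, sensitive,
                                       exclude_keys=all_sig)
    assert resistant == truth.resistant_keys()
    assert all(k not in resistant for k in truth.invalid_junction_keys)
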