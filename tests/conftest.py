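"""Shared fixtures: synthetic cohorts are expensive (hundreds of folds), so
they are generated once per session and reused."""

from collections import defaultdict

import pytest

from splicefold.shape import compute_raw_reactivity, merge_replicates
from splicefold.synthetic import (SyntheticConfig, gen_junction_records,
                                  gen_junction_sequences, gen_shape_profiles,
                                  gen_splicing_counts)


@pytest.fixture(scope="session")
def cohort40():
    """Forty MT and forty WT junctions with probing data at depth 10000.

    Used for the NAG-pattern and structure-contrast group analyses (the
    structure tests take the first 30 per class)."""
    cfg = SyntheticConfig(n_sensitive=40, n_resistant=40, n_control=0,
                          shape_depth=10000.0, seed=1)
    regions, truth = gen_junction_sequences(cfg)
    profiles = gen_shape_profiles(cfg, truth, regions)
    reps = defaultdict(list)
    for p in profiles:
        reps[p.junction_id].append(p)
    reactivities = {jid: merge_replicates([compute_raw_reactivity(p) for p in plist])
                    for jid, plist in sorted(reps.items())}
    return cfg, regions, truth, reactivities


@pytest.fixture(scope="session")
def splicing_cohort():
    """Default-scale cohort with event tables and junction records (no
    probing data), for the classification tests."""
    cfg = SyntheticConfig(seed=2)
    regions, truth = gen_junction_sequences(cfg)
    events = gen_splicing_counts(cfg, truth)
    junctions, annotation = gen_junction_records(cfg, truth)
    return cfg, regions, truth, events, junctions, annotation
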