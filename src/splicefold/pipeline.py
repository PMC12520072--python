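"""End-to-end orchestration: synthesize (or load) inputs, classify
junctions, extract sequence features, compute reactivities, run the
structure analyses and the group comparisons, and write a machine-readable
summary.

Every stochastic stage draws from a substream of one explicit seed; a run
with the same configuration and seed writes a byte-identical summary.
"""

from __future__ import annotations

import json
import logging
import time
from collections import defaultdict

import numpy as np
import yaml

from . import __version__, io
from .classify import (extract_resistant_c3ss, filter_significant_events,
                       intersect_across_datasets, overlap_null_test)
from .compare import aggregate_per_base, bootstrap_compare, rank_compare
from .coords import rel_to_index
from .features import (SpliceSiteModel, cryptic_canonical_distance,
                       extract_3ss_window, gc_content_upstream,
                       positional_nucleotide_probability)
from .fold import count_paired_bases, mfe_fold, pair_probabilities, partition_accessibility
from .fold.scan import dinucleotide_shuffle
from .shape import compute_raw_reactivity, merge_replicates, nag_motif_stats
from .synthetic import (SyntheticConfig, gen_junction_records, gen_junction_sequences,
                        gen_shape_profiles, gen_splicing_counts)

log = logging.getLogger("splicefold.pipeline")

DEFAULT_CONFIG = {
    "synth": {},
    "classify": {
        "fdr_max": 0.1,
        "dpsi_min": 0.05,
        "min_datasets": 2,
        "anchor_min": 8,
        "intron_min": 50,
        "intron_max": 500000,
        "read_min": 1,
        "overlap_resamples": 1000,
    },
    "features": {"gc_window": 150, "n_boot": 1000},
    "shape": {"min_depth": 1000, "min_rho": 0.7, "flank": 150},
    "structure": {
        "region": [-120, 15],
        "max_dist_lo": 27,
        "max_dist_hi": 34,
    },
    "unsafe_random": False,
}


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _merged(config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_pipeline(config: dict | None = None, outdir=None, seed: int | None = None) -> dict:
    """Run the full synthetic analysis and return the summary dict.

    ``seed`` feeds every stochastic stage; without one the stochastic
    comparisons refuse to run unless the config sets ``unsafe_random``."""
    cfg = _merged(config)
    if seed is None:
        seed = cfg.get("seed")
    if seed is None:
        if not cfg.get("unsafe_random"):
            raise ValueError("no seed given; set one or pass unsafe_random")
        seed = int(np.random.SeedSequence().entropy % (2**31))
    seed = int(seed)
    sub = np.random.SeedSequence(seed).spawn(8)
    subseed = [int(s.generate_state(1)[0] % (2**31)) for s in sub]
    t_start = time.time()

    # --- synthesize -------------------------------------------------------
    synth_cfg = SyntheticConfig(**{**cfg["synth"], "seed": subseed[0]})
    regions, truth = gen_junction_sequences(synth_cfg)
    events_per_dataset = gen_splicing_counts(synth_cfg, truth)
    junctions, annotation = gen_junction_records(synth_cfg, truth)
    mut_profiles = gen_shape_profiles(synth_cfg, truth, regions)
    log.info("synthesized %d regions in %.1fs", len(regions), time.time() - t_start)

    # --- classify ---------------------------------------------------------
    ccfg = cfg["classify"]
    filtered = [filter_significant_events(ev, ccfg["fdr_max"], ccfg["dpsi_min"])
                for ev in events_per_dataset]
    sensitive = intersect_across_datasets(filtered, ccfg["min_datasets"])
    all_significant = set()
    for f in filtered:
        all_significant |= {e.key() for e in f}
    resistant = extract_resistant_c3ss(
        junctions, annotation, sensitive, ccfg["anchor_min"], ccfg["intron_min"],
        ccfg["intron_max"], ccfg["read_min"], exclude_keys=all_significant)
    universe = sorted({e.key() for ev in events_per_dataset for e in ev}
                      | {j.key() for j in junctions})
    per_dataset_keys = [{e.key() for e in f} for f in filtered]
    obs, _, overlap_p = overlap_null_test(
        per_dataset_keys, universe, ccfg["min_datasets"],
        ccfg["overlap_resamples"], seed=subseed[1])
    true_sens = truth.sensitive_keys()
    detected = set(sensitive)
    precision = len(detected & true_sens) / len(detected) if detected else float("nan")
    recall = len(detected & true_sens) / len(true_sens) if true_sens else float("nan")

    # classes as classified (planted labels only used for truth metrics)
    key_to_id = {}
    for t in truth.junctions:
        if t.cryptic_acceptor is not None:
            key_to_id[(t.chrom, t.strand, t.cryptic_acceptor)] = t.junction_id
    mt_ids = sorted(key_to_id[k] for k in detected if k in key_to_id)
    wt_ids = sorted(key_to_id[k] for k in resistant if k in key_to_id)
    control_ids = sorted(t.junction_id for t in truth.junctions if t.klass == "control")
    groups = {"MT": mt_ids, "WT": wt_ids, "control": control_ids}
    by_id = {r.junction_id: r for r in regions}

    # --- sequence features --------------------------------------------------
    fcfg = cfg["features"]
    feats = {}
    for klass in ("MT", "WT"):
        rows = []
        for jid in groups[klass]:
            canonical = by_id[jid]
            cryptic = canonical.reanchored()
            dist, side = cryptic_canonical_distance(canonical)
            rows.append({
                "junction_id": jid,
                "gc150_cryptic": gc_content_upstream(cryptic, fcfg["gc_window"]),
                "gc150_canonical": gc_content_upstream(canonical, fcfg["gc_window"]),
                "intron_length": canonical.intron_length,
                "distance": dist,
                "side": side,
            })
        feats[klass] = rows
    # 3'SS strength: model trained on all canonical windows, shuffled background
    rng_bg = np.random.default_rng(subseed[2])
    canon_windows = [extract_3ss_window(by_id[jid])
                     for klass in groups for jid in groups[klass]]
    bg_windows = [dinucleotide_shuffle(w, rng=rng_bg) for w in canon_windows]
    ss_model = SpliceSiteModel().fit(canon_windows, bg_windows)
    for klass in ("MT", "WT"):
        for row in feats[klass]:
            canonical = by_id[row["junction_id"]]
            row["score3ss_canonical"] = ss_model.score_window(
                extract_3ss_window(canonical)).score
            row["score3ss_cryptic"] = ss_model.score_window(
                extract_3ss_window(canonical.reanchored())).score
    comp_profiles = {
        klass: positional_nucleotide_probability(
            [by_id[j].reanchored() for j in groups[klass]], synth_cfg.comp_halfwidth)
        for klass in ("MT", "WT") if groups[klass]
    }

    # --- SHAPE reactivity ---------------------------------------------------
    scfg = cfg["shape"]
    reps = defaultdict(list)
    for p in mut_profiles:
        reps[p.junction_id].append(p)
    reactivities = {}
    nag = {}
    for jid, plist in sorted(reps.items()):
        raws = [compute_raw_reactivity(p, scfg["min_depth"]) for p in plist]
        merged = merge_replicates(raws, scfg["min_rho"])
        reactivities[jid] = merged
        nag[jid] = nag_motif_stats(merged, scfg["flank"])
    group_profiles = {
        klass: aggregate_per_base([reactivities[j] for j in groups[klass]], klass)
        for klass in ("MT", "WT", "control") if groups[klass]
    }

    # --- structure ----------------------------------------------------------
    stc = cfg["structure"]
    lo_pos, hi_pos = stc["region"]
    dists = range(stc["max_dist_lo"], stc["max_dist_hi"] + 1)
    structure_rows = []
    dotbrackets = []
    for klass in ("MT", "WT", "control"):
        for jid in groups[klass]:
            t = truth.by_id()[jid]
            region = by_id[jid]
            anchor = t.cryptic_index if t.cryptic_index is not None else t.canonical_index
            s0 = rel_to_index(anchor, lo_pos)
            s1 = rel_to_index(anchor, hi_pos)
            subseq = region.sequence[s0 : s1 + 1]
            prof = reactivities[jid]
            off = s0 - t.probe_start
            react = prof.values_with_nan()[off : off + len(subseq)]
            st = mfe_fold(subseq, react)
            paired = count_paired_bases(st, 0, len(subseq) - 1)
            ed = pair_probabilities(subseq, react).ensemble_diversity
            acc = partition_accessibility(subseq, react, dists)
            idx_a = -lo_pos - 2  # array index of the acceptor A within subseq
            structure_rows.append({
                "junction_id": jid, "klass": klass, "paired_bases": paired,
                "ensemble_diversity": ed, "mfe": st.energy,
                "accessibility_A": float(acc[idx_a]),
                "accessibility_N": float(acc[idx_a - 1]),
                "accessibility_G": float(acc[idx_a + 1]),
            })
            dotbrackets.append((jid, subseq, st))

    # --- comparisons ----------------------------------------------------------
    reports = []

    def add_rank(metric, a, b, labels):
        rep = rank_compare([a, b], labels=labels, metric=metric)
        reports.append(rep)
        return rep

    def vals(klass, col):
        return [row[col] for row in feats[klass]]

    r_gc_boot = bootstrap_compare(
        vals("MT", "gc150_cryptic"), vals("WT", "gc150_cryptic"),
        n_boot=fcfg["n_boot"], seed=subseed[3], metric="gc150_cryptic",
        groups=("MT", "WT"))
    reports.append(r_gc_boot)
    add_rank("gc150_cryptic", vals("MT", "gc150_cryptic"),
                    vals("WT", "gc150_cryptic"), ("MT", "WT"))
    add_rank("intron_length", vals("MT", "intron_length"),
             vals("WT", "intron_length"), ("MT", "WT"))
    add_rank("distance", vals("MT", "distance"), vals("WT", "distance"), ("MT", "WT"))
    add_rank("score3ss_canonical", vals("MT", "score3ss_canonical"),
                           vals("WT", "score3ss_canonical"), ("MT", "WT"))
    add_rank("score3ss_cryptic", vals("MT", "score3ss_cryptic"),
             vals("WT", "score3ss_cryptic"), ("MT", "WT"))

    mags = {k: [nag[j].magnitude for j in groups[k]] for k in ("MT", "WT", "control")}
    add_rank("nag_magnitude", mags["MT"], mags["WT"], ("MT", "WT"))
    ra = [nag[j].r_a for k in ("MT", "WT") for j in groups[k]]
    rn = [nag[j].r_n for k in ("MT", "WT") for j in groups[k]]
    r_an = rank_compare([ra, rn], paired=True, labels=("r_A", "r_N"),
                        metric="r_A_vs_r_N")
    reports.append(r_an)

    def srows(klass, col):
        return [r[col] for r in structure_rows if r["klass"] == klass]

    add_rank("ensemble_diversity", srows("MT", "ensemble_diversity"),
                    srows("WT", "ensemble_diversity"), ("MT", "WT"))
    add_rank("paired_bases", srows("MT", "paired_bases"),
                    srows("WT", "paired_bases"), ("MT", "WT"))

    summary = {
        "version": __version__,
        "seed": seed,
        "n_junctions": {k: len(v) for k, v in groups.items()},
        "classification": {
            "n_sensitive": len(detected),
            "n_resistant": len(resistant),
            "precision": precision,
            "recall": recall,
            "overlap_observed": obs,
            "overlap_p": overlap_p,
        },
        "sequence_features": {
            "gc150_cryptic_mean": {k: float(np.mean(vals(k, "gc150_cryptic")))
                                   for k in ("MT", "WT")},
            "intron_length_mean": {k: float(np.mean(vals(k, "intron_length")))
                                   for k in ("MT", "WT")},
            "distance_mean": {k: float(np.mean(vals(k, "distance")))
                              for k in ("MT", "WT")},
            "score3ss_canonical_mean": {k: float(np.mean(vals(k, "score3ss_canonical")))
                                        for k in ("MT", "WT")},
            "score3ss_cryptic_mean": {k: float(np.mean(vals(k, "score3ss_cryptic")))
                                      for k in ("MT", "WT")},
        },
        "shape": {
            "magnitude_mean": {k: float(np.mean(v)) for k, v in mags.items() if v},
            "r_a_mean": float(np.mean(ra)),
            "r_n_mean": float(np.mean(rn)),
        },
        "structure": {
            "paired_bases_mean": {k: float(np.mean(srows(k, "paired_bases")))
                                  for k in ("MT", "WT", "control") if srows(k, "paired_bases")},
            "ensemble_diversity_mean": {k: float(np.mean(srows(k, "ensemble_diversity")))
                                        for k in ("MT", "WT", "control")
                                        if srows(k, "ensemble_diversity")},
        },
        "comparisons": [r.to_dict() for r in reports],
    }

    if outdir is not None:
        _write_outputs(outdir, cfg, synth_cfg, regions, truth, events_per_dataset,
                       junctions, mut_profiles, reactivities, sensitive, resistant,
                       feats, nag, structure_rows, comp_profiles, dotbrackets,
                       group_profiles, summary)
    log.info("pipeline finished in %.1fs", time.time() - t_start)
    return summary


def _write_outputs(outdir, cfg, synth_cfg, regions, truth, events_per_dataset,
                   junctions, mut_profiles, reactivities, sensitive, resistant,
                   feats, nag, structure_rows, comp_profiles, dotbrackets,
                   group_profiles, summary):
    import pandas as pd
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_regions_fasta(regions, out / "regions.fasta")
    truth.to_json(out / "truth.json")
    for d, events in enumerate(events_per_dataset):
        io.write_events_tsv(events, out / f"events_ds{d}.tsv")
    io.write_junctions_tsv(junctions, out / "junctions.tsv")
    io.write_annotation_gff3(truth, out / "annotation.gff3")
    io.write_mutation_counts_tsv(mut_profiles, out / "mutation_counts.tsv")
    io.write_reactivity_tsv(list(reactivities.values()), out / "reactivity.tsv")
    io.write_dotbrackets(dotbrackets, out / "structures.dbn")

    cls_rows = [{"chrom": k[0], "strand": k[1], "cryptic_acceptor": k[2],
                 "klass": "MT", "n_datasets": len(ds)} for k, ds in sorted(sensitive.items())]
    cls_rows += [{"chrom": k[0], "strand": k[1], "cryptic_acceptor": k[2],
                  "klass": "WT", "n_datasets": 0} for k in sorted(resistant)]
    pd.DataFrame(cls_rows).to_csv(out / "classified.tsv", sep="\t", index=False)

    feat_rows = [dict(row, klass=klass) for klass in feats for row in feats[klass]]
    pd.DataFrame(feat_rows).to_csv(out / "feature_matrix.tsv", sep="\t", index=False)
    nag_rows = [{"junction_id": s.junction_id, "r_n": s.r_n, "r_a": s.r_a,
                 "r_g": s.r_g, "region_median": s.region_median,
                 "magnitude": s.magnitude} for s in nag.values()]
    pd.DataFrame(nag_rows).to_csv(out / "fig3h.tsv", sep="\t", index=False)
    df_feat = pd.DataFrame(feat_rows)
    if not df_feat.empty:
        df_feat[["junction_id", "klass", "gc150_cryptic"]].to_csv(
            out / "fig1d.tsv", sep="\t", index=False)
        df_feat[["junction_id", "klass", "intron_length"]].to_csv(
            out / "fig1e.tsv", sep="\t", index=False)
        df_feat[["junction_id", "klass", "distance"]].to_csv(
            out / "fig1f.tsv", sep="\t", index=False)
        df_feat[["junction_id", "klass", "score3ss_cryptic",
                 "score3ss_canonical"]].to_csv(out / "fig2a.tsv", sep="\t", index=False)
    df_struct = pd.DataFrame(structure_rows)
    df_struct[["junction_id", "klass", "ensemble_diversity"]].to_csv(
        out / "fig5d.tsv", sep="\t", index=False)
    df_struct[["junction_id", "klass", "paired_bases"]].to_csv(
        out / "fig5e.tsv", sep="\t", index=False)
    gp_frames = []
    for klass, gp in group_profiles.items():
        gp_frames.append(pd.DataFrame({
            "klass": klass, "position": gp.positions, "mean": gp.mean,
            "median": gp.median, "se": gp.se, "n": gp.n}))
    pd.concat(gp_frames, ignore_index=True).to_csv(
        out / "fig3fg_group_reactivity.tsv", sep="\t", index=False,
        float_format="%.6g")
    for klass, prof in comp_profiles.items():
        pd.DataFrame(prof.probs, columns=list("ACGU")).assign(
            position=prof.positions).to_csv(
            out / f"composition_{klass}.tsv", sep="\t", index=False)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"splicefold {__version__}\nseed: {summary['seed']}\n")
        fh.write(f"config: {json.dumps(cfg, sort_keys=True, default=str)}\n")
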