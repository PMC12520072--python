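"""Readers and writers for the pipeline's file formats.

FASTA splice regions (Biopython), TSV event tables and junction records
(pandas), shapemapper-style mutation-count tables, reactivity profiles as
rich TSV and two-column ``.shape`` files (-999 = no data), dot-bracket
structure files, and a minimal GFF3 of exon features for the transcript
model."""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import EventRecord, JunctionRecord
from .features import SpliceRegion
from .shape import MutationCountProfile, ReactivityProfile

NO_DATA = -999.0


# -- splice regions ----------------------------------------------------------

def write_regions_fasta(regions, path) -> None:
    records = []
    for r in regions:
        desc = (f"class={r.klass} role={r.site_role} site_index={r.site_index} "
                f"intron_length={r.intron_length} partner_offset={r.partner_offset}")
        records.append(SeqRecord(Seq(r.sequence), id=r.junction_id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_regions_fasta(path):
    regions = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = dict(item.split("=", 1) for item in rec.description.split()[1:])
        off = meta.get("partner_offset", "None")
        regions.append(SpliceRegion(
            junction_id=rec.id, klass=meta["class"], site_role=meta["role"],
            sequence=str(rec.seq), site_index=int(meta["site_index"]),
            intron_length=int(meta["intron_length"]),
            partner_offset=None if off == "None" else int(off)))
    return regions


# -- event tables ------------------------------------------------------------

_EVENT_COLS = ["dataset", "junction_id", "gene", "chrom", "strand", "donor",
               "canonical_acceptor", "cryptic_acceptor", "inc_wt", "skip_wt",
               "inc_mut", "skip_mut", "psi_wt", "psi_mut", "pvalue", "fdr", "dpsi"]


def events_to_frame(events) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append({
            "dataset": ev.dataset_id, "junction_id": ev.junction_id, "gene": ev.gene,
            "chrom": ev.chrom, "strand": ev.strand, "donor": ev.donor_pos,
            "canonical_acceptor": ev.canonical_acceptor,
            "cryptic_acceptor": ev.cryptic_acceptor,
            "inc_wt": ",".join(map(str, ev.inc_wt)),
            "skip_wt": ",".join(map(str, ev.skip_wt)),
            "inc_mut": ",".join(map(str, ev.inc_mut)),
            "skip_mut": ",".join(map(str, ev.skip_mut)),
            "psi_wt": ev.psi_wt, "psi_mut": ev.psi_mut,
            "pvalue": ev.pvalue, "fdr": ev.fdr, "dpsi": ev.dpsi,
        })
    return pd.DataFrame(rows, columns=_EVENT_COLS)


def write_events_tsv(events, path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def _counts(cell) -> tuple:
    if isinstance(cell, float) and np.isnan(cell):
        return ()
    cell = str(cell)
    return tuple(int(x) for x in cell.split(",")) if cell else ()


def read_events_tsv(path):
    df = pd.read_csv(path, sep="\t")
    events = []
    for _, row in df.iterrows():
        events.append(EventRecord(
            dataset_id=str(row["dataset"]), gene=str(row["gene"]),
            chrom=str(row["chrom"]), strand=str(row["strand"]),
            donor_pos=int(row["donor"]),
            canonical_acceptor=int(row["canonical_acceptor"]),
            cryptic_acceptor=int(row["cryptic_acceptor"]),
            psi_wt=float(row["psi_wt"]), psi_mut=float(row["psi_mut"]),
            pvalue=float(row["pvalue"]), fdr=float(row["fdr"]),
            dpsi=float(row["dpsi"]),
            inc_wt=_counts(row["inc_wt"]), skip_wt=_counts(row["skip_wt"]),
            inc_mut=_counts(row["inc_mut"]), skip_mut=_counts(row["skip_mut"]),
            junction_id=str(row["junction_id"])))
    return events


# -- junction records --------------------------------------------------------

def write_junctions_tsv(junctions, path) -> None:
    df = pd.DataFrame([{
        "chrom": j.chrom, "intron_start": j.intron_start, "intron_end": j.intron_end,
        "strand": j.strand, "read_count": j.read_count, "min_anchor": j.min_anchor,
        "annotation": j.annotation,
    } for j in junctions])
    df.to_csv(path, sep="\t", index=False)


def read_junctions_tsv(path):
    df = pd.read_csv(path, sep="\t")
    return [JunctionRecord(str(r["chrom"]), str(r["strand"]), int(r["intron_start"]),
                           int(r["intron_end"]), int(r["read_count"]),
                           int(r["min_anchor"]), str(r["annotation"]))
            for _, r in df.iterrows()]


# -- annotation --------------------------------------------------------------

def write_annotation_gff3(truth, path, exon_len: int = 100) -> None:
    """Minimal exon-only GFF3 for the planted transcript model: one
    upstream exon ending at the donor and one downstream exon starting at
    the canonical acceptor per junction."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in truth.junctions:
            don, acc = t.donor_pos, t.canonical_acceptor
            gid = t.junction_id
            fh.write(f"{t.chrom}\tsynthetic\texon\t{don - exon_len + 1}\t{don}\t.\t"
                     f"{t.strand}\t.\tID=exon:{gid}.1;Parent={gid}\n")
            fh.write(f"{t.chrom}\tsynthetic\texon\t{acc + 1}\t{acc + exon_len}\t.\t"
                     f"{t.strand}\t.\tID=exon:{gid}.2;Parent={gid}\n")


# -- mutation counts and reactivities ----------------------------------------

def write_mutation_counts_tsv(profiles, path) -> None:
    frames = []
    for p in profiles:
        frames.append(pd.DataFrame({
            "junction_id": p.junction_id, "replicate": p.replicate,
            "position": p.positions, "mod_mut": p.mod_mut, "mod_depth": p.mod_depth,
            "unt_mut": p.unt_mut, "unt_depth": p.unt_depth,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_mutation_counts_tsv(path):
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for (jid, rep), grp in df.groupby(["junction_id", "replicate"], sort=False):
        profiles.append(MutationCountProfile(
            junction_id=str(jid), positions=grp["position"].to_numpy(),
            mod_mut=grp["mod_mut"].to_numpy(), mod_depth=grp["mod_depth"].to_numpy(),
            unt_mut=grp["unt_mut"].to_numpy(), unt_depth=grp["unt_depth"].to_numpy(),
            replicate=int(rep)))
    return profiles


def write_reactivity_tsv(profiles, path) -> None:
    frames = []
    for p in profiles:
        frames.append(pd.DataFrame({
            "junction_id": p.junction_id, "position": p.positions,
            "reactivity": np.where(p.mask, np.nan, p.values),
            "se": np.where(p.mask, np.nan, p.se), "masked": p.mask.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format="%.6g")


def write_shape_file(profile, path) -> None:
    """Two-column ``.shape`` format: 1-based index, reactivity (-999 = no
    data), in position order."""
    with open(path, "w") as fh:
        for i, (v, m) in enumerate(zip(profile.values, profile.mask), start=1):
            fh.write(f"{i}\t{NO_DATA if m or not np.isfinite(v) else round(float(v), 6)}\n")


def read_shape_file(path, junction_id: str = "", positions=None) -> ReactivityProfile:
    vals = []
    for line in open(path):
        parts = line.split()
        if len(parts) >= 2:
            vals.append(float(parts[1]))
    vals = np.array(vals)
    mask = vals == NO_DATA
    vals[mask] = np.nan
    if positions is None:
        positions = np.arange(1, len(vals) + 1)
    return ReactivityProfile(junction_id, np.asarray(positions), vals,
                             np.full(len(vals), np.nan), mask, normalized=True)


# -- structures --------------------------------------------------------------

def write_dotbrackets(entries, path) -> None:
    """Vienna-style file: per structure a header line, sequence line, and
    dot-bracket line with the free energy."""
    with open(path, "w") as fh:
        for name, seq, structure in entries:
            fh.write(f">{name}\n{seq}\n{structure.dotbracket} ({structure.energy:.2f})\n")
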