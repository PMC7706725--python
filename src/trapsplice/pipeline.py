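"""End-to-end orchestration: PSI -> events -> differential calls ->
triplets -> conservation -> exon features -> k-mer enrichment, with a
manifest recording config, seed, and output digests.

Stages run single-process in a fixed order; all randomness flows from the
one top-level seed in the run configuration.  Re-running a completed
manifest with identical inputs performs no recomputation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass

import pandas as pd

from . import __version__
from .conservation import assess_conservation, conservation_rate_compare, extract_triplets, window_profile
from .events import (
    build_splice_graph,
    call_differential,
    classify_events,
    enumerate_events,
    events_to_frame,
    quantify_events,
)
from .features import (
    detect_microexons,
    feature_overlap_rates,
    frame_and_length_stats,
    map_exon_to_protein,
    records_from_triplets,
)
from .motifs import enrich_kmers, extract_event_regions
from .psi import call_alternative_junctions, compute_psi, detect_tissue_enriched
from .simulate import SimulationConfig, SimulatedStudy, simulate_study

logger = logging.getLogger("trapsplice")

STAGES = (
    "psi",
    "enriched",
    "events",
    "diff",
    "triplets",
    "conservation",
    "features",
    "enrichment",
)


@dataclass
class RunConfig:
    seed: int = 0
    sim: SimulationConfig | None = None
    min_group_reads: int = 10
    minor_psi_min: float = 0.05
    min_event_reads: int = 10
    differential_min: float = 0.20
    switch_min: float = 0.80
    enriched_min_reads: int = 5
    enriched_strict: bool = False
    flank_len: int = 23
    smooth: int = 3
    kmer_k: tuple[int, ...] = (6,)
    motif_flank: int = 150

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    out_dir: str,
    config: RunConfig | None = None,
    study: SimulatedStudy | None = None,
) -> dict:
    """Run every stage on a simulated study and write the report directory.

    Returns the manifest.  If a manifest from an identical (config, seed)
    run exists in ``out_dir`` and all recorded digests still match, nothing
    is recomputed.
    """
    config = config or RunConfig()
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.json")
    config_snapshot = json.dumps(config.to_dict(), sort_keys=True, default=str)
    if os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            prev = json.load(fh)
        if prev.get("config_snapshot") == config_snapshot and all(
            os.path.exists(os.path.join(out_dir, f)) and _digest(os.path.join(out_dir, f)) == dg
            for f, dg in prev.get("digests", {}).items()
        ):
            logger.info("manifest up to date; nothing to do")
            return prev

    t0 = time.time()
    stage_records: dict[str, dict] = {}

    def record(stage: str, started: float, **extra) -> None:
        stage_records[stage] = {"seconds": round(time.time() - started, 3), **extra}
        logger.info("stage %s done in %.2fs", stage, stage_records[stage]["seconds"])

    if study is None:
        sim_cfg = config.sim or SimulationConfig(seed=config.seed)
        study = simulate_study(sim_cfg)
    table = study.counts
    genes = study.genes

    # --- psi ---------------------------------------------------------------
    t = time.time()
    psi = compute_psi(table, min_group_reads=config.min_group_reads, pool_by="tissue")
    _write_tsv(psi.sort_values(["junction", "unit"], ignore_index=True),
               os.path.join(out_dir, "psi.tsv"))
    alt_groups = call_alternative_junctions(psi, config.minor_psi_min)
    record("psi", t, n_records=len(psi), n_alternative_groups=len(alt_groups))

    # --- tissue-enriched junctions ----------------------------------------
    t = time.time()
    enriched_frames = []
    for tissue in table.tissues(fraction="IP"):
        enriched_frames.append(
            detect_tissue_enriched(
                table, tissue, config.enriched_min_reads, strict=config.enriched_strict
            )
        )
    enriched = pd.concat(enriched_frames, ignore_index=True)
    _write_tsv(enriched, os.path.join(out_dir, "enriched.tsv"))
    record("enriched", t, n_calls=len(enriched))

    # --- events ------------------------------------------------------------
    t = time.time()
    retention_by_gene: dict[str, dict[tuple[int, int], int]] = {}
    for i, j in enumerate(study.retention.junctions):
        total = int(study.retention.counts[i].sum())
        for gid, g in genes.items():
            span = g.span
            if j.chrom == g.chrom and j.strand == g.strand and span.start <= j.start and j.end <= span.end:
                retention_by_gene.setdefault(gid, {})[(j.start, j.end)] = total
    all_events = []
    n_orphans = 0
    for gid in sorted(genes):
        g = genes[gid]
        span = g.span
        observed = [
            jx for jx in table.junctions
            if jx.chrom == g.chrom and jx.strand == g.strand
            and span.start <= jx.start and jx.end <= span.end
        ]
        graph = build_splice_graph(g, observed, retention_by_gene.get(gid))
        n_orphans += len(graph.orphans)
        events = enumerate_events(graph)
        classify_events(events, graph)
        all_events.extend(events)
    quantify_events(all_events, table, study.retention, config.min_event_reads)
    _write_tsv(events_to_frame(all_events), os.path.join(out_dir, "events.tsv"))
    record("events", t, n_events=len(all_events), n_orphans=n_orphans)

    # --- differential calls -------------------------------------------------
    t = time.time()
    ip_tissues = table.tissues(fraction="IP")
    diff_frames = []
    for i, ta in enumerate(ip_tissues):
        for tb in ip_tissues[i + 1 :]:
            diff_frames.append(
                call_differential(
                    all_events, ta, tb, config.differential_min, config.switch_min
                )
            )
    diff = pd.concat(diff_frames, ignore_index=True)
    _write_tsv(diff, os.path.join(out_dir, "differential.tsv"))
    record(
        "diff",
        t,
        n_calls=len(diff),
        n_differential_events=int(diff.loc[diff.differential, "event_id"].nunique()),
        n_switch_events=int(diff.loc[diff.switch_like, "event_id"].nunique()),
    )

    # --- exon triplets ------------------------------------------------------
    t = time.time()
    triplets = extract_triplets(genes, all_events, diff)
    trip_rows = [
        (
            tr.gene_id, tr.class_label, tr.chrom, tr.strand,
            tr.internal_exon.start, tr.internal_exon.end,
            len(tr.internal_exon), len(tr.upstream_intron), len(tr.downstream_intron),
        )
        for tr in triplets
    ]
    trip_df = pd.DataFrame(
        trip_rows,
        columns=[
            "gene_id", "class_label", "chrom", "strand", "exon_start", "exon_end",
            "exon_len", "upstream_intron_len", "downstream_intron_len",
        ],
    )
    _write_tsv(trip_df, os.path.join(out_dir, "triplets.tsv"))
    record("triplets", t, n_triplets=len(triplets))

    # --- conservation -------------------------------------------------------
    t = time.time()
    aln_by_region = {(a.ref_chrom, a.ref_start): a for a in study.alignments}

    def find_alignment(tr):
        lo, hi = tr.span
        for (chrom, start), a in aln_by_region.items():
            if chrom == tr.chrom and start <= lo and hi <= start + len(a.reference_map):
                return a
        return None

    calls_rows = []
    calls_by = {}
    species = sorted(study.config.phylogeny)
    for tr in triplets:
        aln = find_alignment(tr)
        if aln is None:
            continue
        for sp in species:
            call = assess_conservation(tr, aln, sp)
            calls_rows.append(
                (tr.gene_id, tr.class_label, sp, call.conserved)
            )
            calls_by.setdefault((tr.class_label, sp), []).append(call)
    cons_df = pd.DataFrame(
        calls_rows, columns=["gene_id", "class_label", "species", "conserved"]
    )
    _write_tsv(cons_df, os.path.join(out_dir, "conservation.tsv"))
    rate_rows = []
    for sp in species:
        a = calls_by.get(("alt_tissue_regulated", sp), [])
        b = calls_by.get(("alt_non_tissue", sp), [])
        if a and b:
            ra, rb, p = conservation_rate_compare(a, b)
            rate_rows.append((sp, ra, rb, p))
    rates_df = pd.DataFrame(
        rate_rows,
        columns=["species", "regulated_rate", "non_tissue_rate", "fisher_p"],
    )
    _write_tsv(rates_df, os.path.join(out_dir, "conservation_rates.tsv"))
    profiles, prof_tests = window_profile(
        study.conservation, triplets, config.flank_len, config.smooth
    )
    prof_rows = [
        (cls, region, int(p), float(m), float(r), int(n))
        for (cls, region), prof in sorted(profiles.items())
        for p, m, r, n in zip(prof.positions, prof.mean, prof.raw_mean, prof.n)
    ]
    prof_df = pd.DataFrame(
        prof_rows, columns=["class_label", "region", "position", "mean", "raw_mean", "n"]
    )
    _write_tsv(prof_df, os.path.join(out_dir, "profiles.tsv"))
    _write_tsv(prof_tests, os.path.join(out_dir, "profile_tests.tsv"))
    record("conservation", t, n_calls=len(cons_df))

    # --- exon features ------------------------------------------------------
    t = time.time()
    records = records_from_triplets(triplets)
    with_protein = []
    for rec, tr in zip(records, triplets):
        gene = genes[tr.gene_id]
        cds = next(iter(gene.cds.values()), None)
        aa = map_exon_to_protein(tr.internal_exon, cds, gene.strand) if cds else None
        with_protein.append(dataclasses.replace(rec, protein_interval=aa))
    stats_out = frame_and_length_stats(with_protein)
    overlaps = feature_overlap_rates(with_protein, study.protein_features)
    micro, micro_prov = detect_microexons(with_protein)
    feat_rows = [
        (
            r.class_label, r.exon.chrom, r.exon.start, r.exon.end, r.length,
            r.frame_preserving, r.is_microexon,
            r.protein_interval[0] if r.protein_interval else "",
            r.protein_interval[1] if r.protein_interval else "",
        )
        for r in with_protein
    ]
    feat_df = pd.DataFrame(
        feat_rows,
        columns=[
            "class_label", "chrom", "start", "end", "length",
            "frame_preserving", "is_microexon", "aa_start", "aa_end",
        ],
    )
    _write_tsv(feat_df, os.path.join(out_dir, "features.tsv"))
    record("features", t, n_records=len(with_protein), n_microexons=len(micro))

    # --- k-mer enrichment ---------------------------------------------------
    t = time.time()
    diff_ids = set(diff.loc[diff.differential, "event_id"])
    target_events = [
        ev for ev in all_events if ev.event_class == "cassette" and ev.event_id in diff_ids
    ]
    bg_events = [
        ev for ev in all_events
        if ev.event_class == "cassette" and ev.event_id not in diff_ids
    ]
    if target_events and bg_events:
        target = extract_event_regions(
            target_events, study.genome, config.motif_flank, "regulated"
        )
        background = extract_event_regions(
            bg_events, study.genome, config.motif_flank, "background"
        )
        kmers = enrich_kmers(target, background, config.kmer_k)
    else:
        kmers = pd.DataFrame()
    _write_tsv(kmers.head(200), os.path.join(out_dir, "kmers.tsv"))
    record("enrichment", t, n_kmers=len(kmers))

    # --- summary and manifest ----------------------------------------------
    class_counts = (
        pd.Series([ev.event_class for ev in all_events]).value_counts().to_dict()
    )
    summary = {
        "n_junctions": table.n_junctions,
        "n_events": len(all_events),
        "event_class_counts": class_counts,
        "n_alternative_groups": len(alt_groups),
        "n_tissue_enriched_calls": int(len(enriched)),
        "n_differential_events": stage_records["diff"]["n_differential_events"],
        "n_switch_events": stage_records["diff"]["n_switch_events"],
        "n_triplets": len(triplets),
        "triplet_class_counts": trip_df["class_label"].value_counts().to_dict(),
        "conservation_rates": rate_rows and {
            r[0]: {"regulated": r[1], "non_tissue": r[2], "fisher_p": r[3]}
            for r in rate_rows
        },
        "frame_rates": stats_out["frame_rate"],
        "n_microexons": micro_prov["n_microexons"],
        "overlap_rates": overlaps["rates"],
    }
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)

    outputs = sorted(
        f for f in os.listdir(out_dir) if f.endswith((".tsv", ".json")) and f != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_snapshot": config_snapshot,
        "stages": stage_records,
        "digests": {f: _digest(os.path.join(out_dir, f)) for f in outputs},
        "total_seconds": round(time.time() - t0, 3),
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
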