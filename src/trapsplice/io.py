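"""Readers and writers for the standard formats the pipeline touches.

Every reader converts to the internal 0-based half-open convention at the
boundary: STAR ``SJ.out.tab`` intron coordinates are 1-based inclusive, GTF
records 1-based inclusive, fixed-step wiggle 1-based; bedGraph is already
0-based half-open.
"""

from __future__ import annotations

import os
import warnings
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from .core import (
    ConservationTrack,
    GeneModel,
    GenomicInterval,
    JunctionCountTable,
    SampleMeta,
    SpeciesAlignment,
    SpliceJunction,
)

_STAR_STRAND = {0: "+", 1: "+", 2: "-"}
_STAR_STRAND_CODE = {"+": 1, "-": 2}


class FormatError(ValueError):
    """A malformed record in an input file."""


# ---------------------------------------------------------------------------
# junction count tables
# ---------------------------------------------------------------------------

def _parse_star_sj_line(line: str, lineno: int, path: str) -> tuple[SpliceJunction, int]:
    fields = line.split()
    if len(fields) < 7:
        raise FormatError(f"{path}:{lineno}: expected >=7 columns, got {len(fields)}")
    try:
        chrom = fields[0]
        first = int(fields[1])  # 1-based first intronic base
        last = int(fields[2])  # 1-based last intronic base
        strand_code = int(fields[3])
        annotated = bool(int(fields[5]))
        unique = int(fields[6])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if strand_code not in _STAR_STRAND:
        raise FormatError(f"{path}:{lineno}: bad strand code {strand_code}")
    iv = GenomicInterval(chrom, first - 1, last, _STAR_STRAND[strand_code])
    jx = SpliceJunction(iv, annotated=annotated, strand_undefined=strand_code == 0)
    return jx, unique


def read_junction_counts(
    paths: str | Sequence[str],
    dialect: str = "star_sj",
    samples: Sequence[SampleMeta] | None = None,
) -> JunctionCountTable:
    """Read junction read counts.

    ``star_sj``: one STAR ``SJ.out.tab`` file per sample (only the
    uniquely-mapped read column is used); files are merged on junction
    identity (chrom, start, end, strand).  ``generic_tsv``: a single TSV
    with columns chrom, start, end, strand followed by one count column per
    sample, the column name encoding ``sample_id:tissue:fraction:replicate``
    (a bare name is treated as an IP sample of its own tissue).
    """
    if dialect == "star_sj":
        if isinstance(paths, (str, os.PathLike)):
            paths = [paths]
        paths = [str(p) for p in paths]
        if samples is not None and len(samples) != len(paths):
            raise ValueError("one SampleMeta per SJ file required")
        if samples is None:
            samples = [
                SampleMeta(os.path.splitext(os.path.basename(p))[0], tissue=f"sample{i}",
                           fraction="IP", replicate=1)
                for i, p in enumerate(paths, start=1)
            ]
        per_file: list[dict[tuple, int]] = []
        junctions: dict[tuple, SpliceJunction] = {}
        for path in paths:
            counts: dict[tuple, int] = {}
            with open(path) as fh:
                for lineno, line in enumerate(fh, start=1):
                    if not line.strip():
                        continue
                    jx, unique = _parse_star_sj_line(line, lineno, path)
                    junctions.setdefault(jx.key, jx)
                    counts[jx.key] = counts.get(jx.key, 0) + unique
            per_file.append(counts)
        keys = sorted(junctions)
        mat = np.zeros((len(keys), len(paths)), dtype=np.int64)
        for si, counts in enumerate(per_file):
            for ji, key in enumerate(keys):
                mat[ji, si] = counts.get(key, 0)
        return JunctionCountTable([junctions[k] for k in keys], list(samples), mat)

    if dialect == "generic_tsv":
        if not isinstance(paths, (str, os.PathLike)):
            raise ValueError("generic_tsv expects a single path")
        df = pd.read_csv(paths, sep="\t", dtype={"chrom": str})
        required = ["chrom", "start", "end", "strand"]
        if list(df.columns[:4]) != required:
            raise FormatError(
                f"{paths}: generic_tsv must start with columns {required}"
            )
        metas = []
        for col in df.columns[4:]:
            parts = str(col).split(":")
            if len(parts) == 4:
                metas.append(SampleMeta(parts[0], parts[1], parts[2], int(parts[3])))
            else:
                metas.append(SampleMeta(str(col), tissue=str(col), fraction="IP", replicate=1))
        junctions = [
            SpliceJunction(GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand))
            for row in df.itertuples(index=False)
        ]
        mat = df.iloc[:, 4:].to_numpy(dtype=np.int64)
        return JunctionCountTable(junctions, metas, mat)

    raise ValueError(f"unknown dialect {dialect!r}")


def write_junction_counts(table: JunctionCountTable, path: str) -> None:
    """Write a table as generic TSV (deterministic row order)."""
    table = table.sorted()
    cols = {
        "chrom": [j.chrom for j in table.junctions],
        "start": [j.start for j in table.junctions],
        "end": [j.end for j in table.junctions],
        "strand": [j.strand for j in table.junctions],
    }
    df = pd.DataFrame(cols)
    for i, s in enumerate(table.samples):
        df[f"{s.sample_id}:{s.tissue}:{s.fraction}:{s.replicate}"] = table.counts[:, i]
    df.to_csv(path, sep="\t", index=False)


def write_star_sj(table: JunctionCountTable, path: str, sample_index: int = 0) -> None:
    """Write one sample back in STAR SJ.out.tab coordinates (involution check)."""
    with open(path, "w") as fh:
        for i, j in enumerate(table.junctions):
            code = 0 if j.strand_undefined else _STAR_STRAND_CODE[j.strand]
            fh.write(
                f"{j.chrom}\t{j.start + 1}\t{j.end}\t{code}\t0\t{int(j.annotated)}\t"
                f"{table.counts[i, sample_index]}\t0\t0\n"
            )


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str) -> dict[str, GeneModel]:
    """Read GTF/GFF3 gene models into 0-based half-open exon intervals."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        verbose=False,
    )
    genes: dict[str, GeneModel] = {}
    n_exons_assigned = 0
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        transcripts: dict[str, list[GenomicInterval]] = {}
        cds: dict[str, list[tuple[GenomicInterval, int]]] = {}
        for t in db.children(gene, featuretype=("transcript", "mRNA"), level=1):
            exons = []
            for ex in db.children(t, featuretype="exon", order_by="start"):
                exons.append(GenomicInterval(ex.seqid, ex.start - 1, ex.end, gene.strand))
                n_exons_assigned += 1
            if exons:
                transcripts[t.id] = exons
            parts = []
            for c in db.children(t, featuretype="CDS", order_by="start"):
                phase = 0 if c.frame in (None, ".") else int(c.frame)
                parts.append((GenomicInterval(c.seqid, c.start - 1, c.end, gene.strand), phase))
            if parts:
                cds[t.id] = parts
        if transcripts:
            genes[gene_id] = GeneModel(gene_id, gene.seqid, gene.strand, transcripts, cds)
    n_exons_total = sum(1 for _ in db.features_of_type("exon"))
    if n_exons_assigned < n_exons_total:
        raise FormatError(
            f"{path}: {n_exons_total - n_exons_assigned} exon records lack a "
            "transcript parent"
        )
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str, source: str = "trapsplice") -> None:
    """Write gene models as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            span = g.span
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for tid in g.transcripts:
                exons = g.transcripts[tid]
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
                fh.write(
                    f"{g.chrom}\t{source}\ttranscript\t{exons[0].start + 1}\t"
                    f"{exons[-1].end}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for ex in exons:
                    fh.write(
                        f"{g.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{g.strand}\t.\t{tattrs}\n"
                    )
                for iv, phase in g.cds.get(tid, []):
                    fh.write(
                        f"{g.chrom}\t{source}\tCDS\t{iv.start + 1}\t{iv.end}\t.\t"
                        f"{g.strand}\t{phase}\t{tattrs}\n"
                    )


# ---------------------------------------------------------------------------
# multiple alignments (MAF)
# ---------------------------------------------------------------------------

def read_alignment_maf(path: str, reference_species: str) -> list[SpeciesAlignment]:
    """Read MAF blocks; blocks lacking the reference are dropped (warning)."""
    alignments: list[SpeciesAlignment] = []
    dropped = 0
    for block in AlignIO.parse(str(path), "maf"):
        lengths = {len(rec.seq) for rec in block}
        if len(lengths) > 1:
            raise FormatError(f"{path}: unequal gapped row lengths in a block")
        rows: dict[str, str] = {}
        ref_rec = None
        for rec in block:
            species = rec.id.split(".", 1)[0]
            rows[species] = str(rec.seq).upper()
            if species == reference_species:
                ref_rec = rec
        if ref_rec is None:
            dropped += 1
            continue
        ann = ref_rec.annotations
        start = int(ann.get("start", 0))
        size = int(ann.get("size", len(str(ref_rec.seq).replace("-", ""))))
        strand = "+" if int(ann.get("strand", 1)) >= 0 else "-"
        if strand == "-":
            src_size = int(ann.get("srcSize", 0))
            start = src_size - start - size
        chrom = ref_rec.id.split(".", 1)[1] if "." in ref_rec.id else None
        alignments.append(
            SpeciesAlignment(rows, reference_species, ref_chrom=chrom,
                             ref_start=start, ref_strand=strand)
        )
    if dropped:
        warnings.warn(f"{path}: dropped {dropped} MAF block(s) lacking "
                      f"reference species {reference_species!r}")
    return alignments


def write_alignment_maf(alignments: Iterable[SpeciesAlignment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for aln in alignments:
            fh.write("\na score=0.0\n")
            for species, row in aln.rows.items():
                ungapped = row.replace("-", "")
                if species == aln.reference_species:
                    src = f"{species}.{aln.ref_chrom or 'chr'}"
                    start = aln.ref_start
                else:
                    src = f"{species}.region"
                    start = 0
                fh.write(
                    f"s {src:<24} {start} {len(ungapped)} + {start + len(ungapped)} {row}\n"
                )


# ---------------------------------------------------------------------------
# conservation tracks
# ---------------------------------------------------------------------------

def read_conservation_track(path: str) -> ConservationTrack:
    """Read per-base scores from bedGraph or fixed/variable-step wiggle."""
    track = ConservationTrack()
    clobbered = 0
    mode = "bedgraph"
    chrom = ""
    pos = 0
    step = 1
    span = 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                mode = "fixed"
                params = dict(kv.split("=") for kv in line.split()[1:])
                chrom = params["chrom"]
                pos = int(params["start"]) - 1  # wiggle is 1-based
                step = int(params.get("step", 1))
                span = int(params.get("span", 1))
                continue
            if line.startswith("variableStep"):
                mode = "variable"
                params = dict(kv.split("=") for kv in line.split()[1:])
                chrom = params["chrom"]
                span = int(params.get("span", 1))
                continue
            fields = line.split()
            try:
                if mode == "bedgraph":
                    if len(fields) != 4:
                        raise ValueError(f"expected 4 columns, got {len(fields)}")
                    clobbered += track.set_range(
                        fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                    )
                elif mode == "fixed":
                    clobbered += track.set_range(chrom, pos, pos + span, float(fields[0]))
                    pos += step
                else:
                    start = int(fields[0]) - 1
                    clobbered += track.set_range(chrom, start, start + span, float(fields[1]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if clobbered:
        warnings.warn(f"{path}: {clobbered} overlapping position(s); last record wins")
    return track


def write_conservation_bedgraph(track: ConservationTrack, path: str) -> None:
    """Write a track as bedGraph, merging runs of equal consecutive scores."""
    with open(path, "w") as fh:
        for chrom in track.chroms():
            run_start = None
            prev_pos = None
            prev_score = None
            for pos, score in track.items(chrom):
                if run_start is not None and pos == prev_pos + 1 and score == prev_score:
                    prev_pos = pos
                    continue
                if run_start is not None:
                    fh.write(f"{chrom}\t{run_start}\t{prev_pos + 1}\t{prev_score:.6f}\n")
                run_start = pos
                prev_pos = pos
                prev_score = score
            if run_start is not None:
                fh.write(f"{chrom}\t{run_start}\t{prev_pos + 1}\t{prev_score:.6f}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
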