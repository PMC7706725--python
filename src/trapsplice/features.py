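"""Exon-class characterization: reading-frame preservation, lengths,
microexons, and overlap with protein domains / intrinsically disordered
regions (IDRs).

Protein features are consumed as precomputed intervals (TSV: protein_id,
start, end, label) in 1-based inclusive amino-acid coordinates; disorder
prediction and domain assignment are inputs, not computed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval
from .conservation import ExonTriplet

MICROEXON_MAX_NT = 27


@dataclass(frozen=True)
class ExonFeatureRecord:
    exon: GenomicInterval
    class_label: str
    length: int
    frame_preserving: bool
    is_microexon: bool
    upstream_intron_len: int | None = None
    downstream_intron_len: int | None = None
    protein_id: str | None = None
    protein_interval: tuple[int, int] | None = None  # 1-based inclusive aa
    overlaps_domain: bool | None = None
    overlaps_idr: bool | None = None
    ip_only: bool | None = None  # quantifiable only in IP (tissue-enriched) data


class ProteinFeatureTrack:
    """Labeled {domain, idr} amino-acid intervals per protein (1-based
    inclusive)."""

    LABELS = ("domain", "idr")

    def __init__(self) -> None:
        self._intervals: dict[str, list[tuple[int, int, str]]] = {}

    def add(self, protein_id: str, start: int, end: int, label: str) -> None:
        if label not in self.LABELS:
            raise ValueError(f"label must be one of {self.LABELS}, got {label!r}")
        if end < start:
            raise ValueError(f"interval end {end} < start {start}")
        self._intervals.setdefault(protein_id, []).append((start, end, label))

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._intervals

    def intervals(self, protein_id: str, label: str | None = None):
        out = self._intervals.get(protein_id, [])
        if label is not None:
            out = [iv for iv in out if iv[2] == label]
        return out

    def overlaps(self, protein_id: str, aa_start: int, aa_end: int, label: str) -> bool:
        """Any shared amino acid between [aa_start, aa_end] (inclusive) and
        a feature of ``label``."""
        return any(
            s <= aa_end and aa_start <= e
            for s, e, lab in self._intervals.get(protein_id, [])
            if lab == label
        )

    def proteins(self) -> list[str]:
        return sorted(self._intervals)


def read_protein_features(path: str) -> ProteinFeatureTrack:
    track = ProteinFeatureTrack()
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples(index=False):
        track.add(str(row.protein_id), int(row.start), int(row.end), str(row.label))
    return track


def write_protein_features(track: ProteinFeatureTrack, path: str) -> None:
    rows = [
        (pid, s, e, lab)
        for pid in track.proteins()
        for s, e, lab in sorted(track.intervals(pid))
    ]
    pd.DataFrame(rows, columns=["protein_id", "start", "end", "label"]).to_csv(
        path, sep="\t", index=False
    )


def is_frame_preserving(length: int) -> bool:
    return length % 3 == 0


def records_from_triplets(
    triplets: Sequence[ExonTriplet],
    microexon_max: int = MICROEXON_MAX_NT,
    strict_microexon: bool = False,
) -> list[ExonFeatureRecord]:
    """Feature records for the internal exon of each triplet."""
    records = []
    for t in triplets:
        length = len(t.internal_exon)
        micro = length < microexon_max if strict_microexon else length <= microexon_max
        records.append(
            ExonFeatureRecord(
                exon=t.internal_exon,
                class_label=t.class_label,
                length=length,
                frame_preserving=is_frame_preserving(length),
                is_microexon=micro,
                upstream_intron_len=len(t.upstream_intron),
                downstream_intron_len=len(t.downstream_intron),
                protein_id=t.gene_id,
            )
        )
    return records


def _chi2_2x2(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) for two proportions."""
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if obs.sum(axis=0).min() == 0 or obs.sum(axis=1).min() == 0:
        return 0.0, 1.0
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    return statistic, float(stats.chi2.sf(statistic, df=1))


def frame_and_length_stats(records: Sequence[ExonFeatureRecord]) -> dict:
    """Per-class frame-preservation rates and exon/intron length medians,
    with pairwise chi-squared (frame) and rank-sum (length) tests.

    Classes with fewer than 2 records are excluded from tests and listed
    under ``excluded``.
    """
    by_class: dict[str, list[ExonFeatureRecord]] = {}
    for r in records:
        by_class.setdefault(r.class_label, []).append(r)
    excluded = sorted(c for c, rs in by_class.items() if len(rs) < 2)
    classes = sorted(c for c in by_class if c not in excluded)
    if len(classes) < 2:
        raise ValueError("need >=2 classes with >=2 records each")

    frame_rate = {
        c: sum(r.frame_preserving for r in by_class[c]) / len(by_class[c]) for c in classes
    }
    medians = {}
    for c in classes:
        rs = by_class[c]
        medians[c] = {
            "exon_length": float(np.median([r.length for r in rs])),
            "upstream_intron_length": float(
                np.median([r.upstream_intron_len for r in rs if r.upstream_intron_len])
            )
            if any(r.upstream_intron_len for r in rs)
            else float("nan"),
            "downstream_intron_length": float(
                np.median([r.downstream_intron_len for r in rs if r.downstream_intron_len])
            )
            if any(r.downstream_intron_len for r in rs)
            else float("nan"),
        }

    frame_tests = []
    length_tests = []
    for i, ca in enumerate(classes):
        for cb in classes[i + 1 :]:
            ra, rb = by_class[ca], by_class[cb]
            stat, p = _chi2_2x2(
                sum(r.frame_preserving for r in ra), len(ra),
                sum(r.frame_preserving for r in rb), len(rb),
            )
            frame_tests.append((ca, cb, stat, p))
            for measure, attr in (
                ("exon_length", "length"),
                ("upstream_intron_length", "upstream_intron_len"),
                ("downstream_intron_length", "downstream_intron_len"),
            ):
                va = [getattr(r, attr) for r in ra if getattr(r, attr)]
                vb = [getattr(r, attr) for r in rb if getattr(r, attr)]
                if len(va) >= 2 and len(vb) >= 2:
                    p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
                else:
                    p = float("nan")
                length_tests.append((ca, cb, measure, p))
    return {
        "frame_rate": frame_rate,
        "medians": medians,
        "frame_tests": pd.DataFrame(
            frame_tests, columns=["class_a", "class_b", "statistic", "p_value"]
        ),
        "length_tests": pd.DataFrame(
            length_tests, columns=["class_a", "class_b", "measure", "p_value"]
        ),
        "excluded": excluded,
    }


def detect_microexons(
    records: Sequence[ExonFeatureRecord],
    microexon_max: int = MICROEXON_MAX_NT,
    strict: bool = False,
) -> tuple[list[ExonFeatureRecord], dict]:
    """Exons at or below the microexon length bound, with provenance on how
    many were quantifiable only in tissue-enriched (IP) data."""
    micro = []
    for r in records:
        hit = r.length < microexon_max if strict else r.length <= microexon_max
        if hit:
            micro.append(replace(r, is_microexon=True))
    provenance = {
        "n_microexons": len(micro),
        "n_ip_only": sum(1 for r in micro if r.ip_only),
        "n_unknown_provenance": sum(1 for r in micro if r.ip_only is None),
    }
    return micro, provenance


def map_exon_to_protein(
    exon: GenomicInterval,
    cds_parts: Sequence[tuple[GenomicInterval, int]],
    strand: str,
) -> tuple[int, int] | None:
    """Amino-acid interval (1-based inclusive) covered by the exon's coding
    part, or None for a non-coding exon.

    ``cds_parts`` are (interval, phase) in genome order; phase is the GTF
    frame field (bases to skip to the next codon start).
    """
    parts = sorted(cds_parts, key=lambda p: p[0].start)
    if strand == "-":
        parts = parts[::-1]
    total = sum(len(iv) for iv, _ in parts)
    if total % 3 != 0:
        warnings.warn(f"CDS length {total} is not a multiple of 3")
    offset = 0
    for iv, phase in parts:
        expected = (3 - offset % 3) % 3
        if phase != expected:
            raise ValueError(
                f"inconsistent CDS phase at {iv.chrom}:{iv.start}: "
                f"expected {expected}, got {phase}"
            )
        overlap_lo = max(exon.start, iv.start)
        overlap_hi = min(exon.end, iv.end)
        if overlap_lo < overlap_hi:
            if strand == "+":
                within = overlap_lo - iv.start
            else:
                within = iv.end - overlap_hi
            cds_off = offset + within
            coding_len = overlap_hi - overlap_lo
            aa_start = cds_off // 3 + 1
            aa_end = math.ceil((cds_off + coding_len) / 3)
            return (aa_start, aa_end)
        offset += len(iv)
    return None


def feature_overlap_rates(
    records: Sequence[ExonFeatureRecord],
    track: ProteinFeatureTrack,
    include_unannotated: bool = False,
) -> dict:
    """Per-class fraction of exons overlapping a domain / an IDR (>=1 shared
    amino acid), with pairwise chi-squared tests.

    Records whose protein is absent from the track are excluded from the
    denominator unless ``include_unannotated``.
    """
    per_class: dict[str, dict[str, list[bool]]] = {}
    n_unannotated = 0
    for r in records:
        if r.protein_interval is None or r.protein_id is None:
            continue
        annotated = r.protein_id in track
        if not annotated:
            n_unannotated += 1
            if not include_unannotated:
                continue
        d = per_class.setdefault(r.class_label, {"domain": [], "idr": []})
        s, e = r.protein_interval
        d["domain"].append(track.overlaps(r.protein_id, s, e, "domain"))
        d["idr"].append(track.overlaps(r.protein_id, s, e, "idr"))
    classes = sorted(per_class)
    rates = {
        c: {lab: float(np.mean(per_class[c][lab])) if per_class[c][lab] else float("nan")
            for lab in ("domain", "idr")}
        for c in classes
    }
    tests = []
    for lab in ("domain", "idr"):
        for i, ca in enumerate(classes):
            for cb in classes[i + 1 :]:
                va, vb = per_class[ca][lab], per_class[cb][lab]
                if va and vb:
                    stat, p = _chi2_2x2(sum(va), len(va), sum(vb), len(vb))
                else:
                    stat, p = float("nan"), float("nan")
                tests.append((lab, ca, cb, stat, p))
    return {
        "rates": rates,
        "tests": pd.DataFrame(
            tests, columns=["feature", "class_a", "class_b", "statistic", "p_value"]
        ),
        "n_unannotated": n_unannotated,
    }
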