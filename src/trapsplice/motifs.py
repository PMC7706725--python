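"""K-mer enrichment between target and background event-region sequences.

A transparent presence/absence (zero-or-one occurrence per sequence)
enrichment: for every k-mer, the hypergeometric tail probability of seeing
at least the observed number of target sequences containing it, drawing
the target-set size from the pooled sequences.  No de novo motif
optimization, degenerate positions, or PWM building — exact-match k-mers
only, with per-k multiple-testing correction over all 4^k words.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import SplicingEvent

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EventRegion:
    """Sequences of one event in transcript (5'->3') orientation."""

    event_id: str
    exon: str
    upstream_flank: str
    downstream_flank: str

    def combined(self) -> str:
        return self.upstream_flank + self.exon + self.downstream_flank


@dataclass
class RegionSequenceSet:
    label: str
    regions: list[EventRegion]
    flank_len: int

    def sequences(self, part: str = "all") -> list[str]:
        if part == "all":
            return [r.combined() for r in self.regions]
        if part == "exon":
            return [r.exon for r in self.regions]
        if part == "introns":
            return [r.upstream_flank + "N" + r.downstream_flank for r in self.regions]
        raise ValueError(f"part must be all/exon/introns, got {part!r}")

    def __len__(self) -> int:
        return len(self.regions)


def extract_event_regions(
    events: Sequence[SplicingEvent],
    genome: Mapping[str, str],
    flank_len: int = 200,
    label: str = "events",
) -> RegionSequenceSet:
    """Internal-exon plus intron-flank sequences for cassette events.

    Flanks are truncated at short introns; minus-strand events are
    reverse-complemented so all sequences read 5'->3' in transcript
    orientation.
    """
    regions = []
    for ev in events:
        if ev.cassette_parts is None:
            continue
        left, internal, right = ev.cassette_parts
        chrom_seq = genome[internal.chrom]
        if isinstance(chrom_seq, str):
            seq = chrom_seq
        else:  # pyfaidx-style record
            seq = str(chrom_seq[:])
        if internal.end > len(seq):
            raise ValueError(
                f"event {ev.event_id} exon extends past the end of {internal.chrom}"
            )
        left_intron = (left.end, internal.start)
        right_intron = (internal.end, right.start)
        lflank_lo = max(left_intron[0], internal.start - flank_len)
        rflank_hi = min(right_intron[1], internal.end + flank_len)
        exon_seq = seq[internal.start : internal.end].upper()
        lseq = seq[lflank_lo : internal.start].upper()
        rseq = seq[internal.end : rflank_hi].upper()
        if internal.strand == "+":
            regions.append(EventRegion(ev.event_id, exon_seq, lseq, rseq))
        else:
            regions.append(
                EventRegion(
                    ev.event_id,
                    reverse_complement(exon_seq),
                    reverse_complement(rseq),
                    reverse_complement(lseq),
                )
            )
    return RegionSequenceSet(label, regions, flank_len)


def _presence_counts(sequences: Iterable[str], k: int, both_strands: bool) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in sequences:
        kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        if both_strands:
            kmers |= {reverse_complement(km) for km in kmers}
        kmers = {km for km in kmers if "N" not in km}
        for km in kmers:
            counts[km] = counts.get(km, 0) + 1
    return counts


def _bh_adjust(pvals: np.ndarray, n_tests: int) -> np.ndarray:
    """Benjamini-Hochberg over ``n_tests`` hypotheses, the unlisted ones
    implicitly at p = 1."""
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order]
    adj = ranked * n_tests / np.arange(1, len(ranked) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty_like(pvals)
    out[order] = np.minimum(adj, 1.0)
    return out


def enrich_kmers(
    target: RegionSequenceSet,
    background: RegionSequenceSet,
    k_range: Sequence[int] = (5, 6, 7),
    correction: str = "bh",
    part: str = "all",
    both_strands: bool = False,
) -> pd.DataFrame:
    """Ranked k-mer enrichment of target over background sequence sets.

    For each k-mer: p = P(X >= n_target_with) with X hypergeometric
    (population = pooled sequences, successes = sequences containing the
    k-mer, draws = target-set size).  Correction (``bonferroni`` or ``bh``)
    is applied per k over all 4^k k-mers; the result is sorted by corrected
    then raw p-value, then k-mer.
    """
    if len(target) == 0 or len(background) == 0:
        raise ValueError("both sequence sets must be non-empty")
    if correction not in ("bonferroni", "bh"):
        raise ValueError(f"correction must be bonferroni or bh, got {correction!r}")
    t_seqs = target.sequences(part)
    b_seqs = background.sequences(part)
    n_t, n_b = len(t_seqs), len(b_seqs)
    frames = []
    for k in k_range:
        t_counts = _presence_counts(t_seqs, k, both_strands)
        b_counts = _presence_counts(b_seqs, k, both_strands)
        kmers = sorted(set(t_counts) | set(b_counts))
        if not kmers:
            continue
        tw = np.array([t_counts.get(km, 0) for km in kmers])
        bw = np.array([b_counts.get(km, 0) for km in kmers])
        pop = n_t + n_b
        succ = tw + bw
        p = stats.hypergeom.sf(tw - 1, pop, succ, n_t)
        n_tests = 4**k
        if correction == "bonferroni":
            corrected = np.minimum(p * n_tests, 1.0)
        else:
            corrected = _bh_adjust(p, n_tests)
        frames.append(
            pd.DataFrame(
                {
                    "kmer": kmers,
                    "k": k,
                    "n_target_with": tw,
                    "n_target": n_t,
                    "n_background_with": bw,
                    "n_background": n_b,
                    "target_pct": 100.0 * tw / n_t,
                    "background_pct": 100.0 * bw / n_b,
                    "p_value": p,
                    "corrected_p": corrected,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=[
            "kmer", "k", "n_target_with", "n_target", "n_background_with",
            "n_background", "target_pct", "background_pct", "p_value", "corrected_p",
        ]
    )
    return out.sort_values(
        ["corrected_p", "p_value", "kmer"], kind="stable", ignore_index=True
    )
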