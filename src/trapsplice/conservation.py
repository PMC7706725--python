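"""Cross-species conservation of exon triplets.

An exon triplet is an internal exon together with its two flanking introns
and exons.  Triplets are classed constitutive, alternative non-tissue-
regulated, or tissue-regulated; a triplet counts as conserved in another
species when all three exons are present in the alignment and the four
splice sites around the internal exon align.  Windowed per-base
conservation-score profiles over the first/last ``flank_len`` intronic
bases quantify selection near splice sites.
"""

from __future__ import annotations

import bisect
import functools
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConservationTrack, GeneModel, GenomicInterval, SpeciesAlignment
from .events import SplicingEvent

TRIPLET_CLASSES = ("constitutive", "alt_non_tissue", "alt_tissue_regulated")
REGIONS = ("up5", "up3", "down5", "down3")


@dataclass(frozen=True)
class ExonTriplet:
    gene_id: str
    upstream_exon: GenomicInterval
    upstream_intron: GenomicInterval
    internal_exon: GenomicInterval
    downstream_intron: GenomicInterval
    downstream_exon: GenomicInterval
    class_label: str
    event_id: str | None = None

    def __post_init__(self) -> None:
        parts = [
            self.upstream_exon,
            self.upstream_intron,
            self.internal_exon,
            self.downstream_intron,
            self.downstream_exon,
        ]
        genome_order = parts if self.strand == "+" else parts[::-1]
        for a, b in zip(genome_order, genome_order[1:]):
            if a.end != b.start:
                raise ValueError("triplet intervals must be contiguous")

    @property
    def chrom(self) -> str:
        return self.internal_exon.chrom

    @property
    def strand(self) -> str:
        return self.internal_exon.strand

    @property
    def span(self) -> tuple[int, int]:
        parts = [self.upstream_exon, self.downstream_exon]
        return (min(p.start for p in parts), max(p.end for p in parts))

    @property
    def exons(self) -> tuple[GenomicInterval, GenomicInterval, GenomicInterval]:
        return (self.upstream_exon, self.internal_exon, self.downstream_exon)

    @property
    def introns(self) -> tuple[GenomicInterval, GenomicInterval]:
        return (self.upstream_intron, self.downstream_intron)


def extract_triplets(
    genes: Mapping[str, GeneModel],
    events: Sequence[SplicingEvent],
    diff_calls: pd.DataFrame | None = None,
) -> list[ExonTriplet]:
    """Exon triplets for cassette events and constitutive internal exons.

    A cassette event's triplet is tissue-regulated when any differential
    call flags it; otherwise alternative non-tissue-regulated.  Constitutive
    triplets come from annotated internal exons that overlap no event and
    whose flanking junctions are the only junctions at their splice sites.
    """
    differential_events: set[str] = set()
    if diff_calls is not None and len(diff_calls):
        differential_events = set(
            diff_calls.loc[diff_calls["differential"], "event_id"]
        )

    triplets: dict[tuple, ExonTriplet] = {}

    def orient(gene: GeneModel, left, mid_left, internal, mid_right, right):
        if gene.strand == "+":
            return left, mid_left, internal, mid_right, right
        return right, mid_right, internal, mid_left, left

    for ev in events:
        if ev.event_class != "cassette" or ev.cassette_parts is None:
            continue
        gene = genes.get(ev.gene_id)
        if gene is None:
            continue
        left, internal, right = ev.cassette_parts
        up_iv = GenomicInterval(gene.chrom, left.end, internal.start, gene.strand)
        down_iv = GenomicInterval(gene.chrom, internal.end, right.start, gene.strand)
        label = (
            "alt_tissue_regulated" if ev.event_id in differential_events else "alt_non_tissue"
        )
        key = (gene.gene_id, internal.start, internal.end)
        prev = triplets.get(key)
        if prev is not None and (
            prev.class_label == "alt_tissue_regulated" or prev.class_label == label
        ):
            continue
        ue, ui, ie, di, de = orient(gene, left, up_iv, internal, down_iv, right)
        triplets[key] = ExonTriplet(gene.gene_id, ue, ui, ie, di, de, label, ev.event_id)

    event_exons: dict[str, list[GenomicInterval]] = {}
    for ev in events:
        spans = [GenomicInterval(e.chrom, e.start, e.end, e.strand) for e in ev.edges]
        spans.append(ev.anchor)
        event_exons.setdefault(ev.gene_id, []).extend(spans)

    for gene in genes.values():
        # splice-site usage across all annotated junctions of the gene
        donor_use: dict[int, set] = {}
        acceptor_use: dict[int, set] = {}
        for j in gene.annotated_junctions():
            donor_use.setdefault(j.donor, set()).add(j.key)
            acceptor_use.setdefault(j.acceptor, set()).add(j.key)
        blocked = event_exons.get(gene.gene_id, [])
        for tid, exons in gene.transcripts.items():
            for i in range(1, len(exons) - 1):
                exon = exons[i]
                key = (gene.gene_id, exon.start, exon.end)
                if key in triplets:
                    continue
                if any(exon.overlaps(b) for b in blocked):
                    continue
                left, right = exons[i - 1], exons[i + 1]
                up_iv = GenomicInterval(gene.chrom, left.end, exon.start, gene.strand)
                down_iv = GenomicInterval(gene.chrom, exon.end, right.start, gene.strand)
                sites_unique = all(
                    len(donor_use.get(iv.start if gene.strand == "+" else iv.end - 1, set())) <= 1
                    and len(acceptor_use.get(iv.end - 1 if gene.strand == "+" else iv.start, set())) <= 1
                    for iv in (up_iv, down_iv)
                )
                if not sites_unique:
                    continue
                ue, ui, ie, di, de = orient(gene, left, up_iv, exon, down_iv, right)
                triplets[key] = ExonTriplet(
                    gene.gene_id, ue, ui, ie, di, de, "constitutive", None
                )
    return [triplets[k] for k in sorted(triplets)]


# ---------------------------------------------------------------------------
# center-star multiple alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignScores:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5


def pairwise_global(a: str, b: str, scores: AlignScores = AlignScores()) -> tuple[str, str, float]:
    """Needleman-Wunsch with affine gaps (a gap of length L scores
    open + L*extend).  Deterministic traceback: prefer diagonal, then up
    (gap in ``b``), then left (gap in ``a``)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    n, m = len(a), len(b)
    NEG = -1e18
    open_, ext = scores.gap_open, scores.gap_extend
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (vertical / "up")
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal / "left")
    M[0, 0] = 0.0
    js = np.arange(1, m + 1)
    Y[0, 1:] = open_ + ext * js
    X[1:, 0] = open_ + ext * np.arange(1, n + 1)
    for i in range(1, n + 1):
        sub = np.where(arr_b == arr_a[i - 1], scores.match, scores.mismatch)
        best_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = best_prev[:-1] + sub
        X[i, 1:] = np.maximum(M[i - 1, 1:] + open_ + ext, X[i - 1, 1:] + ext)
        # Y depends on the current row only through M: closed-form scan
        base = np.maximum(M[i, :-1], X[i, :-1]) - ext * np.arange(m)
        Y[i, 1:] = open_ + ext * js + np.maximum.accumulate(base)
    i, j = n, m
    out_a: list[str] = []
    out_b: list[str] = []
    # state preference at every step: M (diagonal), X (up), Y (left)
    score = max(M[n, m], X[n, m], Y[n, m])
    if M[n, m] >= X[n, m] and M[n, m] >= Y[n, m]:
        state = "M"
    elif X[n, m] >= Y[n, m]:
        state = "X"
    else:
        state = "Y"
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                state = "Y" if i == 0 else "X"
                continue
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            sub = scores.match if a[i - 1] == b[j - 1] else scores.mismatch
            target = M[i, j] - sub
            i, j = i - 1, j - 1
            if abs(M[i, j] - target) < eps:
                state = "M"
            elif abs(X[i, j] - target) < eps:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            if abs(M[i - 1, j] + open_ + ext - X[i, j]) < eps:
                state = "M"
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            target = Y[i, j] - ext
            if abs(M[i, j - 1] + open_ - target) < eps:
                state = "M"
            elif abs(X[i, j - 1] + open_ - target) < eps:
                state = "X"
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)


def align_center_star(
    sequences: Mapping[str, str],
    reference_species: str,
    scores: AlignScores = AlignScores(),
    ref_chrom: str | None = None,
    ref_start: int = 0,
) -> SpeciesAlignment:
    """Star alignment: every species aligned pairwise to the reference,
    merged on the reference coordinate system."""
    if reference_species not in sequences:
        raise ValueError(f"reference {reference_species!r} missing")
    if len(sequences) < 2:
        raise ValueError("need >=2 sequences")
    ref = sequences[reference_species]
    if not ref:
        raise ValueError("empty reference sequence")
    n = len(ref)
    # per species: insertions[slot] (before ref position slot, slot n = after
    # the last) and aligned char per ref position
    others = [s for s in sequences if s != reference_species]
    ins: dict[str, list[str]] = {}
    chars: dict[str, list[str]] = {}
    for sp in others:
        seq = sequences[sp]
        if not seq:
            raise ValueError(f"empty sequence for {sp!r}")
        ra, sa, _ = pairwise_global(ref, seq, scores)
        slots = [""] * (n + 1)
        aligned = []
        pos = 0
        for rc, sc in zip(ra, sa):
            if rc == "-":
                slots[pos] += sc
            else:
                aligned.append(sc)
                pos += 1
        ins[sp] = slots
        chars[sp] = aligned
    ins_len = [max((len(ins[sp][k]) for sp in others), default=0) for k in range(n + 1)]
    rows: dict[str, list[str]] = {sp: [] for sp in sequences}
    for k in range(n + 1):
        pad = ins_len[k]
        if pad:
            rows[reference_species].append("-" * pad)
            for sp in others:
                seg = ins[sp][k]
                rows[sp].append(seg + "-" * (pad - len(seg)))
        if k < n:
            rows[reference_species].append(ref[k])
            for sp in others:
                rows[sp].append(chars[sp][k])
    merged = {sp: "".join(parts) for sp, parts in rows.items()}
    return SpeciesAlignment(
        merged, reference_species, ref_chrom=ref_chrom, ref_start=ref_start
    )


# ---------------------------------------------------------------------------
# conservation calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConservationCall:
    triplet: ExonTriplet
    species_id: str
    conserved: bool
    site_aligned: tuple[bool, bool, bool, bool]
    exon_presence: tuple[float, float, float]


_CANONICAL = {("donor", "+"): "GT", ("donor", "-"): "AC",
              ("acceptor", "+"): "AG", ("acceptor", "-"): "CT"}


def assess_conservation(
    triplet: ExonTriplet,
    alignment: SpeciesAlignment,
    species_id: str,
    exon_presence_min: float = 0.5,
    splice_site_window: int = 0,
    require_canonical: bool = False,
) -> ConservationCall:
    """Conserved iff all 3 exons are present (non-gap fraction >=
    ``exon_presence_min``) and the 4 internal splice sites align (species
    non-gap at both intron-terminal reference columns, within
    ``splice_site_window`` columns)."""
    lo, hi = triplet.span
    ref_lo = alignment.ref_start
    ref_hi = alignment.ref_start + len(alignment.reference_map)
    if lo < ref_lo or hi > ref_hi:
        raise ValueError("triplet lies outside the alignment span")
    row = alignment.rows[species_id]
    n_cols = alignment.n_columns

    def presence(iv: GenomicInterval) -> float:
        cols = alignment.columns_for(iv.start - ref_lo, iv.end - ref_lo)
        non_gap = sum(1 for c in cols if row[c] != "-")
        return non_gap / len(cols)

    def site_ok(positions: tuple[int, int], expected: str) -> bool:
        ok = []
        for k, pos in enumerate(positions):
            col = int(alignment.reference_map[pos - ref_lo])
            found = False
            for c in range(max(0, col - splice_site_window),
                           min(n_cols, col + splice_site_window + 1)):
                ch = row[c]
                if ch == "-":
                    continue
                if require_canonical and ch != expected[k]:
                    continue
                found = True
                break
            ok.append(found)
        return all(ok)

    sites = []
    for intron in triplet.introns:
        donor_pos = (intron.start, intron.start + 1) if intron.strand == "+" else (
            intron.end - 2, intron.end - 1)
        acceptor_pos = (intron.end - 2, intron.end - 1) if intron.strand == "+" else (
            intron.start, intron.start + 1)
        sites.append(site_ok(donor_pos, _CANONICAL[("donor", intron.strand)]))
        sites.append(site_ok(acceptor_pos, _CANONICAL[("acceptor", intron.strand)]))

    pres = tuple(presence(e) for e in triplet.exons)
    conserved = all(p >= exon_presence_min for p in pres) and all(sites)
    return ConservationCall(triplet, species_id, conserved, tuple(sites), pres)


@functools.lru_cache(maxsize=100000)
def _fisher_margin(n1: int, n2: int, K: int):
    """Per-margin hypergeometric weights: support offset, raw weights,
    sorted weights with cumulative sums (exact integers)."""
    lo = max(0, K - n2)
    hi = min(n1, K)
    weights = tuple(
        math.comb(n1, x) * math.comb(n2, K - x) for x in range(lo, hi + 1)
    )
    ordered = sorted(weights)
    cum = list(itertools.accumulate(ordered))
    return lo, weights, tuple(ordered), tuple(cum)


def fisher_exact_two_sided(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[k1, n1-k1], [k2, n2-k2]].

    Sums the hypergeometric probabilities of every table (with the observed
    margins) at most as probable as the observed one.  Ties are resolved in
    exact integer arithmetic (probabilities share one denominator), so no
    floating-point tolerance enters the tail definition.
    """
    K = k1 + k2
    lo, weights, ordered, cum = _fisher_margin(n1, n2, K)
    if not weights:
        return 1.0
    q_obs = weights[k1 - lo]
    idx = bisect.bisect_right(ordered, q_obs)
    return cum[idx - 1] / cum[-1]


def conservation_rate_compare(
    calls_a: Sequence[ConservationCall], calls_b: Sequence[ConservationCall]
):
    """Conserved fractions of two call sets plus the two-sided Fisher exact
    p-value for the 2x2 (conserved/not x set)."""
    if not calls_a or not calls_b:
        raise ValueError("empty conservation call set")
    ka = sum(c.conserved for c in calls_a)
    kb = sum(c.conserved for c in calls_b)
    na, nb = len(calls_a), len(calls_b)
    p = fisher_exact_two_sided(ka, na, kb, nb)
    return ka / na, kb / nb, float(p)


# ---------------------------------------------------------------------------
# windowed conservation profiles
# ---------------------------------------------------------------------------

@dataclass
class WindowProfile:
    group: str
    region: str  # up5 / up3 / down5 / down3 (intron ends, transcription order)
    positions: np.ndarray  # 1..flank_len
    mean: np.ndarray  # smoothed per-position mean
    raw_mean: np.ndarray
    n: np.ndarray  # events contributing per position
    n_truncated: int = 0


def _intron_end_positions(intron: GenomicInterval, end: str, flank_len: int) -> list[int]:
    """Genomic positions 1..flank_len counted from the splice site into the
    intron; ``end`` is '5' (donor side) or '3' (acceptor side)."""
    L = len(intron)
    k = min(flank_len, L)
    five_prime_left = intron.strand == "+"  # genome-left end is the 5' end on '+'
    if (end == "5") == five_prime_left:
        return [intron.start + i for i in range(k)]
    return [intron.end - 1 - i for i in range(k)]


def rolling_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean, truncated at the edges; window 1 is identity."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    half = window // 2
    out = np.empty_like(values, dtype=float)
    n = len(values)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.nanmean(values[lo:hi])
    return out


def window_profile(
    track: ConservationTrack,
    triplets: Sequence[ExonTriplet],
    flank_len: int = 23,
    smooth: int = 3,
) -> tuple[dict[tuple[str, str], WindowProfile], pd.DataFrame]:
    """Per class/region mean conservation over intron-flank positions.

    Regions are the 5' and 3' ends of the upstream and downstream introns,
    position 1 being the first intronic base from the splice site.  Returns
    smoothed profiles plus pairwise class comparisons per region: a Wilcoxon
    signed-rank over the paired position means and a Mann-Whitney rank-sum
    over per-event mean scores.
    """
    classes = sorted({t.class_label for t in triplets})
    profiles: dict[tuple[str, str], WindowProfile] = {}
    per_event_means: dict[tuple[str, str], list[float]] = {}
    for cls in classes:
        members = [t for t in triplets if t.class_label == cls]
        for region in REGIONS:
            intron_of = (lambda t: t.upstream_intron) if region.startswith("up") else (
                lambda t: t.downstream_intron)
            end = region[-1]
            sums = np.zeros(flank_len)
            counts = np.zeros(flank_len, dtype=int)
            truncated = 0
            missing = 0
            total = 0
            ev_means: list[float] = []
            for t in members:
                intron = intron_of(t)
                if len(intron) < 2 * flank_len:
                    truncated += 1
                positions = _intron_end_positions(intron, end, flank_len)
                vals = track.values(t.chrom, positions)
                got = []
                for i, v in enumerate(vals):
                    total += 1
                    if v is None:
                        missing += 1
                        continue
                    sums[i] += v
                    counts[i] += 1
                    got.append(v)
                if got:
                    ev_means.append(float(np.mean(got)))
            if total and missing / total > 0.5:
                raise ValueError(
                    f"conservation track missing >50% of positions for class {cls!r}"
                )
            with np.errstate(invalid="ignore"):
                raw = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
            profiles[(cls, region)] = WindowProfile(
                cls,
                region,
                np.arange(1, flank_len + 1),
                rolling_mean(raw, smooth),
                raw,
                counts,
                truncated,
            )
            per_event_means[(cls, region)] = ev_means

    rows = []
    for region in REGIONS:
        for i, ca in enumerate(classes):
            for cb in classes[i + 1 :]:
                pa = profiles[(ca, region)].raw_mean
                pb = profiles[(cb, region)].raw_mean
                mask = ~(np.isnan(pa) | np.isnan(pb))
                diff = pa[mask] - pb[mask]
                if len(diff) >= 5 and np.any(diff != 0):
                    sr_p = float(stats.wilcoxon(diff).pvalue)
                elif len(diff) >= 5:
                    sr_p = 1.0
                else:
                    sr_p = float("nan")
                ea = per_event_means[(ca, region)]
                eb = per_event_means[(cb, region)]
                if len(ea) >= 2 and len(eb) >= 2:
                    rs_p = float(stats.mannwhitneyu(ea, eb, alternative="two-sided").pvalue)
                else:
                    rs_p = float("nan")
                rows.append((region, ca, cb, sr_p, rs_p))
    tests = pd.DataFrame(
        rows, columns=["region", "class_a", "class_b", "signed_rank_p", "rank_sum_p"]
    )
    return profiles, tests
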