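import functools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trapsplice.conservation import (
    AlignScores,
    ExonTriplet,
    align_center_star,
    assess_conservation,
    conservation_rate_compare,
    extract_triplets,
    pairwise_global,
    rolling_mean,
    window_profile,
)
from trapsplice.core import ConservationTrack, GenomicInterval, SpeciesAlignment
from trapsplice.events import build_splice_graph, classify_events, enumerate_events
from trapsplice.core import GeneModel


def iv(start, end, strand="+"):
    return GenomicInterval("chrI", start, end, strand)


def make_triplet(strand="+", label="constitutive"):
    # exon1 [0,100) intron [100,200) exon2 [200,300) intron [300,400) exon3 [400,500)
    e1, i1, e2, i2, e3 = iv(0, 100, strand), iv(100, 200, strand), iv(200, 300, strand), iv(300, 400, strand), iv(400, 500, strand)
    if strand == "+":
        return ExonTriplet("g", e1, i1, e2, i2, e3, label)
    return ExonTriplet("g", e3, i2, e2, i1, e1, label)


# ---------------------------------------------------------------------------
# triplet extraction
# ---------------------------------------------------------------------------

def test_extract_triplets_classes_and_boundaries():
    exons = [iv(0, 100), iv(200, 300), iv(400, 500)]
    gene = GeneModel(
        "g", "chrI", "+", {"t1": list(exons), "t2": [exons[0], exons[2]]}
    )
    graph = build_splice_graph(gene, [])
    events = enumerate_events(graph)
    classify_events(events, graph)
    diff = pd.DataFrame(
        {"event_id": [events[0].event_id], "differential": [True]}
    )
    trips = extract_triplets({"g": gene}, events, diff)
    labels = {t.class_label for t in trips}
    assert "alt_tissue_regulated" in labels
    cassette = [t for t in trips if t.class_label == "alt_tissue_regulated"]
    assert len(cassette) == 1
    assert (cassette[0].internal_exon.start, cassette[0].internal_exon.end) == (200, 300)
    # without a differential call the same event is non-tissue-regulated
    trips2 = extract_triplets({"g": gene}, events, None)
    assert {t.class_label for t in trips2} == {"alt_non_tissue"}


def test_constitutive_triplets_require_unique_sites():
    exons = [iv(0, 100), iv(200, 300), iv(400, 500), iv(600, 700)]
    gene = GeneModel("g", "chrI", "+", {"t1": list(exons)})
    trips = extract_triplets({"g": gene}, [], None)
    # internal exons 2 and 3 qualify; the first/last exons never do
    assert len(trips) == 2
    assert all(t.class_label == "constitutive" for t in trips)
    starts = {t.internal_exon.start for t in trips}
    assert starts == {200, 400}


# ---------------------------------------------------------------------------
# center-star alignment
# ---------------------------------------------------------------------------

def brute_force_affine_score(a, b, scores=AlignScores()):
    """Plain recursive affine-gap DP (independent of the vectorized one)."""

    @functools.lru_cache(maxsize=None)
    def best(i, j, state):
        if i == 0 and j == 0:
            return 0.0 if state == "M" else -math.inf
        out = -math.inf
        if state == "M" and i > 0 and j > 0:
            sub = scores.match if a[i - 1] == b[j - 1] else scores.mismatch
            out = max(best(i - 1, j - 1, s) for s in "MXY") + sub
        elif state == "X" and i > 0:
            out = max(
                best(i - 1, j, "M") + scores.gap_open + scores.gap_extend,
                best(i - 1, j, "X") + scores.gap_extend,
            )
        elif state == "Y" and j > 0:
            out = max(
                best(i, j - 1, "M") + scores.gap_open + scores.gap_extend,
                best(i, j - 1, "X") + scores.gap_open + scores.gap_extend,
                best(i, j - 1, "Y") + scores.gap_extend,
            )
        return out

    return max(best(len(a), len(b), s) for s in "MXY")


@pytest.mark.parametrize(
    "a,b",
    [
        ("ACGTACGT", "ACGACGT"),
        ("GATTACA", "GCATGCU".replace("U", "T")),
        ("AAAA", "TTTT"),
        ("ACGT", "ACGT"),
        ("AC", "ACGTACGT"),
    ],
)
def test_pairwise_score_matches_brute_force_dp(a, b):
    _, _, score = pairwise_global(a, b)
    assert score == pytest.approx(brute_force_affine_score(a, b), abs=1e-9)


def test_pairwise_alignment_shapes():
    ra, rb, _ = pairwise_global("ACGTACGT", "ACGACGT")
    assert len(ra) == len(rb)
    assert ra.replace("-", "") == "ACGTACGT"
    assert rb.replace("-", "") == "ACGACGT"
    assert rb.count("-") - ra.count("-") == 1


def test_star_alignment_of_identical_sequences_is_gap_free():
    seqs = {f"s{i}": "ACGTACGTAA" for i in range(4)}
    seqs["ref"] = "ACGTACGTAA"
    aln = align_center_star(seqs, "ref")
    assert all("-" not in row for row in aln.rows.values())
    assert aln.reference_sequence() == "ACGTACGTAA"


def test_star_alignment_single_deletion():
    aln = align_center_star({"ref": "ACGTACGT", "sp": "ACGACGT"}, "ref")
    assert aln.rows["sp"].count("-") == 1
    assert aln.rows["ref"].count("-") == 0


def test_alignment_determinism():
    seqs = {"ref": "ACGTTGCAACGT", "a": "ACGTGCAACG", "b": "ACTTGCACGT"}
    a1 = align_center_star(seqs, "ref")
    a2 = align_center_star(dict(reversed(list(seqs.items()))), "ref")
    assert a1.rows == a2.rows


def test_empty_sequence_is_an_error():
    with pytest.raises(ValueError):
        align_center_star({"ref": "ACGT", "sp": ""}, "ref")


# ---------------------------------------------------------------------------
# conservation calls
# ---------------------------------------------------------------------------

def _aln_from_rows(ref_row, sp_row, ref_start=0):
    return SpeciesAlignment(
        {"ref": ref_row, "sp": sp_row}, "ref", ref_chrom="chrI", ref_start=ref_start
    )


def test_identical_species_row_is_conserved():
    trip = make_triplet()
    ref = "A" * 500
    aln = _aln_from_rows(ref, ref)
    call = assess_conservation(trip, aln, "sp")
    assert call.conserved
    assert call.exon_presence == (1.0, 1.0, 1.0)
    assert all(call.site_aligned)


@pytest.mark.parametrize("strand", ["+", "-"])
def test_gapped_internal_exon_is_not_conserved(strand):
    trip = make_triplet(strand)
    ref = "A" * 500
    sp = "A" * 200 + "-" * 100 + "A" * 200  # internal exon fully deleted
    call = assess_conservation(trip, _aln_from_rows(ref, sp), "sp")
    assert not call.conserved
    assert call.exon_presence[1] == 0.0


def test_single_gapped_splice_site_column_breaks_conservation():
    trip = make_triplet()
    ref = "A" * 500
    # gap exactly at the last base of the upstream intron (position 199)
    sp = "A" * 199 + "-" + "A" * 300
    call = assess_conservation(trip, _aln_from_rows(ref, sp), "sp")
    assert not call.conserved
    assert min(call.exon_presence) == 1.0  # exons untouched


def test_assess_is_invariant_to_columns_outside_span():
    trip = make_triplet()
    ref = "A" * 500
    sp = "A" * 500
    base = assess_conservation(trip, _aln_from_rows(ref, sp), "sp")
    # add garbage beyond the triplet span (alignment covering more sequence)
    ref2 = ref + "C" * 50
    sp2 = sp + "-" * 50
    ext = assess_conservation(trip, _aln_from_rows(ref2, sp2), "sp")
    assert base.conserved == ext.conserved
    assert base.exon_presence == ext.exon_presence


def test_triplet_outside_alignment_span_is_an_error():
    trip = make_triplet()
    aln = _aln_from_rows("A" * 100, "A" * 100, ref_start=0)
    with pytest.raises(ValueError, match="span"):
        assess_conservation(trip, aln, "sp")


# ---------------------------------------------------------------------------
# Fisher exact oracle
# ---------------------------------------------------------------------------

def brute_force_fisher(k1, n1, k2, n2):
    """Two-sided Fisher p by direct per-table enumeration with exact
    integer tie comparison (independent of the vectorized implementation)."""
    K = k1 + k2
    N = n1 + n2
    q_obs = math.comb(n1, k1) * math.comb(n2, K - k1)
    num = 0
    for x in range(0, min(n1, K) + 1):
        if not 0 <= K - x <= n2:
            continue
        q = math.comb(n1, x) * math.comb(n2, K - x)
        if q <= q_obs:
            num += q
    return num / math.comb(N, K)


class _Call:
    def __init__(self, conserved):
        self.conserved = conserved


def _calls(k, n):
    return [_Call(i < k) for i in range(n)]


def test_fisher_examples_match_exact_enumeration():
    ra, rb, p = conservation_rate_compare(_calls(81, 113), _calls(163, 277))
    assert (ra, rb) == (81 / 113, 163 / 277)
    assert p == pytest.approx(brute_force_fisher(81, 113, 163, 277), rel=1e-9)
    _, _, p2 = conservation_rate_compare(_calls(10, 10), _calls(0, 10))
    assert p2 == pytest.approx(brute_force_fisher(10, 10, 0, 10), rel=1e-9)
    _, _, p3 = conservation_rate_compare(_calls(5, 10), _calls(5, 10))
    assert p3 == pytest.approx(1.0)


def test_fisher_matches_enumeration_for_all_small_tables():
    from trapsplice.conservation import fisher_exact_two_sided

    for n1 in range(1, 13):
        for n2 in range(1, 13):
            for k1 in range(n1 + 1):
                for k2 in range(n2 + 1):
                    p = fisher_exact_two_sided(k1, n1, k2, n2)
                    assert p == pytest.approx(
                        brute_force_fisher(k1, n1, k2, n2), abs=1e-12
                    )


def test_fisher_agrees_with_scipy_cross_check():
    from trapsplice.conservation import fisher_exact_two_sided

    rng = np.random.default_rng(8)
    for _ in range(300):
        n1, n2 = int(rng.integers(1, 60)), int(rng.integers(1, 60))
        k1, k2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
        mine = fisher_exact_two_sided(k1, n1, k2, n2)
        _, ref = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])
        assert mine == pytest.approx(ref, abs=1e-7)


def test_empty_call_set_is_an_error():
    with pytest.raises(ValueError):
        conservation_rate_compare([], _calls(1, 2))


# ---------------------------------------------------------------------------
# window profiles
# ---------------------------------------------------------------------------

def test_rolling_mean_examples():
    x = np.arange(1.0, 24.0)
    sm = rolling_mean(x, 3)
    assert sm[1] == pytest.approx(2.0)  # mean of 1,2,3
    assert sm[0] == pytest.approx(1.5)  # truncated edge
    assert np.allclose(rolling_mean(x, 1), x)
    # interior mean preserved
    assert np.mean(sm[1:-1]) == pytest.approx(np.mean(x[1:-1]))


def _track_constant(v, length=1000):
    t = ConservationTrack()
    t.set_range("chrI", 0, length, v)
    return t


def test_window_profile_constant_track():
    trips = [make_triplet(label="constitutive"), make_triplet(label="alt_tissue_regulated")]
    profiles, tests = window_profile(_track_constant(2.5), trips, flank_len=23, smooth=3)
    for prof in profiles.values():
        assert np.allclose(prof.mean, 2.5)
        assert len(prof.positions) == 23
    assert ((tests.signed_rank_p == 1.0) | tests.signed_rank_p.isna()).all()


def test_window_profile_positions_are_strand_aware():
    # score = genomic position; position 1 of the upstream-intron 3' end is
    # the last intronic base before the internal exon
    t = ConservationTrack()
    for p in range(1000):
        t.set_range("chrI", p, p + 1, float(p))
    plus, _ = window_profile(t, [make_triplet("+")], flank_len=5, smooth=1)
    minus, _ = window_profile(t, [make_triplet("-")], flank_len=5, smooth=1)
    up3_plus = plus[("constitutive", "up3")].raw_mean
    assert list(up3_plus) == [199.0, 198.0, 197.0, 196.0, 195.0]
    up3_minus = minus[("constitutive", "up3")].raw_mean
    assert list(up3_minus) == [300.0, 301.0, 302.0, 303.0, 304.0]
    up5_plus = plus[("constitutive", "up5")].raw_mean
    assert list(up5_plus) == [100.0, 101.0, 102.0, 103.0, 104.0]


def test_window_profile_detects_implanted_splice_site_signal():
    rng = np.random.default_rng(5)
    track = ConservationTrack()
    trips = []
    delta = 2.0
    for i in range(60):
        base = i * 600
        e1 = iv(base, base + 100)
        i1 = iv(base + 100, base + 200)
        e2 = iv(base + 200, base + 300)
        i2 = iv(base + 300, base + 400)
        e3 = iv(base + 400, base + 500)
        label = "alt_tissue_regulated" if i % 2 == 0 else "constitutive"
        trips.append(ExonTriplet(f"g{i}", e1, i1, e2, i2, e3, label))
        for p in range(base, base + 500):
            bonus = delta if (
                label == "alt_tissue_regulated"
                and (base + 177 <= p < base + 200 or base + 300 <= p < base + 323)
            ) else 0.0
            track.set_range("chrI", p, p + 1, float(rng.normal(0, 1) + bonus))
    profiles, tests = window_profile(track, trips, flank_len=23, smooth=3)
    reg = profiles[("alt_tissue_regulated", "up3")].raw_mean
    con = profiles[("constitutive", "up3")].raw_mean
    assert np.all(reg[:10] > con[:10])
    row = tests[(tests.region == "up3") & (tests.class_a == "alt_tissue_regulated")]
    assert float(row.signed_rank_p.iloc[0]) < 0.05


def test_window_profile_missing_track_is_an_error():
    trips = [make_triplet(label="constitutive")]
    empty = ConservationTrack()
    empty.set_range("chrI", 0, 10, 1.0)  # <50% of needed positions
    with pytest.raises(ValueError, match="constitutive"):
        window_profile(empty, trips)
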