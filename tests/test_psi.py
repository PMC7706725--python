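import numpy as np
import pytest

from trapsplice.core import GenomicInterval, JunctionCountTable, SampleMeta, SpliceJunction
from trapsplice.psi import (
    call_alternative_junctions,
    compute_psi,
    correlate_psi,
    detect_tissue_enriched,
    subsample_counts,
)

from conftest import make_table


def brute_force_psi(table, min_group_reads, pool_by):
    """Independent oracle: groups re-derived by scanning all junction
    pairs, PSI recomputed from scratch."""
    if pool_by == "sample":
        units = [(s.sample_id, [i]) for i, s in enumerate(table.samples)]
    else:
        seen = {}
        for i, s in enumerate(table.samples):
            seen.setdefault((s.tissue, s.fraction), []).append(i)
        n_fracs = {t: len({f for (tt, f) in seen if tt == t}) for (t, _) in seen}
        units = [
            (t if n_fracs[t] == 1 else f"{t}[{f}]", idx) for (t, f), idx in seen.items()
        ]
    out = {}
    for ui, (unit, cols) in enumerate(units):
        for i, ji in enumerate(table.junctions):
            donor_members = [
                k
                for k, jk in enumerate(table.junctions)
                if jk.chrom == ji.chrom and jk.strand == ji.strand and jk.donor == ji.donor
            ]
            acc_members = [
                k
                for k, jk in enumerate(table.junctions)
                if jk.chrom == ji.chrom
                and jk.strand == ji.strand
                and jk.acceptor == ji.acceptor
            ]
            c = sum(table.counts[i, col] for col in cols)
            dt = sum(table.counts[k, col] for k in donor_members for col in cols)
            at = sum(table.counts[k, col] for k in acc_members for col in cols)
            pd_ = c / dt if dt >= min_group_reads else None
            pa_ = c / at if at >= min_group_reads else None
            if pd_ is None and pa_ is None:
                p = None
            elif pd_ is None or pa_ is None:
                p = pd_ if pa_ is None else pa_
            else:
                p = min(pd_, pa_)
            out[(ji.key_str(), unit)] = (pd_, pa_, p, dt, at)
    return out


def random_table(rng, n_junctions, n_samples):
    sites = rng.integers(0, 6, size=(n_junctions, 2))
    rows = []
    seen = set()
    for a, b in sites:
        start = int(min(a, b)) * 100
        end = int(max(a, b)) * 100 + 150
        strand = "+" if rng.random() < 0.7 else "-"
        key = ("chrI", start, end, strand)
        if key in seen:
            continue
        seen.add(key)
        rows.append(("chrI", start, end, strand, *rng.integers(0, 40, n_samples)))
    if not rows:
        rows = [("chrI", 0, 150, "+", *rng.integers(0, 40, n_samples))]
    return make_table(rows)


@pytest.mark.parametrize("pool_by", ["sample", "tissue"])
def test_psi_matches_brute_force_on_random_tables(pool_by):
    for seed in range(30):
        rng = np.random.default_rng(seed)
        table = random_table(rng, 15, 3)
        min_reads = 10
        df = compute_psi(table, min_reads, pool_by)
        want = brute_force_psi(table, min_reads, pool_by)
        for row in df.itertuples(index=False):
            pd_, pa_, p, dt, at = want[(row.junction, row.unit)]
            for got_v, want_v in ((row.psi_donor, pd_), (row.psi_acceptor, pa_), (row.psi, p)):
                if want_v is None:
                    assert np.isnan(got_v)
                else:
                    assert got_v == pytest.approx(want_v, abs=1e-12)
            assert (row.total_donor, row.total_acceptor) == (dt, at)


def test_psi_forced_examples():
    # shared donor at 100 (+): psi_donor = 0.8 / 0.2
    table = make_table(
        [("chrI", 100, 200, "+", 80), ("chrI", 100, 300, "+", 20)]
    )
    df = compute_psi(table, min_group_reads=10, pool_by="sample")
    by = {r.junction: r for r in df.itertuples(index=False)}
    assert by["chrI:100-200:+"].psi_donor == pytest.approx(0.8)
    assert by["chrI:100-300:+"].psi_donor == pytest.approx(0.2)
    # singleton junction, count 7, min 5 -> psi 1.0
    single = make_table([("chrI", 0, 100, "+", 7)])
    df = compute_psi(single, min_group_reads=5)
    assert df.psi.iloc[0] == pytest.approx(1.0)
    # group total 4 below min 10 -> undefined
    low = make_table([("chrI", 0, 100, "+", 4)])
    df = compute_psi(low, min_group_reads=10)
    assert np.isnan(df.psi.iloc[0])


def test_group_psi_sums_to_one():
    rng = np.random.default_rng(3)
    for seed in range(20):
        table = random_table(np.random.default_rng(seed), 18, 2)
        df = compute_psi(table, min_group_reads=5, pool_by="sample")
        for (gid, unit), grp in df.groupby(["donor_group", "unit"]):
            vals = grp.psi_donor.dropna()
            if len(vals) == len(grp):
                assert vals.sum() == pytest.approx(1.0, abs=1e-9)
        for (gid, unit), grp in df.groupby(["acceptor_group", "unit"]):
            vals = grp.psi_acceptor.dropna()
            if len(vals) == len(grp):
                assert vals.sum() == pytest.approx(1.0, abs=1e-9)


def test_psi_monotone_in_added_reads():
    base = make_table(
        [("chrI", 100, 200, "+", 30), ("chrI", 100, 300, "+", 20), ("chrI", 100, 400, "+", 10)]
    )
    more = make_table(
        [("chrI", 100, 200, "+", 45), ("chrI", 100, 300, "+", 20), ("chrI", 100, 400, "+", 10)]
    )
    a = compute_psi(base, 10).set_index("junction").psi_donor
    b = compute_psi(more, 10).set_index("junction").psi_donor
    assert b["chrI:100-200:+"] >= a["chrI:100-200:+"]
    assert b["chrI:100-300:+"] <= a["chrI:100-300:+"]
    assert b["chrI:100-400:+"] <= a["chrI:100-400:+"]


def _enrichment_table():
    samples = [
        SampleMeta("n1", "neurons", "IP", 1),
        SampleMeta("n2", "neurons", "IP", 2),
        SampleMeta("w1", "whole_animal", "input", 1),
    ]
    return samples


def test_detect_tissue_enriched_thresholds():
    samples = _enrichment_table()
    # ip_sum 25, input 0
    t = make_table([("chrI", 0, 100, "+", 15, 10, 0)], samples)
    assert len(detect_tissue_enriched(t, "neurons", 20, strict=True)) == 1
    # exactly 20 fails the strict (>20) rule but passes inclusive
    t20 = make_table([("chrI", 0, 100, "+", 10, 10, 0)], samples)
    assert len(detect_tissue_enriched(t20, "neurons", 20, strict=True)) == 0
    assert len(detect_tissue_enriched(t20, "neurons", 20, strict=False)) == 1
    # any input support disqualifies
    t_in = make_table([("chrI", 0, 100, "+", 15, 10, 1)], samples)
    assert len(detect_tissue_enriched(t_in, "neurons", 20)) == 0
    # ip_sum 5 at inclusive min 5
    t5 = make_table([("chrI", 0, 100, "+", 3, 2, 0)], samples)
    assert len(detect_tissue_enriched(t5, "neurons", 5)) == 1
    assert len(detect_tissue_enriched(t5, "neurons", 5, strict=True)) == 0


def test_detect_tissue_enriched_empty_when_input_supported():
    samples = _enrichment_table()
    t = make_table(
        [("chrI", 0, 100, "+", 50, 50, 1), ("chrI", 0, 200, "+", 9, 9, 3)], samples
    )
    assert detect_tissue_enriched(t, "neurons", 5).empty


def test_detect_tissue_enriched_requires_input_samples():
    t = make_table([("chrI", 0, 100, "+", 5)])
    with pytest.raises(ValueError, match="input"):
        detect_tissue_enriched(t, "t0", 5)


def test_call_alternative_junction_threshold():
    samples = [SampleMeta("a", "neurons", "IP", 1)]
    t = make_table(
        [("chrI", 100, 200, "+", 93), ("chrI", 100, 300, "+", 7)], samples
    )
    df = compute_psi(t, 10, pool_by="tissue")
    alt = call_alternative_junctions(df, 0.05)
    assert any(g.startswith("D:chrI:100") for g in alt)
    t2 = make_table(
        [("chrI", 100, 200, "+", 97), ("chrI", 100, 300, "+", 3)], samples
    )
    assert call_alternative_junctions(compute_psi(t2, 10, "tissue"), 0.05) == {}
    # single defined member is never alternative
    t3 = make_table([("chrI", 100, 200, "+", 50)], samples)
    assert call_alternative_junctions(compute_psi(t3, 10, "tissue"), 0.05) == {}


def test_subsample_identity_zero_and_tail_bound():
    t = make_table([("chrI", 0, 100, "+", 10000), ("chrI", 0, 200, "+", 0)])
    same = subsample_counts(t, 1.0, seed=5)
    assert np.array_equal(same.counts, t.counts)
    half = subsample_counts(t, 0.5, seed=5)
    # binomial(10000, 0.5): +/-4 sigma = [4600, 5400]
    assert 4600 <= half.counts[0, 0] <= 5400
    assert half.counts[1, 0] == 0
    assert np.array_equal(
        subsample_counts(t, 0.5, seed=5).counts, subsample_counts(t, 0.5, seed=5).counts
    )


def test_correlate_psi_examples():
    a = np.array([0.1, 0.5, 0.9])
    assert correlate_psi(a, a).coefficient == pytest.approx(1.0)
    assert correlate_psi(a, a[::-1]).coefficient == pytest.approx(-1.0)
    x = np.array([0.2, 0.4, 0.6, 0.8])
    y = np.array([0.3, 0.3, 0.7, 0.7])
    # hand-computed Pearson: cov/sd_x/sd_y
    r_hand = float(np.sum((x - x.mean()) * (y - y.mean())) /
                   np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
    assert correlate_psi(x, y).coefficient == pytest.approx(r_hand, abs=1e-12)


def test_correlate_psi_drops_incomplete_pairs_and_errors():
    a = np.array([0.1, np.nan, 0.5, 0.9, 0.3])
    b = np.array([0.2, 0.5, np.nan, 0.8, 0.4])
    res = correlate_psi(a, b)
    assert res.n_pairs == 3
    with pytest.raises(ValueError, match=">=3"):
        correlate_psi([0.1, np.nan, 0.2], [0.2, 0.3, np.nan])
    flat = correlate_psi([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
    assert not flat.defined and np.isnan(flat.coefficient)
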