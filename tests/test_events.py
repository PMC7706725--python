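import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trapsplice.core import (
    GeneModel,
    GenomicInterval,
    JunctionCountTable,
    SampleMeta,
    SpliceJunction,
)
from trapsplice.events import (
    build_splice_graph,
    call_differential,
    class_proportion_test,
    classify_event,
    classify_events,
    enumerate_events,
    expression_vs_splicing,
    quantify_events,
)

from conftest import make_table


def iv(start, end, strand="+"):
    return GenomicInterval("chrI", start, end, strand)


def jx(start, end, strand="+"):
    return SpliceJunction(iv(start, end, strand))


def three_exon_gene(strand="+"):
    """Exons [0,100), [200,300), [400,500); inclusion + skipping."""
    exons = [iv(0, 100, strand), iv(200, 300, strand), iv(400, 500, strand)]
    return GeneModel(
        "g", "chrI", strand,
        {"t_inc": list(exons), "t_skip": [exons[0], exons[2]]},
    )


@pytest.mark.parametrize("strand", ["+", "-"])
def test_cassette_substrate_graph(strand):
    gene = three_exon_gene(strand)
    graph = build_splice_graph(gene, [jx(100, 400, strand)])
    assert len(graph.nodes) == 3
    assert len(graph.edges) == 3


def test_junction_landing_mid_exon_splits_node():
    gene = GeneModel("g", "chrI", "+", {"t": [iv(0, 100), iv(200, 300)]})
    graph = build_splice_graph(gene, [jx(100, 250)])
    starts = sorted(n.start for n in graph.nodes)
    assert starts == [0, 200, 250]


def test_graph_with_only_annotated_edges():
    gene = three_exon_gene()
    graph = build_splice_graph(gene, [])
    assert len(graph.edges) == 3  # two inclusion introns + annotated skip


def test_orphan_junction_is_excluded_and_counted():
    gene = GeneModel("g", "chrI", "+", {"t": [iv(0, 100), iv(200, 300)]})
    graph = build_splice_graph(gene, [jx(100, 200), jx(150, 999)])
    assert len(graph.orphans) == 1
    assert graph.orphans[0].start == 150


@pytest.mark.parametrize("strand", ["+", "-"])
def test_cassette_enumeration_and_classification(strand):
    gene = three_exon_gene(strand)
    graph = build_splice_graph(gene, [])
    events = enumerate_events(graph)
    assert len(events) == 2  # source split and target join
    classify_events(events, graph)
    assert {e.event_class for e in events} == {"cassette"}
    for e in events:
        assert e.cassette_parts is not None
        assert (e.cassette_parts[1].start, e.cassette_parts[1].end) == (200, 300)


def test_linear_gene_has_no_events():
    gene = GeneModel("g", "chrI", "+", {"t": [iv(0, 100), iv(200, 300)]})
    graph = build_splice_graph(gene, [])
    assert enumerate_events(graph) == []


def test_three_junction_node_gives_one_event():
    gene = GeneModel(
        "g", "chrI", "+",
        {
            "t1": [iv(0, 100), iv(200, 300), iv(400, 500), iv(600, 700)],
            "t2": [iv(0, 100), iv(400, 500), iv(600, 700)],
            "t3": [iv(0, 100), iv(600, 700)],
        },
    )
    graph = build_splice_graph(gene, [])
    events = enumerate_events(graph)
    sources = [e for e in events if e.side == "source" and len(e.edges) == 3]
    assert len(sources) == 1
    classify_events(events, graph)
    assert sources[0].event_class == "complex"


@pytest.mark.parametrize("strand", ["+", "-"])
def test_alt_splice_site_classes_are_strand_aware(strand):
    # shared donor-side node, two acceptors 12 nt apart inside one extension
    exons = [iv(0, 100, strand), iv(200, 300, strand)]
    variant = iv(188, 300, strand) if strand == "+" else iv(0, 112, strand)
    gene = GeneModel(
        "g", "chrI", strand,
        {"t1": list(exons), "t2": [variant, exons[1]] if strand == "-" else [exons[0], variant]},
    )
    graph = build_splice_graph(gene, [])
    events = enumerate_events(graph)
    assert len(events) == 1
    cls = classify_event(events[0], graph)
    assert cls == "alt3ss"  # the varying site is the acceptor on either strand


@pytest.mark.parametrize("strand", ["+", "-"])
def test_alt_donor_class(strand):
    exons = [iv(0, 100, strand), iv(200, 300, strand)]
    variant = iv(0, 112, strand) if strand == "+" else iv(188, 300, strand)
    gene = GeneModel(
        "g", "chrI", strand,
        {"t1": list(exons), "t2": [variant, exons[1]] if strand == "+" else [exons[0], variant]},
    )
    graph = build_splice_graph(gene, [])
    events = enumerate_events(graph)
    assert len(events) == 1
    assert classify_event(events[0], graph) == "alt5ss"


@pytest.mark.parametrize("strand", ["+", "-"])
def test_mutually_exclusive_class(strand):
    e = [iv(0, 100, strand), iv(200, 300, strand), iv(400, 500, strand), iv(600, 700, strand)]
    gene = GeneModel(
        "g", "chrI", strand, {"tA": [e[0], e[1], e[3]], "tB": [e[0], e[2], e[3]]}
    )
    graph = build_splice_graph(gene, [])
    events = enumerate_events(graph)
    classify_events(events, graph)
    assert {ev.event_class for ev in events} == {"mutually_exclusive"}


@pytest.mark.parametrize("strand", ["+", "-"])
def test_alternative_start_and_terminal_classes(strand):
    e = [iv(0, 100, strand), iv(200, 300, strand), iv(400, 500, strand), iv(600, 700, strand)]
    gene = GeneModel(
        "g", "chrI", strand, {"tA": [e[0], e[2], e[3]], "tB": [e[1], e[2], e[3]]}
    )
    graph = build_splice_graph(gene, [])
    events = enumerate_events(graph)
    assert len(events) == 1
    assert classify_event(events[0], graph) == "alt_start_terminal"


def test_intron_retention_class():
    gene = GeneModel(
        "g", "chrI", "+",
        {"t1": [iv(0, 100), iv(200, 300)], "t2": [iv(0, 300)]},
    )
    graph = build_splice_graph(gene, [], retention_counts={(100, 200): 50})
    events = enumerate_events(graph)
    classify_events(events, graph)
    assert {e.event_class for e in events} == {"intron_retention"}


def test_multi_mode_region_is_complex():
    # cassette plus an extra long skip from the same anchor
    gene = GeneModel(
        "g", "chrI", "+",
        {
            "t1": [iv(0, 100), iv(200, 300), iv(400, 500), iv(600, 700)],
            "t2": [iv(0, 100), iv(400, 500), iv(600, 700)],
            "t3": [iv(0, 100), iv(600, 700)],
        },
    )
    graph = build_splice_graph(gene, [])
    events = enumerate_events(graph)
    classify_events(events, graph)
    three = [e for e in events if len(e.edges) == 3]
    assert three and all(e.event_class == "complex" for e in three)


def test_enumerate_matches_exhaustive_oracle(small_study):
    """Independent oracle: collect edge sets per node side directly from the
    edge list and compare with enumerate_events output."""
    genes = small_study.genes
    table = small_study.counts
    for gid in sorted(genes)[:30]:
        g = genes[gid]
        span = g.span
        observed = [
            j for j in table.junctions
            if j.chrom == g.chrom and j.strand == g.strand
            and span.start <= j.start and j.end <= span.end
        ]
        graph = build_splice_graph(g, observed)
        expected = set()
        for node in graph.nodes:
            three_prime = node.end if g.strand == "+" else node.start
            five_prime = node.start if g.strand == "+" else node.end
            out_edges = frozenset(
                (e.kind, e.start, e.end)
                for e in graph.edges
                if (e.start if g.strand == "+" else e.end) == three_prime
            )
            in_edges = frozenset(
                (e.kind, e.start, e.end)
                for e in graph.edges
                if (e.end if g.strand == "+" else e.start) == five_prime
            )
            for s in (out_edges, in_edges):
                if len(s) >= 2:
                    expected.add(s)
        got = {
            frozenset((e.kind, e.start, e.end) for e in ev.edges)
            for ev in enumerate_events(graph)
        }
        assert got == expected


def _quantified_cassette(counts_by_tissue):
    gene = three_exon_gene()
    graph = build_splice_graph(gene, [])
    events = enumerate_events(graph)
    classify_events(events, graph)
    samples = [SampleMeta(f"{t}_1", t, "IP", 1) for t in counts_by_tissue]
    rows = []
    for key, pos in (("inc1", (100, 200)), ("inc2", (300, 400)), ("skip", (100, 400))):
        rows.append(("chrI", pos[0], pos[1], "+",
                     *[counts_by_tissue[t][key] for t in counts_by_tissue]))
    table = make_table(rows, samples)
    quantify_events(events, table, min_event_reads=10)
    return events


def test_quantify_event_psi_and_coverage_gate():
    events = _quantified_cassette(
        {"a": {"inc1": 90, "inc2": 90, "skip": 10}, "b": {"inc1": 3, "inc2": 3, "skip": 3}}
    )
    src = next(e for e in events if e.side == "source")
    psis = src.psi["a"]
    inc_key = "J:chrI:100-200:+"
    skip_key = "J:chrI:100-400:+"
    assert psis[inc_key] == pytest.approx(0.9)
    assert psis[skip_key] == pytest.approx(0.1)
    assert not src.quantifiable_in("b")  # event total 6 < 10
    # per-tissue PSI of an event sums to 1
    assert sum(psis.values()) == pytest.approx(1.0, abs=1e-9)


def test_quantify_retention_psi():
    gene = GeneModel(
        "g", "chrI", "+", {"t1": [iv(0, 100), iv(200, 300)], "t2": [iv(0, 300)]}
    )
    graph = build_splice_graph(gene, [], retention_counts={(100, 200): 1})
    events = enumerate_events(graph)
    samples = [SampleMeta("a_1", "a", "IP", 1)]
    table = make_table([("chrI", 100, 200, "+", 50)], samples)
    retention = make_table([("chrI", 100, 200, "+", 50)], samples)
    quantify_events(events, table, retention, min_event_reads=10)
    ev = events[0]
    assert ev.psi["a"]["IR:chrI:100-200:+"] == pytest.approx(0.5)


def test_differential_thresholds_and_antisymmetry():
    events = _quantified_cassette(
        {"a": {"inc1": 90, "inc2": 90, "skip": 10}, "b": {"inc1": 5, "inc2": 5, "skip": 95}}
    )
    calls = call_differential(events, "a", "b", 0.20, 0.80)
    src = calls.iloc[0]
    assert abs(src.dpsi) == pytest.approx(0.85)
    assert src.differential and src.switch_like
    rev = call_differential(events, "b", "a", 0.20, 0.80)
    assert rev.dpsi.iloc[0] == pytest.approx(-calls.dpsi.iloc[0])
    # dPSI 0.15: not differential at 0.20, differential at 0.15
    ev15 = _quantified_cassette(
        {"a": {"inc1": 55, "inc2": 55, "skip": 45}, "b": {"inc1": 40, "inc2": 40, "skip": 60}}
    )
    at20 = call_differential(ev15, "a", "b", 0.20, 0.80)
    at15 = call_differential(ev15, "a", "b", 0.15, 0.80)
    assert not at20.differential.any()
    assert at15.differential.all()
    # equal PSI: no flags
    eq = _quantified_cassette(
        {"a": {"inc1": 50, "inc2": 50, "skip": 50}, "b": {"inc1": 50, "inc2": 50, "skip": 50}}
    )
    c = call_differential(eq, "a", "b")
    assert (c.dpsi == 0).all() and not c.differential.any()


def test_differential_skips_unquantifiable_events():
    events = _quantified_cassette(
        {"a": {"inc1": 90, "inc2": 90, "skip": 10}, "b": {"inc1": 1, "inc2": 1, "skip": 1}}
    )
    calls = call_differential(events, "a", "b")
    assert calls.empty
    assert calls.attrs["n_skipped"] == len(events)


def test_class_proportion_test_matches_hand_formula():
    res = class_proportion_test(
        {"complex": 50, "other": 50}, {"complex": 10, "other": 90}, "complex"
    )
    obs = np.array([[50, 50], [10, 90]], dtype=float)
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    stat_hand = ((obs - expected) ** 2 / expected).sum()
    assert res.statistic == pytest.approx(stat_hand, abs=1e-12)
    assert res.p_value == pytest.approx(stats.chi2.sf(stat_hand, 1), abs=1e-15)
    assert res.dof == 1


def test_class_proportion_test_degenerate_cases():
    same = class_proportion_test(
        {"complex": 400, "other": 600}, {"complex": 200, "other": 300}, "complex"
    )
    assert same.statistic == pytest.approx(0.0, abs=1e-9)
    assert same.p_value == pytest.approx(1.0, abs=1e-6)
    zero = class_proportion_test({"a": 10}, {"a": 20}, "missing")
    assert zero.statistic == 0.0 and zero.p_value == 1.0
    small = class_proportion_test({"a": 1, "b": 1}, {"a": 1, "b": 2}, "a")
    assert small.low_expected


def test_expression_vs_splicing():
    genes = [f"g{i}" for i in range(40)]
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(
        rng.integers(50, 500, size=(40, 3)), index=genes, columns=["a", "b", "c"]
    )
    expr.loc["g0"] = [100, 100, 100]
    expr.loc["g1"] = [500, 100, 100]
    dpsi = pd.Series(rng.uniform(-0.8, 0.8, 40), index=genes)
    res = expression_vs_splicing(expr, dpsi, min_expression=50, de_fold=5)
    assert np.allclose(res.fold_change.loc["g0"], 0.0)
    assert res.de_genes["g1"]
    assert not res.de_genes["g0"]
    assert res.n_genes == 40


def test_expression_independent_of_splicing_gives_small_rho():
    rng = np.random.default_rng(11)
    genes = [f"g{i}" for i in range(400)]
    expr = pd.DataFrame(
        rng.integers(20, 2000, size=(400, 3)), index=genes, columns=["a", "b", "c"]
    )
    dpsi = pd.Series(rng.uniform(0, 0.9, 400), index=genes)
    res = expression_vs_splicing(expr, dpsi)
    assert abs(res.rho) < 0.12  # independence regime
    assert res.p_value > 0.01
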