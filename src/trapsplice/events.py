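"""Per-gene splice graphs and local splicing variation (LSV) analysis.

A splice graph's nodes are exonic segments (transcript exons merged and
split at every splice-site boundary); edges are splice junctions plus
optional intron-retention edges.  An LSV is the set of >=2 edges leaving
one node's 3' side (source) or entering one node's 5' side (target).
Events are classified into five canonical modes — cassette exon,
alternative 5'/3' splice site, mutually exclusive exons, alternative
start/terminal exon, intron retention — with everything matching no
single template labelled "complex".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, GenomicInterval, JunctionCountTable, SpliceJunction
from .psi import pool_counts

EVENT_CLASSES = (
    "cassette",
    "alt5ss",
    "alt3ss",
    "alt_start_terminal",
    "intron_retention",
    "mutually_exclusive",
    "complex",
)


@dataclass(frozen=True, order=True)
class Edge:
    """A graph edge: a splice junction or an intron-retention path.

    ``start``/``end`` delimit the spanned intron [start, end); the edge
    connects the node ending at ``start`` to the node starting at ``end``.
    """

    kind: str  # "junction" or "retention"
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def key_str(self) -> str:
        tag = "J" if self.kind == "junction" else "IR"
        return f"{tag}:{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @property
    def intron(self) -> tuple[int, int]:
        return (self.start, self.end)


class SpliceGraph:
    def __init__(self, gene: GeneModel):
        self.gene_id = gene.gene_id
        self.chrom = gene.chrom
        self.strand = gene.strand
        self.nodes: list[GenomicInterval] = []
        self.first_exon_nodes: set[int] = set()
        self.last_exon_nodes: set[int] = set()
        self.edges: list[Edge] = []
        self.orphans: list[SpliceJunction] = []
        self._edge_set: set[tuple[int, int, str]] = set()

    def node_at_start(self, pos: int) -> int | None:
        return self._starts.get(pos)

    def node_at_end(self, pos: int) -> int | None:
        return self._ends.get(pos)

    def _index_nodes(self) -> None:
        self._starts = {n.start: i for i, n in enumerate(self.nodes)}
        self._ends = {n.end: i for i, n in enumerate(self.nodes)}

    def has_edge(self, start: int, end: int, kind: str = "junction") -> bool:
        return (start, end, kind) in self._edge_set

    def add_edge(self, edge: Edge) -> None:
        if (edge.start, edge.end, edge.kind) not in self._edge_set:
            self.edges.append(edge)
            self._edge_set.add((edge.start, edge.end, edge.kind))

    # transcription-order helpers -----------------------------------------
    def upstream_node(self, edge: Edge) -> int:
        """Node index on the 5' (transcription) side of the edge."""
        i = self.node_at_end(edge.start) if self.strand == "+" else self.node_at_start(edge.end)
        assert i is not None
        return i

    def downstream_node(self, edge: Edge) -> int:
        i = self.node_at_start(edge.end) if self.strand == "+" else self.node_at_end(edge.start)
        assert i is not None
        return i

    def is_internal(self, node: int) -> bool:
        return node not in self.first_exon_nodes and node not in self.last_exon_nodes


def build_splice_graph(
    gene: GeneModel,
    junctions: Iterable[SpliceJunction] = (),
    retention_counts: dict[tuple[int, int], int] | Iterable[tuple[int, int]] | None = None,
) -> SpliceGraph:
    """Build the splice graph from annotation plus observed junctions.

    Annotated transcript junctions are always included; observed junctions
    whose endpoints match no exonic boundary (after splitting) are recorded
    as orphans.  ``retention_counts`` introns (with nonzero support) get
    retention edges.
    """
    graph = SpliceGraph(gene)
    observed = [j for j in junctions if j.chrom == gene.chrom]
    annotated = gene.annotated_junctions()

    # exonic coverage: union of transcript exons
    exon_ivs = sorted(
        ((e.start, e.end) for exons in gene.transcripts.values() for e in exons)
    )
    merged: list[list[int]] = []
    for s, e in exon_ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    # split boundaries: exon edges and junction endpoints inside exonic cover
    boundaries: set[int] = set()
    for exons in gene.transcripts.values():
        for e in exons:
            boundaries.update((e.start, e.end))
    for j in list(observed) + annotated:
        boundaries.update((j.start, j.end))

    nodes: list[GenomicInterval] = []
    for s, e in merged:
        cuts = sorted({s, e} | {b for b in boundaries if s < b < e})
        for a, b in zip(cuts, cuts[1:]):
            nodes.append(GenomicInterval(gene.chrom, a, b, gene.strand))
    graph.nodes = nodes
    graph._index_nodes()

    # terminal-exon roles from transcript annotation (strand-aware)
    for exons in gene.transcripts.values():
        first = exons[0] if gene.strand == "+" else exons[-1]
        last = exons[-1] if gene.strand == "+" else exons[0]
        for i, n in enumerate(nodes):
            if n.start >= first.start and n.end <= first.end:
                graph.first_exon_nodes.add(i)
            if n.start >= last.start and n.end <= last.end:
                graph.last_exon_nodes.add(i)

    for j in annotated + observed:
        if graph.node_at_end(j.start) is None or graph.node_at_start(j.end) is None:
            if not j.annotated:
                graph.orphans.append(j)
            continue
        graph.add_edge(Edge("junction", gene.chrom, j.start, j.end, gene.strand))

    if retention_counts:
        introns = (
            retention_counts.keys()
            if isinstance(retention_counts, dict)
            else retention_counts
        )
        for s, e in introns:
            if isinstance(retention_counts, dict) and retention_counts[(s, e)] <= 0:
                continue
            if graph.node_at_end(s) is not None and graph.node_at_start(e) is not None:
                graph.add_edge(Edge("retention", gene.chrom, s, e, gene.strand))
    return graph


@dataclass
class SplicingEvent:
    event_id: str
    gene_id: str
    anchor: GenomicInterval
    side: str  # "source" or "target"
    edges: tuple[Edge, ...]
    event_class: str | None = None
    psi: dict[str, dict[str, float]] = field(default_factory=dict)  # tissue -> edge -> psi
    totals: dict[str, int] = field(default_factory=dict)  # tissue -> event read total
    # genome-ordered (left exon, internal exon, right exon) for cassette events
    cassette_parts: tuple[GenomicInterval, GenomicInterval, GenomicInterval] | None = None

    @property
    def junction_edges(self) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if e.kind == "junction")

    @property
    def retention_edges(self) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if e.kind == "retention")

    def quantifiable_in(self, tissue: str) -> bool:
        return tissue in self.psi


def enumerate_events(graph: SpliceGraph) -> list[SplicingEvent]:
    """All source/target LSVs with >=2 edges, deduplicated on edge sets."""
    events: list[SplicingEvent] = []
    seen: set[frozenset] = set()
    counter = 0
    for ni, node in enumerate(graph.nodes):
        for side in ("source", "target"):
            if side == "source":
                # edges leaving the node's 3' boundary
                if graph.strand == "+":
                    members = [e for e in graph.edges if e.start == node.end]
                else:
                    members = [e for e in graph.edges if e.end == node.start]
            else:
                if graph.strand == "+":
                    members = [e for e in graph.edges if e.end == node.start]
                else:
                    members = [e for e in graph.edges if e.start == node.end]
            if len(members) < 2:
                continue
            key = frozenset((e.kind, e.start, e.end) for e in members)
            if key in seen:
                continue
            seen.add(key)
            counter += 1
            events.append(
                SplicingEvent(
                    event_id=f"{graph.gene_id}:lsv{counter}",
                    gene_id=graph.gene_id,
                    anchor=node,
                    side=side,
                    edges=tuple(sorted(members)),
                )
            )
    return events


# ---------------------------------------------------------------------------
# classification templates
# ---------------------------------------------------------------------------

def _distal_nodes(event: SplicingEvent, graph: SpliceGraph) -> list[int]:
    """The nodes at the far (non-anchor) side of each junction edge."""
    if event.side == "source":
        return [graph.downstream_node(e) for e in event.junction_edges]
    return [graph.upstream_node(e) for e in event.junction_edges]


def _tmpl_cassette(event, graph):
    """Cassette match; returns the (left exon, internal exon, right exon)
    genome-ordered parts, or None."""
    if len(event.edges) != 2 or event.retention_edges:
        return None
    d1, d2 = _distal_nodes(event, graph)
    if d1 == d2:
        return None
    # E = distal node nearer the anchor (the skippable exon); D = far node
    near, far = sorted(
        (d1, d2),
        key=lambda n: abs(graph.nodes[n].start - event.anchor.start),
    )
    if not graph.is_internal(near):
        return None
    n_iv, f_iv = graph.nodes[near], graph.nodes[far]
    if event.side == "source":
        lo, hi = (n_iv.end, f_iv.start) if graph.strand == "+" else (f_iv.end, n_iv.start)
    else:
        lo, hi = (f_iv.end, n_iv.start) if graph.strand == "+" else (n_iv.end, f_iv.start)
    if not (lo < hi and graph.has_edge(lo, hi)):
        return None
    flank1, internal, flank2 = sorted([event.anchor, n_iv, f_iv], key=lambda iv: iv.start)
    return (flank1, internal, flank2)


def _tmpl_altss(event: SplicingEvent, graph: SpliceGraph) -> str | None:
    """Two junctions sharing the anchor site, alternate sites inside one
    contiguous exonic extension.  Source events vary the acceptor (alt3ss),
    target events the donor (alt5ss)."""
    if len(event.edges) != 2 or event.retention_edges:
        return None
    d1, d2 = _distal_nodes(event, graph)
    if d1 == d2:
        return None
    a, b = graph.nodes[d1], graph.nodes[d2]
    contiguous = a.end == b.start or b.end == a.start
    if not contiguous:
        return None
    return "alt3ss" if event.side == "source" else "alt5ss"


def _tmpl_mutually_exclusive(event: SplicingEvent, graph: SpliceGraph) -> bool:
    if len(event.edges) != 2 or event.retention_edges:
        return False
    e1, e2 = event.junction_edges
    d1, d2 = _distal_nodes(event, graph)
    if d1 == d2:
        return False
    if not (graph.is_internal(d1) and graph.is_internal(d2)):
        return False
    iv1, iv2 = graph.nodes[d1], graph.nodes[d2]
    if iv1.end == iv2.start or iv2.end == iv1.start:
        return False  # contiguous segments are an alt-ss pattern
    # no junction directly between the two middle exons
    lo, hi = sorted((d1, d2), key=lambda n: graph.nodes[n].start)
    if graph.has_edge(graph.nodes[lo].end, graph.nodes[hi].start):
        return False
    # both middle exons must splice to a common node on the far side,
    # and the anchor must not splice straight to that node
    if event.side == "source":
        partners1 = {
            graph.downstream_node(e)
            for e in graph.edges
            if e.kind == "junction"
            and graph.upstream_node(e) == d1
            and e not in event.edges
        }
        partners2 = {
            graph.downstream_node(e)
            for e in graph.edges
            if e.kind == "junction"
            and graph.upstream_node(e) == d2
            and e not in event.edges
        }
    else:
        partners1 = {
            graph.upstream_node(e)
            for e in graph.edges
            if e.kind == "junction"
            and graph.downstream_node(e) == d1
            and e not in event.edges
        }
        partners2 = {
            graph.upstream_node(e)
            for e in graph.edges
            if e.kind == "junction"
            and graph.downstream_node(e) == d2
            and e not in event.edges
        }
    common = partners1 & partners2
    if not common:
        return False
    for c in common:
        c_iv = graph.nodes[c]
        a_iv = event.anchor
        lo2, hi2 = sorted((a_iv, c_iv), key=lambda iv: iv.start)
        if not graph.has_edge(lo2.end, hi2.start):
            return True  # found a common partner with no direct anchor->partner skip
    return False


def _tmpl_alt_start_terminal(event: SplicingEvent, graph: SpliceGraph) -> bool:
    if event.retention_edges or len(event.junction_edges) < 2:
        return False
    distal = set(_distal_nodes(event, graph))
    if len(distal) < 2:
        return False
    # contiguous distal segments are one exon with alternative splice sites,
    # not distinct terminal exons
    ivs = sorted((graph.nodes[n] for n in distal), key=lambda x: x.start)
    if any(a.end == b.start for a, b in zip(ivs, ivs[1:])):
        return False
    flags = graph.last_exon_nodes if event.side == "source" else graph.first_exon_nodes
    return all(n in flags for n in distal)


def _tmpl_intron_retention(event: SplicingEvent, graph: SpliceGraph) -> bool:
    if len(event.edges) != 2:
        return False
    kinds = sorted(e.kind for e in event.edges)
    if kinds != ["junction", "retention"]:
        return False
    j = event.junction_edges[0]
    r = event.retention_edges[0]
    return j.intron == r.intron


def classify_event(event: SplicingEvent, graph: SpliceGraph) -> str:
    """Assign one of the six canonical classes or ``complex``.

    Templates are tested in fixed order; an event matching exactly one gets
    that class, anything ambiguous or unmatched is complex.
    """
    if len(event.edges) < 2:
        raise ValueError("an event needs >=2 edges")
    matches: list[str] = []
    parts = _tmpl_cassette(event, graph)
    if parts is not None:
        matches.append("cassette")
    ss = _tmpl_altss(event, graph)
    if ss is not None:
        matches.append(ss)
    if _tmpl_mutually_exclusive(event, graph):
        matches.append("mutually_exclusive")
    if _tmpl_alt_start_terminal(event, graph):
        matches.append("alt_start_terminal")
    if _tmpl_intron_retention(event, graph):
        matches.append("intron_retention")
    if len(matches) == 1:
        if matches[0] == "cassette":
            event.cassette_parts = parts
        return matches[0]
    return "complex"


def classify_events(events: Sequence[SplicingEvent], graph: SpliceGraph) -> None:
    for ev in events:
        ev.event_class = classify_event(ev, graph)


# ---------------------------------------------------------------------------
# quantification and differential calls
# ---------------------------------------------------------------------------

def quantify_events(
    events: Sequence[SplicingEvent],
    table: JunctionCountTable,
    retention_table: JunctionCountTable | None = None,
    min_event_reads: int = 10,
    ip_only: bool = True,
) -> None:
    """Fill per-tissue event PSI: junction count over total event count.

    Counts are pooled per tissue (replicates summed); retention edges draw
    their support from ``retention_table`` (introns with intronic read
    counts).  A tissue where the event total is below ``min_event_reads``
    stays unquantified.
    """
    units, pooled = pool_counts(table, "tissue")
    jx_index = {j.key: i for i, j in enumerate(table.junctions)}
    keep = list(range(len(units)))
    if ip_only:
        ip_tissues = set(table.tissues(fraction="IP"))
        keep = [ui for ui, u in enumerate(units) if u in ip_tissues]
    r_index: dict[tuple, int] = {}
    r_pooled = None
    r_map: dict[str, int] = {}
    if retention_table is not None:
        r_units, r_pooled = pool_counts(retention_table, "tissue")
        r_map = {u: i for i, u in enumerate(r_units)}
        r_index = {j.key: i for i, j in enumerate(retention_table.junctions)}

    for ev in events:
        ev.psi.clear()
        ev.totals.clear()
        for ui in keep:
            unit = units[ui]
            counts: dict[str, int] = {}
            for e in ev.edges:
                key = (e.chrom, e.start, e.end, e.strand)
                if e.kind == "junction":
                    ji = jx_index.get(key)
                    counts[e.key_str] = int(pooled[ji, ui]) if ji is not None else 0
                else:
                    ri = r_index.get(key)
                    if ri is not None and r_pooled is not None and unit in r_map:
                        counts[e.key_str] = int(r_pooled[ri, r_map[unit]])
                    else:
                        counts[e.key_str] = 0
            total = sum(counts.values())
            ev.totals[unit] = total
            if total >= min_event_reads:
                ev.psi[unit] = {k: c / total for k, c in counts.items()}


class DifferentialCall(NamedTuple):
    event_id: str
    tissue_a: str
    tissue_b: str
    ref_edge: str
    psi_a: float
    psi_b: float
    dpsi: float
    differential: bool
    switch_like: bool


def call_differential(
    events: Sequence[SplicingEvent],
    tissue_a: str,
    tissue_b: str,
    differential_min: float = 0.20,
    switch_min: float = 0.80,
) -> pd.DataFrame:
    """ΔPSI of each event's reference junction between two tissues.

    The reference junction is the event edge with the largest read total
    summed across all quantified tissues (ties broken by edge key).  Events
    unquantifiable in either tissue are skipped and counted in
    ``df.attrs['n_skipped']``.
    """
    rows: list[DifferentialCall] = []
    n_skipped = 0
    for ev in events:
        if not (ev.quantifiable_in(tissue_a) and ev.quantifiable_in(tissue_b)):
            n_skipped += 1
            continue
        support: dict[str, float] = {}
        for tissue, psis in ev.psi.items():
            total = ev.totals.get(tissue, 0)
            for key, p in psis.items():
                support[key] = support.get(key, 0.0) + p * total
        ref = max(sorted(support), key=lambda k: support[k])
        pa = ev.psi[tissue_a][ref]
        pb = ev.psi[tissue_b][ref]
        dpsi = pa - pb
        rows.append(
            DifferentialCall(
                ev.event_id,
                tissue_a,
                tissue_b,
                ref,
                pa,
                pb,
                dpsi,
                # tolerance keeps exact-threshold cases from flipping on
                # float rounding of the PSI difference
                abs(dpsi) >= differential_min - 1e-9,
                abs(dpsi) >= switch_min - 1e-9,
            )
        )
    df = pd.DataFrame(rows, columns=DifferentialCall._fields)
    df.attrs["n_skipped"] = n_skipped
    return df


class ProportionTestResult(NamedTuple):
    statistic: float
    p_value: float
    dof: int
    low_expected: bool


def class_proportion_test(
    dist_a: dict[str, int], dist_b: dict[str, int], event_class: str
) -> ProportionTestResult:
    """Pearson chi-squared (no continuity correction) for one class's
    proportion between two class-count distributions (class vs rest, 2x2)."""
    if not dist_a or not dist_b:
        raise ValueError("both distributions must be non-empty")
    a_cls = dist_a.get(event_class, 0)
    a_rest = sum(dist_a.values()) - a_cls
    b_cls = dist_b.get(event_class, 0)
    b_rest = sum(dist_b.values()) - b_cls
    obs = np.array([[a_cls, a_rest], [b_cls, b_rest]], dtype=float)
    if obs.sum(axis=0).min() == 0 or obs.sum(axis=1).min() == 0:
        return ProportionTestResult(0.0, 1.0, 1, True)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return ProportionTestResult(statistic, p, 1, bool(expected.min() < 1))


class ExpressionSplicingResult(NamedTuple):
    fold_change: pd.DataFrame  # genes x tissues, log2 fold change over median
    de_genes: pd.Series  # boolean per gene
    rho: float
    p_value: float
    n_genes: int
    n_dropped: int


def expression_vs_splicing(
    expression: pd.DataFrame,
    dpsi: pd.Series,
    min_expression: int = 50,
    de_fold: float = 5.0,
) -> ExpressionSplicingResult:
    """Relate steady-state expression differences to splicing differences.

    ``expression`` is a gene x tissue read-count matrix, ``dpsi`` a per-gene
    splicing-difference magnitude.  Per gene and tissue the log2 fold change
    over the cross-tissue median (pseudocount 1) is computed; genes whose
    max/min count ratio reaches ``de_fold`` (and whose maximum passes
    ``min_expression``) are flagged differentially expressed.  Returns the
    Spearman correlation between per-gene expression-difference magnitude
    and |ΔPSI| over genes present in both inputs.
    """
    nonzero = expression.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    expr = expression.loc[nonzero]
    median = expr.median(axis=1)
    fc = np.log2(expr.add(1).div(median + 1, axis=0))
    maxc = expr.max(axis=1)
    minc = expr.min(axis=1)
    de = (maxc >= min_expression) & (maxc / np.maximum(minc, 1) >= de_fold)
    shared = fc.index.intersection(dpsi.dropna().index)
    if len(shared) < 3:
        raise ValueError("need >=3 genes shared between expression and dPSI")
    expr_mag = fc.loc[shared].abs().max(axis=1)
    res = stats.spearmanr(expr_mag.to_numpy(), dpsi.loc[shared].abs().to_numpy())
    return ExpressionSplicingResult(
        fc, de, float(res.statistic), float(res.pvalue), len(shared), n_dropped
    )


def events_to_frame(events: Sequence[SplicingEvent]) -> pd.DataFrame:
    """Flat event table: one row per event/tissue/edge with PSI."""
    rows = []
    for ev in events:
        tissues = sorted(set(ev.totals))
        if not tissues:
            rows.append((ev.event_id, ev.gene_id, ev.event_class, ev.side,
                         ";".join(e.key_str for e in ev.edges), "", "", np.nan, 0, False))
        for tissue in tissues:
            quant = ev.quantifiable_in(tissue)
            for e in ev.edges:
                rows.append(
                    (
                        ev.event_id,
                        ev.gene_id,
                        ev.event_class,
                        ev.side,
                        ";".join(x.key_str for x in ev.edges),
                        tissue,
                        e.key_str,
                        ev.psi.get(tissue, {}).get(e.key_str, np.nan),
                        ev.totals.get(tissue, 0),
                        quant,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "gene_id",
            "event_class",
            "side",
            "edges",
            "tissue",
            "edge",
            "psi",
            "event_total",
            "quantifiable",
        ],
    )
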