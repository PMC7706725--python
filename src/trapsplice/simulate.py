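"""Ground-truthed synthetic data with the statistical structure the
analysis assumes.

The generator emulates a tissue-enriched ribosome-affinity (TRAP-seq)
study design: IP libraries profile single tissues (three broad tissues
plus two rare neuronal subtypes), while whole-animal input libraries see
each transcript diluted by its tissue's share of the animal.  IP
libraries additionally enrich their tissue's transcripts by roughly two
orders of magnitude relative to whole-animal abundance, so a transcript
confined to a 2% subtype can be well covered in its IP library yet
expected below one read in the input — the dilution phenomenon behind
tissue-enriched junction detection.  ``input_rate_ratio`` encodes that
enrichment (input reads per transcript per unit IP rate; default 0.01,
i.e. ~100x enrichment).

All outputs are deterministic given (seed, config).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    ConservationTrack,
    GeneModel,
    GenomicInterval,
    JunctionCountTable,
    SampleMeta,
    SpeciesAlignment,
    SpliceJunction,
)
from .conservation import ExonTriplet
from .features import ProteinFeatureTrack, map_exon_to_protein

BASES = np.array(list("ACGT"))


@dataclass
class PhyloBranch:
    substitution_rate: float = 0.1
    indel_rate: float = 0.005  # expected indel events per base
    exon_loss_prob: float = 0.05

    def __post_init__(self) -> None:
        if min(self.substitution_rate, self.indel_rate, self.exon_loss_prob) < 0:
            raise ValueError("phylogeny rates must be >= 0")


def _default_phylogeny() -> dict[str, PhyloBranch]:
    return {
        "sp1": PhyloBranch(0.05, 0.002, 0.02),
        "sp2": PhyloBranch(0.10, 0.004, 0.06),
        "sp3": PhyloBranch(0.15, 0.006, 0.12),
        "sp4": PhyloBranch(0.22, 0.009, 0.20),
        "sp5": PhyloBranch(0.30, 0.012, 0.30),
        "sp6": PhyloBranch(0.40, 0.016, 0.45),
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 200
    # whole-animal mixture fractions; the two subtypes are rare cell classes
    tissues: dict[str, float] = field(
        default_factory=lambda: {
            "neurons": 0.26,
            "muscle": 0.30,
            "intestine": 0.40,
            "dopaminergic": 0.02,
            "serotonergic": 0.02,
        }
    )
    subtype_tissues: tuple[str, ...] = ("dopaminergic", "serotonergic")
    n_replicates: int = 2
    n_input_replicates: int = 2
    events_per_class: dict[str, int] = field(
        default_factory=lambda: {
            "cassette": 40,
            "alt5ss": 10,
            "alt3ss": 10,
            "mutually_exclusive": 8,
            "alt_start_terminal": 8,
            "intron_retention": 10,
            "complex": 6,
        }
    )
    regulated_fraction: float = 0.5  # of cassette events, tissue-regulated
    regulated_dpsi: float = 0.7
    regulated_dpsi_values: tuple[float, ...] | None = None  # cycle if set
    depth: float = 200.0  # expected event-group reads per tissue per replicate
    constitutive_depth_range: tuple[float, float] = (300.0, 800.0)
    n_exclusive_genes: int = 10  # genes expressed only in a subtype tissue
    exclusive_depth: float = 100.0
    replicate_dispersion: float = 5e-4  # beta/Dirichlet-multinomial rho
    input_rate_ratio: float = 0.01  # input reads per unit IP rate (TRAP enrichment)
    noise_free: bool = False  # deterministic expected counts
    exon_len_range: tuple[int, int] = (75, 150)
    intron_len_range: tuple[int, int] = (60, 100)
    frame_preserving_rates: dict[str, float] = field(
        default_factory=lambda: {
            "constitutive": 0.45,
            "alt_non_tissue": 0.60,
            "alt_tissue_regulated": 0.80,
        }
    )
    microexon_lengths: tuple[int, ...] = (6, 15, 21, 27)
    phylogeny: dict[str, PhyloBranch] = field(default_factory=_default_phylogeny)
    reference_species: str = "ref"
    conservation_delta: float = 2.0
    flank_conserved_len: int = 23
    site_protection: float = 0.1  # substitution-rate multiplier at regulated sites
    regulated_loss_factor: float = 0.5  # exon-loss multiplier for regulated exons
    idr_overlap_rates: dict[str, float] = field(
        default_factory=lambda: {
            "constitutive": 0.30,
            "alt_non_tissue": 0.55,
            "alt_tissue_regulated": 0.80,
        }
    )
    domain_overlap_rates: dict[str, float] = field(
        default_factory=lambda: {
            "constitutive": 0.60,
            "alt_non_tissue": 0.40,
            "alt_tissue_regulated": 0.30,
        }
    )

    def validate(self) -> None:
        total = sum(self.tissues.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tissue mixture fractions sum to {total}, not 1")
        if any(not 0 < f < 1 for f in self.tissues.values()):
            raise ValueError("mixture fractions must lie in (0, 1)")
        n_events = sum(self.events_per_class.values())
        if n_events + self.n_exclusive_genes > self.n_genes:
            raise ValueError(
                f"{n_events} events + {self.n_exclusive_genes} exclusive genes "
                f"exceed {self.n_genes} genes"
            )
        if not 0 <= self.replicate_dispersion < 1:
            raise ValueError("replicate_dispersion must be in [0, 1)")

    def broad_tissues(self) -> list[str]:
        return [t for t in self.tissues if t not in self.subtype_tissues]


def dilution_config(seed: int = 0) -> SimulationConfig:
    """Study config for the tissue-enriched junction (dilution) experiment:
    highly expressed shared genes plus subtype-exclusive genes, no
    alternative events."""
    return SimulationConfig(
        seed=seed,
        n_genes=120,
        events_per_class={},
        n_exclusive_genes=60,
        constitutive_depth_range=(500.0, 1000.0),
        exclusive_depth=100.0,
    )


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class TrueEvent:
    gene_id: str
    event_class: str
    paths: tuple[tuple[str, ...], ...]  # junction key_str per isoform path
    psi: dict[str, tuple[float, ...]]  # tissue -> path probabilities
    regulated: bool
    dpsi_target: float | None
    internal_exon: GenomicInterval | None = None
    retention_intron: tuple[str, int, int, str] | None = None
    is_microexon: bool = False


@dataclass
class TrueJunction:
    key_str: str
    gene_id: str
    exclusive_tissue: str | None
    rates: dict[str, float]  # expected IP count per replicate per tissue


@dataclass
class TrueTriplet:
    gene_id: str
    triplet: ExonTriplet
    conserved: dict[str, bool] = field(default_factory=dict)


@dataclass
class GroundTruth:
    events: dict[str, TrueEvent] = field(default_factory=dict)  # by gene
    junctions: dict[str, TrueJunction] = field(default_factory=dict)
    triplets: list[TrueTriplet] = field(default_factory=list)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, n)]


def _stamp_intron_ends(seq: np.ndarray, start: int, end: int, strand: str) -> None:
    """Write canonical splice dinucleotides (genome letters) at an intron's
    ends: GT..AG in transcription orientation."""
    if strand == "+":
        seq[start], seq[start + 1] = "G", "T"
        seq[end - 2], seq[end - 1] = "A", "G"
    else:
        seq[start], seq[start + 1] = "C", "T"
        seq[end - 2], seq[end - 1] = "A", "C"


def _draw_len(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def _adjust_frame(rng: np.random.Generator, length: int, preserve_prob: float) -> int:
    """Nudge an exon length so it is a multiple of 3 with the given
    probability."""
    want = rng.random() < preserve_prob
    rem = length % 3
    if want and rem:
        return length + (3 - rem)
    if not want and not rem:
        return length + int(rng.integers(1, 3))
    return length


def _junction_key(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}-{end}:{strand}"


class _GeneBuilder:
    """Lays out one gene's exons left-to-right and derives transcripts."""

    def __init__(self, gene_id: str, chrom: str, strand: str, offset: int):
        self.gene_id = gene_id
        self.chrom = chrom
        self.strand = strand
        self.offset = offset
        self.exons: list[GenomicInterval] = []  # genome order

    def add_exons(self, rng, cfg: SimulationConfig, lengths: Sequence[int],
                  intron_lengths: Sequence[int]) -> None:
        pos = self.offset
        for i, L in enumerate(lengths):
            self.exons.append(GenomicInterval(self.chrom, pos, pos + L, self.strand))
            pos += L
            if i < len(lengths) - 1:
                pos += intron_lengths[i]
        self.end = pos

    def tx(self, tx_indices: Sequence[int]) -> list[GenomicInterval]:
        """Transcript from tx-order exon indices (0 = 5' first)."""
        n = len(self.exons)
        genome_idx = [i if self.strand == "+" else n - 1 - i for i in tx_indices]
        return sorted((self.exons[i] for i in genome_idx), key=lambda e: e.start)

    def tx_exon(self, tx_index: int) -> GenomicInterval:
        n = len(self.exons)
        return self.exons[tx_index if self.strand == "+" else n - 1 - tx_index]

    def junction_between(self, exon_a: GenomicInterval, exon_b: GenomicInterval) -> str:
        lo, hi = sorted((exon_a, exon_b), key=lambda e: e.start)
        return _junction_key(self.chrom, lo.end, hi.start, self.strand)

    def extend_tx_upstream(self, exon: GenomicInterval, d: int) -> GenomicInterval:
        """Extend an exon into its tx-upstream intron (acceptor shift)."""
        if self.strand == "+":
            return GenomicInterval(self.chrom, exon.start - d, exon.end, self.strand)
        return GenomicInterval(self.chrom, exon.start, exon.end + d, self.strand)

    def extend_tx_downstream(self, exon: GenomicInterval, d: int) -> GenomicInterval:
        """Extend an exon into its tx-downstream intron (donor shift)."""
        if self.strand == "+":
            return GenomicInterval(self.chrom, exon.start, exon.end + d, self.strand)
        return GenomicInterval(self.chrom, exon.start - d, exon.end, self.strand)


def _event_psi_profiles(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    n_paths: int,
    regulated: bool,
    dpsi: float | None,
) -> tuple[dict[str, tuple[float, ...]], float | None]:
    tissues = list(cfg.tissues)
    if n_paths == 2:
        if regulated:
            d = dpsi if dpsi is not None else cfg.regulated_dpsi
            hi = 0.90
            lo = hi - d
            broad = cfg.broad_tissues()
            up = broad[int(rng.integers(0, len(broad)))]
            psi = {t: ((hi, 1 - hi) if t == up else (lo, 1 - lo)) for t in tissues}
            return psi, d
        p = float(rng.uniform(0.1, 0.9))
        return {t: (p, 1 - p) for t in tissues}, None
    # multi-path (complex): fixed moderate usage
    base = np.array([0.5, 0.3, 0.2][:n_paths])
    base = base / base.sum()
    return {t: tuple(base) for t in tissues}, None


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, GeneModel], GroundTruth]:
    """Genome FASTA sequences, gene models, and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    genes: dict[str, GeneModel] = {}
    chrom = "chrI"
    seq_len_guess = config.n_genes * 2000 + 1000
    seq = _rand_seq(rng, seq_len_guess)

    kinds: list[str] = []
    for cls, n in sorted(config.events_per_class.items()):
        kinds += [cls] * n
    n_cassette = config.events_per_class.get("cassette", 0)
    n_regulated = int(round(n_cassette * config.regulated_fraction))
    kinds += ["exclusive"] * config.n_exclusive_genes
    kinds += ["constitutive"] * (config.n_genes - len(kinds))
    rng.shuffle(kinds)

    dpsi_values = list(config.regulated_dpsi_values or ())
    regulated_seen = 0
    micro_queue = list(config.microexon_lengths)
    cassette_seen = 0
    exclusive_seen = 0
    pos = 100

    for gi, kind in enumerate(kinds):
        gene_id = f"g{gi + 1:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        b = _GeneBuilder(gene_id, chrom, strand, pos)
        elo, ehi = config.exon_len_range
        ilo, ihi = config.intron_len_range
        n_exons = {"mutually_exclusive": 6, "complex": 6}.get(kind, 5)
        exon_lens = [_draw_len(rng, elo, ehi) for _ in range(n_exons)]
        intron_lens = [_draw_len(rng, max(ilo, 56), ihi) for _ in range(n_exons - 1)]

        regulated = False
        dpsi = None
        event_cls = kind if kind in (
            "cassette", "alt5ss", "alt3ss", "mutually_exclusive",
            "alt_start_terminal", "intron_retention", "complex",
        ) else None

        if kind == "cassette":
            regulated = cassette_seen < n_regulated
            if regulated:
                if dpsi_values:
                    dpsi = dpsi_values[regulated_seen % len(dpsi_values)]
                regulated_seen += 1
            cls_label = "alt_tissue_regulated" if regulated else "alt_non_tissue"
            if regulated and micro_queue:
                exon_lens[2] = micro_queue.pop(0)
            else:
                exon_lens[2] = _adjust_frame(
                    rng, exon_lens[2], config.frame_preserving_rates[cls_label]
                )
            cassette_seen += 1
        elif kind in ("constitutive", "exclusive"):
            exon_lens[2] = _adjust_frame(
                rng, exon_lens[2], config.frame_preserving_rates["constitutive"]
            )

        b.add_exons(rng, config, exon_lens, intron_lens)
        while b.end + 200 > len(seq):
            seq = np.concatenate([seq, _rand_seq(rng, 200000)])

        transcripts: dict[str, list[GenomicInterval]] = {}
        paths: list[tuple[str, ...]] = []
        internal_exon = None
        retention_intron = None

        all_tx = list(range(n_exons))
        if kind == "cassette":
            inc = b.tx(all_tx)
            skip = b.tx([i for i in all_tx if i != 2])
            transcripts = {"t1": inc, "t2": skip}
            e1, e2, e3 = b.tx_exon(1), b.tx_exon(2), b.tx_exon(3)
            paths = [
                (b.junction_between(e1, e2), b.junction_between(e2, e3)),
                (b.junction_between(e1, e3),),
            ]
            internal_exon = e2
        elif kind in ("alt3ss", "alt5ss"):
            exon = b.tx_exon(2)
            d = int(rng.choice([6, 9, 12]))
            if kind == "alt3ss":
                variant = b.extend_tx_upstream(exon, d)
                partner = b.tx_exon(1)
            else:
                variant = b.extend_tx_downstream(exon, d)
                partner = b.tx_exon(3)
            var_tx = [b.tx_exon(i) if i != 2 else variant for i in all_tx]
            transcripts = {"t1": b.tx(all_tx), "t2": sorted(var_tx, key=lambda e: e.start)}
            paths = [
                (b.junction_between(partner, exon),),
                (b.junction_between(partner, variant),),
            ]
        elif kind == "mutually_exclusive":
            txA = b.tx([0, 1, 2, 4, 5])
            txB = b.tx([0, 1, 3, 4, 5])
            transcripts = {"t1": txA, "t2": txB}
            e1, eA, eB, e4 = b.tx_exon(1), b.tx_exon(2), b.tx_exon(3), b.tx_exon(4)
            paths = [
                (b.junction_between(e1, eA), b.junction_between(eA, e4)),
                (b.junction_between(e1, eB), b.junction_between(eB, e4)),
            ]
        elif kind == "alt_start_terminal":
            if gi % 4 < 2:  # alternative first exons
                txA = b.tx([0] + list(range(2, n_exons)))
                txB = b.tx(list(range(1, n_exons)))
                a, bb, common = b.tx_exon(0), b.tx_exon(1), b.tx_exon(2)
            else:  # alternative last exons
                txA = b.tx(list(range(0, n_exons - 1)))
                txB = b.tx(list(range(0, n_exons - 2)) + [n_exons - 1])
                a, bb, common = b.tx_exon(n_exons - 2), b.tx_exon(n_exons - 1), b.tx_exon(n_exons - 3)
            transcripts = {"t1": txA, "t2": txB}
            paths = [
                (b.junction_between(common, a),),
                (b.junction_between(common, bb),),
            ]
        elif kind == "intron_retention":
            spliced = b.tx(all_tx)
            eL, eR = b.tx_exon(2), b.tx_exon(3)
            lo, hi = sorted((eL, eR), key=lambda e: e.start)
            merged = GenomicInterval(chrom, lo.start, hi.end, strand)
            retained = sorted(
                [e for e in spliced if e.start not in (lo.start, hi.start)] + [merged],
                key=lambda e: e.start,
            )
            transcripts = {"t1": spliced, "t2": retained}
            jx = b.junction_between(eL, eR)
            paths = [(jx,), ()]  # path 2 = retained (intronic reads)
            retention_intron = (chrom, lo.end, hi.start, strand)
        elif kind == "complex":
            inc = b.tx(all_tx)
            skip1 = b.tx([i for i in all_tx if i != 2])
            skip2 = b.tx([i for i in all_tx if i not in (2, 3)])
            transcripts = {"t1": inc, "t2": skip1, "t3": skip2}
            e1, e2, e3, e4 = b.tx_exon(1), b.tx_exon(2), b.tx_exon(3), b.tx_exon(4)
            paths = [
                (b.junction_between(e1, e2), b.junction_between(e2, e3)),
                (b.junction_between(e1, e3),),
                (b.junction_between(e1, e4),),
            ]
        else:  # constitutive or exclusive
            transcripts = {"t1": b.tx(all_tx)}
            internal_exon = b.tx_exon(2)

        transcripts = {f"{gene_id}.{k}": v for k, v in transcripts.items()}
        gene = GeneModel(gene_id, chrom, strand, transcripts)
        # stamp canonical splice sites for every transcript intron
        for exons in transcripts.values():
            for a_, b_ in zip(exons, exons[1:]):
                _stamp_intron_ends(seq, a_.end, b_.start, strand)
        if retention_intron is not None:
            _stamp_intron_ends(seq, retention_intron[1], retention_intron[2], strand)

        # CDS on the primary transcript: full exons, 3' end trimmed to a
        # codon boundary
        t1 = transcripts[f"{gene_id}.t1"]
        total = sum(len(e) for e in t1)
        trim = total % 3
        cds_parts = []
        cum = 0
        order = t1 if strand == "+" else t1[::-1]
        for e in order:
            s_, e_ = e.start, e.end
            take = len(e)
            if cum + take > total - trim:
                take = total - trim - cum
            if take <= 0:
                break
            phase = (3 - cum % 3) % 3
            if strand == "+":
                cds_parts.append((GenomicInterval(chrom, s_, s_ + take, strand), phase))
            else:
                cds_parts.append((GenomicInterval(chrom, e_ - take, e_, strand), phase))
            cum += take
        gene.cds[f"{gene_id}.t1"] = sorted(cds_parts, key=lambda p: p[0].start)
        genes[gene_id] = gene

        exclusive_tissue = None
        if kind == "exclusive":
            exclusive_tissue = config.subtype_tissues[
                exclusive_seen % len(config.subtype_tissues)
            ]
            exclusive_seen += 1

        if event_cls is not None:
            psi, dpsi_used = _event_psi_profiles(
                rng, config, len(paths), regulated, dpsi
            )
            truth.events[gene_id] = TrueEvent(
                gene_id,
                event_cls,
                tuple(tuple(p) for p in paths),
                psi,
                regulated,
                dpsi_used,
                internal_exon=internal_exon,
                retention_intron=retention_intron,
                is_microexon=internal_exon is not None and len(internal_exon) <= 27,
            )

        # per-junction truth rates
        gene_rate = (
            config.depth
            if event_cls is not None
            else (
                config.exclusive_depth
                if kind == "exclusive"
                else float(np.exp(rng.uniform(*np.log(config.constitutive_depth_range))))
            )
        )
        event = truth.events.get(gene_id)
        for j in gene.annotated_junctions():
            key = j.key_str()
            rates = {}
            for t in config.tissues:
                if exclusive_tissue is not None:
                    rates[t] = gene_rate if t == exclusive_tissue else 0.0
                elif event is not None:
                    usage = sum(
                        event.psi[t][pi]
                        for pi, p in enumerate(event.paths)
                        if key in p
                    )
                    if not any(key in p for p in event.paths):
                        usage = 1.0  # constitutive within the gene
                    rates[t] = config.depth * usage
                else:
                    rates[t] = gene_rate
            truth.junctions[key] = TrueJunction(key, gene_id, exclusive_tissue, rates)

        # triplet truth (internal exon with flanks) for cassette/constitutive
        trip = None
        if kind == "cassette":
            label = "alt_tissue_regulated" if regulated else "alt_non_tissue"
            trip = _triplet_from_builder(b, label)
        elif kind == "constitutive":
            trip = _triplet_from_builder(b, "constitutive")
        if trip is not None:
            truth.triplets.append(TrueTriplet(gene_id, trip))

        pos = b.end + _draw_len(rng, 200, 400)

    genome = {chrom: "".join(seq[: pos + 100])}
    return genome, genes, truth


def _triplet_from_builder(b: _GeneBuilder, label: str) -> ExonTriplet:
    e1, e2, e3 = b.tx_exon(1), b.tx_exon(2), b.tx_exon(3)
    lo, mid, hi = sorted((e1, e2, e3), key=lambda e: e.start)
    up_iv = GenomicInterval(b.chrom, lo.end, mid.start, b.strand)
    down_iv = GenomicInterval(b.chrom, mid.end, hi.start, b.strand)
    if b.strand == "+":
        return ExonTriplet(b.gene_id, lo, up_iv, mid, down_iv, hi, label)
    return ExonTriplet(b.gene_id, hi, down_iv, mid, up_iv, lo, label)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(
    config: SimulationConfig,
    genes: dict[str, GeneModel],
    truth: GroundTruth,
) -> tuple[JunctionCountTable, JunctionCountTable]:
    """IP junction counts per tissue/replicate plus whole-animal input
    samples, and a matching intron-retention count table."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    tissues = list(config.tissues)
    samples = [
        SampleMeta(f"{t}_ip_{r}", t, "IP", r)
        for t in tissues
        for r in range(1, config.n_replicates + 1)
    ] + [
        SampleMeta(f"input_{r}", "whole_animal", "input", r)
        for r in range(1, config.n_input_replicates + 1)
    ]
    jx_keys = sorted(truth.junctions)
    jx_index = {k: i for i, k in enumerate(jx_keys)}
    counts = np.zeros((len(jx_keys), len(samples)), dtype=np.int64)

    retention_keys = sorted(
        ev.retention_intron for ev in truth.events.values() if ev.retention_intron
    )
    r_index = {k: i for i, k in enumerate(retention_keys)}
    r_counts = np.zeros((len(retention_keys), len(samples)), dtype=np.int64)

    rho = config.replicate_dispersion

    def draw_total(rate: float) -> int:
        if config.noise_free:
            return int(round(rate))
        return int(rng.poisson(rate))

    events_by_gene = truth.events
    for si, s in enumerate(samples):
        if s.fraction == "IP":
            for gene_id, ev in events_by_gene.items():
                probs = np.array(ev.psi[s.tissue], dtype=float)
                N = draw_total(config.depth)
                if N > 0:
                    if config.noise_free or rho == 0:
                        path_counts = np.round(probs * N).astype(np.int64)
                    else:
                        alpha = probs * (1 - rho) / rho
                        p_rep = rng.dirichlet(np.maximum(alpha, 1e-8))
                        path_counts = rng.multinomial(N, p_rep)
                else:
                    path_counts = np.zeros(len(probs), dtype=np.int64)
                for pi, path in enumerate(ev.paths):
                    for key in path:
                        counts[jx_index[key], si] += path_counts[pi]
                    if not path and ev.retention_intron:
                        r_counts[r_index[ev.retention_intron], si] += path_counts[pi]
            for key in jx_keys:
                tj = truth.junctions[key]
                if tj.gene_id in events_by_gene:
                    ev = events_by_gene[tj.gene_id]
                    if any(key in p for p in ev.paths):
                        continue  # handled above
                counts[jx_index[key], si] += draw_total(tj.rates[s.tissue])
        else:  # whole-animal input: diluted mixture, TRAP-enrichment inverse
            def rate_for(key: str, tissue: str) -> float:
                tj = truth.junctions[key]
                ev = events_by_gene.get(tj.gene_id)
                if ev is not None and any(key in p for p in ev.paths):
                    usage = sum(
                        ev.psi[tissue][pi] for pi, p in enumerate(ev.paths) if key in p
                    )
                    return config.depth * usage
                return tj.rates[tissue]

            for key in jx_keys:
                mixture = sum(config.tissues[t] * rate_for(key, t) for t in tissues)
                counts[jx_index[key], si] += draw_total(config.input_rate_ratio * mixture)
            for ev in events_by_gene.values():
                if not ev.retention_intron:
                    continue
                ret_rate = sum(
                    config.tissues[t] * config.depth * ev.psi[t][1] for t in tissues
                )
                r_counts[r_index[ev.retention_intron], si] += draw_total(
                    config.input_rate_ratio * ret_rate
                )

    def parse_key(k: str) -> SpliceJunction:
        chrom, span, strand = k.split(":")
        a, b = span.split("-")
        return SpliceJunction(GenomicInterval(chrom, int(a), int(b), strand))

    table = JunctionCountTable([parse_key(k) for k in jx_keys], samples, counts)
    r_junctions = [
        SpliceJunction(GenomicInterval(c, s_, e_, st)) for (c, s_, e_, st) in retention_keys
    ]
    retention = JunctionCountTable(r_junctions, samples, r_counts)
    return table, retention


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def _evolve_region(
    rng: np.random.Generator,
    ref: str,
    branch: PhyloBranch,
    protected: set[int],
    protection: float,
    lose: tuple[int, int] | None,
) -> tuple[str, str]:
    """Evolve one species copy of a region; returns (gapped_ref, gapped_sp)
    rows of the true pairwise alignment (region coordinates)."""
    n = len(ref)
    chars = list(ref)
    # substitutions
    rates = np.full(n, branch.substitution_rate)
    if protected:
        idx = np.fromiter(protected, dtype=int)
        rates[idx] *= protection
    hits = np.nonzero(rng.random(n) < rates)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != chars[i]]
        chars[i] = choices[rng.integers(0, 3)]
    deleted = np.zeros(n, dtype=bool)
    if lose is not None:
        deleted[lose[0] : lose[1]] = True
    inserts = [""] * (n + 1)
    n_indels = rng.poisson(branch.indel_rate * n)
    for _ in range(n_indels):
        length = int(rng.geometric(0.5))
        at = int(rng.integers(0, n))
        if rng.random() < 0.5:
            deleted[at : at + length] = True
        else:
            inserts[at] += "".join(BASES[rng.integers(0, 4, length)])
    ref_row = []
    sp_row = []
    for i in range(n + 1):
        if inserts[i]:
            ref_row.append("-" * len(inserts[i]))
            sp_row.append(inserts[i])
        if i < n:
            ref_row.append(ref[i])
            sp_row.append("-" if deleted[i] else chars[i])
    return "".join(ref_row), "".join(sp_row)


def simulate_phylogeny(
    config: SimulationConfig,
    genome: dict[str, str],
    truth: GroundTruth,
) -> list[SpeciesAlignment]:
    """Evolve each triplet region across the configured species and return
    the true multi-species alignments (one block per triplet).

    Exon loss deletes the internal exon atomically; the true conservation
    label per species is simply "exon not lost".  Splice-site dinucleotides
    of tissue-regulated triplets substitute at a reduced rate
    (``site_protection``).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    alignments: list[SpeciesAlignment] = []
    ref_sp = config.reference_species
    for tt in truth.triplets:
        trip = tt.triplet
        lo, hi = trip.span
        ref = genome[trip.chrom][lo:hi]
        n = len(ref)
        protected: set[int] = set()
        if trip.class_label == "alt_tissue_regulated":
            for intron in trip.introns:
                for p in (intron.start, intron.start + 1, intron.end - 2, intron.end - 1):
                    protected.add(p - lo)
        exon_span = (trip.internal_exon.start - lo, trip.internal_exon.end - lo)

        per_species: dict[str, tuple[str, str]] = {}
        for sp, branch in config.phylogeny.items():
            loss_p = branch.exon_loss_prob
            if trip.class_label == "alt_tissue_regulated":
                loss_p *= config.regulated_loss_factor
            lost = bool(rng.random() < loss_p)
            tt.conserved[sp] = not lost
            per_species[sp] = _evolve_region(
                rng, ref, branch, protected, config.site_protection,
                exon_span if lost else None,
            )
        # merge the pairwise rows into one block on reference coordinates
        others = list(per_species)
        ins: dict[str, list[str]] = {}
        chars: dict[str, list[str]] = {}
        for sp in others:
            ref_row, sp_row = per_species[sp]
            slots = [""] * (n + 1)
            aligned = []
            p = 0
            for rc, sc in zip(ref_row, sp_row):
                if rc == "-":
                    slots[p] += sc
                else:
                    aligned.append(sc)
                    p += 1
            ins[sp] = slots
            chars[sp] = aligned
        ins_len = [max(len(ins[sp][k]) for sp in others) for k in range(n + 1)]
        rows: dict[str, list[str]] = {sp: [] for sp in [ref_sp] + others}
        for k in range(n + 1):
            pad = ins_len[k]
            if pad:
                rows[ref_sp].append("-" * pad)
                for sp in others:
                    seg = ins[sp][k]
                    rows[sp].append(seg + "-" * (pad - len(seg)))
            if k < n:
                rows[ref_sp].append(ref[k])
                for sp in others:
                    rows[sp].append(chars[sp][k])
        merged = {sp: "".join(parts) for sp, parts in rows.items()}
        alignments.append(
            SpeciesAlignment(merged, ref_sp, ref_chrom=trip.chrom, ref_start=lo)
        )
    return alignments


# ---------------------------------------------------------------------------
# conservation track and protein features
# ---------------------------------------------------------------------------

def simulate_tracks_and_features(
    config: SimulationConfig,
    genes: dict[str, GeneModel],
    truth: GroundTruth,
) -> tuple[ConservationTrack, ProteinFeatureTrack]:
    """Per-base conservation scores over triplet regions (baseline N(0,1),
    +delta within ``flank_conserved_len`` nt of regulated exons' splice
    sites) and protein domain/IDR intervals placed to hit the configured
    per-class overlap rates."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    track = ConservationTrack()
    w = config.flank_conserved_len
    for tt in truth.triplets:
        trip = tt.triplet
        lo, hi = trip.span
        scores = rng.normal(0.0, 1.0, hi - lo)
        if trip.class_label == "alt_tissue_regulated" and config.conservation_delta:
            exon = trip.internal_exon
            for intron in trip.introns:
                # the intron end adjacent to the internal exon
                if intron.end == exon.start:
                    region = range(max(intron.start, exon.start - w), exon.start)
                elif intron.start == exon.end:
                    region = range(exon.end, min(intron.end, exon.end + w))
                else:
                    continue
                for p in region:
                    scores[p - lo] += config.conservation_delta
        for i, sc in enumerate(scores):
            track.set_range(trip.chrom, lo + i, lo + i + 1, float(sc))

    feats = ProteinFeatureTrack()
    for tt in truth.triplets:
        gene = genes[tt.gene_id]
        cds = next(iter(gene.cds.values()), None)
        if not cds:
            continue
        aa_len = sum(len(iv) for iv, _ in cds) // 3
        aa = map_exon_to_protein(tt.triplet.internal_exon, cds, gene.strand)
        if aa is None:
            continue
        aa_s, aa_e = aa
        cls = tt.triplet.class_label
        for label, rates in (("idr", config.idr_overlap_rates),
                             ("domain", config.domain_overlap_rates)):
            rate = rates.get(cls, 0.0)
            if rng.random() < rate:
                s = max(1, aa_s - int(rng.integers(0, 5)))
                e = min(aa_len, aa_e + int(rng.integers(0, 5)))
                feats.add(tt.gene_id, s, e, label)
            else:
                if aa_e + 20 <= aa_len:
                    feats.add(tt.gene_id, aa_e + 5, aa_e + 15, label)
                elif aa_s - 20 >= 1:
                    feats.add(tt.gene_id, aa_s - 15, aa_s - 5, label)
    return track, feats


# ---------------------------------------------------------------------------
# convenience bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome: dict[str, str]
    genes: dict[str, GeneModel]
    truth: GroundTruth
    counts: JunctionCountTable
    retention: JunctionCountTable
    alignments: list[SpeciesAlignment]
    conservation: ConservationTrack
    protein_features: ProteinFeatureTrack


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    config = config or SimulationConfig()
    genome, genes, truth = simulate_annotation(config)
    counts, retention = simulate_counts(config, genes, truth)
    alignments = simulate_phylogeny(config, genome, truth)
    track, feats = simulate_tracks_and_features(config, genes, truth)
    return SimulatedStudy(
        config, genome, genes, truth, counts, retention, alignments, track, feats
    )


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a flat mapping (YAML/JSON-friendly)."""
    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(SimulationConfig)}
    for k, v in d.items():
        if k not in fields:
            raise ValueError(f"unknown config key {k!r}")
        if k == "phylogeny":
            v = {sp: PhyloBranch(*vals) if not isinstance(vals, PhyloBranch) else vals
                 for sp, vals in v.items()}
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return SimulationConfig(**kwargs)
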