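"""Shared domain types for junction-centric splicing analysis.

All genomic coordinates are 0-based, half-open ``[start, end)`` on the
forward genome strand; strand only decides 5'/3' orientation.  External
formats (GTF, STAR SJ tables, wiggle) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class SpliceJunction:
    """An intron: the junction between a splice donor and acceptor.

    ``interval`` covers the intron.  The donor is the first intronic base in
    transcription order (the GT side), the acceptor the last (the AG side);
    on the minus strand the two swap genomic ends.  ``strand_undefined``
    marks junctions whose source reported no strand (kept as '+').
    """

    interval: GenomicInterval
    annotated: bool = False
    strand_undefined: bool = False

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def donor(self) -> int:
        """Genomic position of the first intronic base, strand-aware."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def acceptor(self) -> int:
        """Genomic position of the last intronic base, strand-aware."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def key(self) -> tuple[str, int, int, str]:
        """Identity: (chrom, start, end, strand); flags are advisory."""
        return (self.chrom, self.start, self.end, self.strand)

    def key_str(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    tissue: str
    fraction: str  # "IP" or "input"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.fraction not in ("IP", "input"):
            raise ValueError(f"fraction must be 'IP' or 'input', got {self.fraction!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.tissue, self.fraction, self.replicate)


class JunctionCountTable:
    """Junctions x samples matrix of non-negative read counts."""

    def __init__(
        self,
        junctions: Sequence[SpliceJunction],
        samples: Sequence[SampleMeta],
        counts: np.ndarray,
    ) -> None:
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (len(junctions), len(samples)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(junctions)} junctions x {len(samples)} samples"
            )
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        keys = [j.key for j in junctions]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate junctions in table")
        skeys = [s.key for s in samples]
        if len(set(skeys)) != len(skeys):
            raise ValueError("duplicate (tissue, fraction, replicate) in samples")
        self.junctions = list(junctions)
        self.samples = list(samples)
        self.counts = counts
        self._index = {k: i for i, k in enumerate(keys)}

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def junction_index(self, key: tuple[str, int, int, str]) -> int:
        return self._index[key]

    def sample_indices(self, tissue: str | None = None, fraction: str | None = None) -> list[int]:
        out = []
        for i, s in enumerate(self.samples):
            if tissue is not None and s.tissue != tissue:
                continue
            if fraction is not None and s.fraction != fraction:
                continue
            out.append(i)
        return out

    def tissues(self, fraction: str | None = None) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if fraction is not None and s.fraction != fraction:
                continue
            if s.tissue not in seen:
                seen.append(s.tissue)
        return seen

    def subset_junctions(self, indices: Sequence[int]) -> "JunctionCountTable":
        return JunctionCountTable(
            [self.junctions[i] for i in indices], self.samples, self.counts[list(indices)]
        )

    def sorted(self) -> "JunctionCountTable":
        """Deterministic row order: (chrom, start, end, strand)."""
        order = sorted(range(self.n_junctions), key=lambda i: self.junctions[i].key)
        return self.subset_junctions(order)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, JunctionCountTable):
            return NotImplemented
        return (
            self.junctions == other.junctions
            and self.samples == other.samples
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class GeneModel:
    """Exon structure of one gene: transcripts as genome-ordered exon lists."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, list[GenomicInterval]]
    cds: dict[str, list[tuple[GenomicInterval, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, exons in self.transcripts.items():
            exons.sort(key=lambda e: e.start)
            for a, b in zip(exons, exons[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping exons in transcript {tid} of {self.gene_id}"
                    )
        for tid, parts in self.cds.items():
            parts.sort(key=lambda p: p[0].start)

    @property
    def span(self) -> GenomicInterval:
        starts = [e.start for ex in self.transcripts.values() for e in ex]
        ends = [e.end for ex in self.transcripts.values() for e in ex]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)

    def exons_5to3(self, transcript_id: str) -> list[GenomicInterval]:
        exons = self.transcripts[transcript_id]
        return exons if self.strand == "+" else exons[::-1]

    def annotated_junctions(self) -> list[SpliceJunction]:
        """Introns implied by adjacent exons, deduplicated across transcripts."""
        seen: dict[tuple, SpliceJunction] = {}
        for exons in self.transcripts.values():
            for a, b in zip(exons, exons[1:]):
                iv = GenomicInterval(self.chrom, a.end, b.start, self.strand)
                j = SpliceJunction(iv, annotated=True)
                seen.setdefault(j.key, j)
        return [seen[k] for k in sorted(seen)]


class ConservationTrack:
    """Sparse per-base scores; uncovered positions are distinct from 0."""

    def __init__(self) -> None:
        self._scores: dict[str, dict[int, float]] = {}

    def set_range(self, chrom: str, start: int, end: int, score: float) -> int:
        """Assign ``score`` to [start, end); returns how many positions were
        already covered (overwritten, last record wins)."""
        d = self._scores.setdefault(chrom, {})
        clobbered = 0
        for pos in range(start, end):
            if pos in d:
                clobbered += 1
            d[pos] = float(score)
        return clobbered

    def get(self, chrom: str, pos: int) -> float | None:
        return self._scores.get(chrom, {}).get(pos)

    def values(self, chrom: str, positions: Sequence[int]) -> list[float | None]:
        d = self._scores.get(chrom, {})
        return [d.get(p) for p in positions]

    def n_covered(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self._scores.get(chrom, {}))
        return sum(len(d) for d in self._scores.values())

    def chroms(self) -> list[str]:
        return sorted(self._scores)

    def items(self, chrom: str) -> Iterator[tuple[int, float]]:
        yield from sorted(self._scores.get(chrom, {}).items())


class SpeciesAlignment:
    """Gapped sequences for several species plus a reference coordinate map.

    ``reference_map[i]`` is the alignment column of ungapped reference
    position ``i``.  ``ref_start`` anchors ungapped position 0 on the genome
    (forward-strand coordinate of the first reference base).
    """

    def __init__(
        self,
        rows: Mapping[str, str],
        reference_species: str,
        ref_chrom: str | None = None,
        ref_start: int = 0,
        ref_strand: str = "+",
    ) -> None:
        if reference_species not in rows:
            raise ValueError(f"reference species {reference_species!r} missing")
        lengths = {len(s) for s in rows.values()}
        if len(lengths) > 1:
            raise ValueError("gapped rows have unequal lengths")
        self.rows = dict(rows)
        self.reference_species = reference_species
        self.ref_chrom = ref_chrom
        self.ref_start = ref_start
        self.ref_strand = ref_strand
        ref = self.rows[reference_species]
        self.reference_map = np.array(
            [col for col, ch in enumerate(ref) if ch != "-"], dtype=np.int64
        )

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def reference_sequence(self) -> str:
        return self.rows[self.reference_species].replace("-", "")

    def columns_for(self, ref_offset_start: int, ref_offset_end: int) -> np.ndarray:
        """Alignment columns of reference offsets [start, end)."""
        return self.reference_map[ref_offset_start:ref_offset_end]
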