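"""Junction-level percent-spliced-in (PSI) over splice-site sharing groups.

A junction's PSI is its read support divided by the summed support of all
junctions sharing its splice donor (resp. acceptor) site.  Each side is
gated on a minimum group read total; the reported PSI is the more
conservative (minimum) of the two defined sides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import JunctionCountTable


@dataclass(frozen=True)
class SpliceSiteGroup:
    """Junctions sharing one splice site (donor or acceptor)."""

    chrom: str
    site: int
    side: str  # "donor" or "acceptor"
    strand: str
    members: tuple[int, ...]

    @property
    def group_id(self) -> str:
        tag = "D" if self.side == "donor" else "A"
        return f"{tag}:{self.chrom}:{self.site}:{self.strand}"


def build_site_groups(table: JunctionCountTable) -> tuple[list[SpliceSiteGroup], list[SpliceSiteGroup]]:
    """Donor-side and acceptor-side groups; every junction is in exactly one
    group per side."""
    donor: dict[tuple, list[int]] = {}
    acceptor: dict[tuple, list[int]] = {}
    for i, j in enumerate(table.junctions):
        donor.setdefault((j.chrom, j.donor, j.strand), []).append(i)
        acceptor.setdefault((j.chrom, j.acceptor, j.strand), []).append(i)
    dgroups = [
        SpliceSiteGroup(c, s, "donor", st, tuple(m)) for (c, s, st), m in sorted(donor.items())
    ]
    agroups = [
        SpliceSiteGroup(c, s, "acceptor", st, tuple(m))
        for (c, s, st), m in sorted(acceptor.items())
    ]
    return dgroups, agroups


def pool_counts(table: JunctionCountTable, pool_by: str = "sample") -> tuple[list[str], np.ndarray]:
    """Counts per pooling unit.  ``sample`` keeps columns; ``tissue`` sums
    replicates within each (tissue, fraction)."""
    if pool_by == "sample":
        return [s.sample_id for s in table.samples], table.counts.copy()
    if pool_by != "tissue":
        raise ValueError(f"pool_by must be 'sample' or 'tissue', got {pool_by!r}")
    if not table.samples:
        raise ValueError("table has no sample metadata to pool by tissue")
    units: list[tuple[str, str]] = []
    for s in table.samples:
        if (s.tissue, s.fraction) not in units:
            units.append((s.tissue, s.fraction))
    fractions_per_tissue: dict[str, set[str]] = {}
    for t, f in units:
        fractions_per_tissue.setdefault(t, set()).add(f)
    labels = [
        t if len(fractions_per_tissue[t]) == 1 else f"{t}[{f}]" for t, f in units
    ]
    mat = np.zeros((table.n_junctions, len(units)), dtype=np.int64)
    for si, s in enumerate(table.samples):
        ui = units.index((s.tissue, s.fraction))
        mat[:, ui] += table.counts[:, si]
    return labels, mat


def compute_psi(
    table: JunctionCountTable,
    min_group_reads: int = 10,
    pool_by: str = "sample",
) -> pd.DataFrame:
    """Per-junction, per-unit PSI records.

    Columns: junction, unit, psi_donor, psi_acceptor, psi, total_donor,
    total_acceptor, donor_group, acceptor_group.  A side's PSI is NaN when
    its group total is below ``min_group_reads``; ``psi`` is the minimum of
    the defined sides.
    """
    if table.n_junctions == 0:
        raise ValueError("empty junction table")
    if min_group_reads < 1:
        raise ValueError("min_group_reads must be >= 1")
    units, counts = pool_counts(table, pool_by)
    dgroups, agroups = build_site_groups(table)

    n_j, n_u = counts.shape
    d_total = np.zeros((n_j, n_u), dtype=np.int64)
    a_total = np.zeros((n_j, n_u), dtype=np.int64)
    d_id = [""] * n_j
    a_id = [""] * n_j
    for g in dgroups:
        members = list(g.members)
        tot = counts[members].sum(axis=0)
        for m in members:
            d_total[m] = tot
            d_id[m] = g.group_id
    for g in agroups:
        members = list(g.members)
        tot = counts[members].sum(axis=0)
        for m in members:
            a_total[m] = tot
            a_id[m] = g.group_id

    with np.errstate(divide="ignore", invalid="ignore"):
        psi_d = np.where(d_total >= min_group_reads, counts / np.maximum(d_total, 1), np.nan)
        psi_a = np.where(a_total >= min_group_reads, counts / np.maximum(a_total, 1), np.nan)
    psi = np.fmin(psi_d, psi_a)  # fmin ignores NaN when the other side is defined

    rows = []
    keys = [j.key_str() for j in table.junctions]
    for ui, unit in enumerate(units):
        for ji in range(n_j):
            rows.append(
                (
                    keys[ji],
                    unit,
                    psi_d[ji, ui],
                    psi_a[ji, ui],
                    psi[ji, ui],
                    d_total[ji, ui],
                    a_total[ji, ui],
                    d_id[ji],
                    a_id[ji],
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "junction",
            "unit",
            "psi_donor",
            "psi_acceptor",
            "psi",
            "total_donor",
            "total_acceptor",
            "donor_group",
            "acceptor_group",
        ],
    )


def detect_tissue_enriched(
    table: JunctionCountTable,
    tissue: str,
    min_ip_reads: int = 5,
    strict: bool = False,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Junctions supported in a tissue's IP samples but absent (0 reads)
    from every whole-animal input sample.

    ``strict`` uses a strict inequality ("more than N reads"); the default
    is inclusive ("at least N reads").  ``per_replicate`` requires every IP
    replicate to meet the threshold individually instead of their sum.
    """
    ip_idx = table.sample_indices(tissue=tissue, fraction="IP")
    if not ip_idx:
        raise ValueError(f"no IP samples for tissue {tissue!r}")
    input_idx = table.sample_indices(fraction="input")
    if not input_idx:
        raise ValueError("table contains no input samples")
    ip_sum = table.counts[:, ip_idx].sum(axis=1)
    input_sum = table.counts[:, input_idx].sum(axis=1)
    if per_replicate:
        per = table.counts[:, ip_idx]
        passed = (per > min_ip_reads).all(axis=1) if strict else (per >= min_ip_reads).all(axis=1)
    else:
        passed = ip_sum > min_ip_reads if strict else ip_sum >= min_ip_reads
    called = passed & (input_sum == 0)
    idx = np.nonzero(called)[0]
    order = idx[np.argsort(-ip_sum[idx], kind="stable")]
    return pd.DataFrame(
        {
            "junction": [table.junctions[i].key_str() for i in order],
            "tissue": tissue,
            "ip_support": ip_sum[order],
            "input_support": input_sum[order],
            "threshold": min_ip_reads,
            "strict": strict,
        }
    )


def call_alternative_junctions(
    psi: pd.DataFrame, minor_psi_min: float = 0.05
) -> dict[str, list[str]]:
    """Splice-site groups with evidence of alternative splicing.

    A group is alternative in a unit when >=2 members have defined PSI on
    that side and the minor (non-maximal) member's PSI is at least
    ``minor_psi_min``.  Returns group_id -> sorted units where alternative.
    """
    out: dict[str, set[str]] = {}
    for side, group_col, psi_col in (
        ("donor", "donor_group", "psi_donor"),
        ("acceptor", "acceptor_group", "psi_acceptor"),
    ):
        sub = psi[[group_col, "unit", psi_col]].dropna(subset=[psi_col])
        for (gid, unit), grp in sub.groupby([group_col, "unit"], sort=True):
            vals = np.sort(grp[psi_col].to_numpy())
            if len(vals) >= 2 and vals[-2] >= minor_psi_min:
                out.setdefault(gid, set()).add(unit)
    return {gid: sorted(units) for gid, units in sorted(out.items())}


def subsample_counts(
    table: JunctionCountTable, fraction: float, seed: int
) -> JunctionCountTable:
    """Binomially thin every count to ``fraction`` of its reads."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return JunctionCountTable(table.junctions, table.samples, table.counts.copy())
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(table.counts, fraction)
    return JunctionCountTable(table.junctions, table.samples, thinned)


class CorrelationResult(NamedTuple):
    coefficient: float
    n_pairs: int
    defined: bool


def correlate_psi(a, b, method: str = "pearson") -> CorrelationResult:
    """Correlation over complete (both-defined) PSI pairs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("PSI vectors must be index-aligned (equal length)")
    mask = ~(np.isnan(a) | np.isnan(b))
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"need >=3 complete pairs, have {n}")
    aa, bb = a[mask], b[mask]
    if np.ptp(aa) == 0 or np.ptp(bb) == 0:
        return CorrelationResult(float("nan"), n, False)
    if method == "pearson":
        r = stats.pearsonr(aa, bb).statistic
    elif method == "spearman":
        r = stats.spearmanr(aa, bb).statistic
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return CorrelationResult(float(r), n, True)
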