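"""Instrument selection: significance filter, greedy LD clumping, F statistics.

Instruments are exposure SNPs below the genome-wide significance threshold
(P < 5e-8 by default, strict inequality) thinned to approximate independence
by greedy clumping: the unassigned SNP with the smallest p-value becomes an
index SNP and every unassigned SNP on the same chromosome within the window
(10 Mb default) with r2 >= 0.001 against it is discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .sumstats import LDReference, SnpRecord, SumStatsTable

log = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_WINDOW_BP = 10_000_000


@dataclass
class InstrumentSet:
    """Selected instruments with per-SNP strength and provenance."""

    table: SumStatsTable
    f_stats: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)


def f_statistic(beta: float, se: float) -> float:
    """Per-SNP instrument strength as the squared Wald z, F = (beta/se)^2."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def f_statistic_r2(beta: float, eaf: float, n: int) -> float:
    """Alternative F from explained variance: (N-2) R2 / (1 - R2).

    R2 per SNP is 2*eaf*(1-eaf)*beta^2 assuming a variance-1 trait.
    """
    if not 0 < eaf < 1:
        raise ValueError("eaf must be in (0,1)")
    r2 = 2.0 * eaf * (1.0 - eaf) * beta * beta
    if r2 >= 1:
        raise ValueError("per-SNP R2 >= 1; beta not on a variance-1 trait scale")
    return (n - 2) * r2 / (1.0 - r2)


def filter_significant(table: SumStatsTable, p_threshold: float = DEFAULT_P_THRESHOLD) -> SumStatsTable:
    """Records with pvalue strictly below ``p_threshold``, order preserved."""
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0,1)")
    keep = table.df["pval"] < p_threshold
    return SumStatsTable(table.trait_name, table.trait_type, table.df[keep].reset_index(drop=True))


def _chrom_sort_key(chrom: str):
    # numeric chromosomes order naturally before named ones (X, MT, ...)
    try:
        return (0, int(chrom), "")
    except (TypeError, ValueError):
        return (1, 0, str(chrom))


def _positions(table: SumStatsTable, ld: LDReference) -> dict[str, tuple[str, int]]:
    pos: dict[str, tuple[str, int]] = {}
    for rec in table.records:
        if rec.chrom is not None and rec.pos is not None:
            pos[rec.snp] = (rec.chrom, rec.pos)
        elif rec.snp in ld.positions:
            pos[rec.snp] = ld.positions[rec.snp]
        else:
            raise ValueError(f"no position known for SNP {rec.snp!r}; cannot clump")
    return pos


def clump(
    table: SumStatsTable,
    ld: LDReference,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
) -> SumStatsTable:
    """Greedy LD clumping; returns index SNPs sorted by (chrom, pos).

    Repeatedly the unassigned SNP with minimum p-value (ties broken by
    smaller (chrom, pos), then lexicographic id) becomes an index SNP; every
    unassigned SNP on the same chromosome within ``window_bp`` with
    r2 >= ``r2_threshold`` against it is discarded.  SNPs on different
    chromosomes are treated as infinitely distant.
    """
    pos = _positions(table, ld)
    recs: list[SnpRecord] = list(table.records)
    order = sorted(
        range(len(recs)),
        key=lambda i: (recs[i].pval, _chrom_sort_key(pos[recs[i].snp][0]), pos[recs[i].snp][1], recs[i].snp),
    )
    unassigned = set(range(len(recs)))
    index_ids: list[str] = []
    for i in order:
        if i not in unassigned:
            continue
        unassigned.discard(i)
        index_ids.append(recs[i].snp)
        chrom_i, pos_i = pos[recs[i].snp]
        for j in list(unassigned):
            chrom_j, pos_j = pos[recs[j].snp]
            if chrom_j != chrom_i:
                continue
            if abs(pos_j - pos_i) > window_bp:
                continue
            if ld.r2(recs[i].snp, recs[j].snp) >= r2_threshold:
                unassigned.discard(j)
    kept = table.subset(index_ids)
    sort_key = kept.df["snp"].map(lambda s: (_chrom_sort_key(pos[s][0]), pos[s][1]))
    df = kept.df.iloc[sort_key.argsort(kind="stable")].reset_index(drop=True)
    return SumStatsTable(table.trait_name, table.trait_type, df)


def select_instruments(
    table: SumStatsTable,
    ld: LDReference,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
) -> InstrumentSet:
    """Significance filter + clumping + per-SNP F statistics."""
    sig = filter_significant(table, p_threshold)
    idx = clump(sig, ld, r2_threshold, window_bp)
    f_stats = {rec.snp: f_statistic(rec.beta, rec.se) for rec in idx.records}
    provenance = {
        rec.snp: f"passed p<{p_threshold:g}; clump index {k}" for k, rec in enumerate(idx.records)
    }
    log.info(
        "%s: %d/%d SNPs pass p<%g, %d index SNPs after clumping",
        table.trait_name, len(sig), len(table), p_threshold, len(idx),
    )
    return InstrumentSet(table=idx, f_stats=f_stats, provenance=provenance)
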