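"""GWAS summary-statistics containers and plain-text I/O.

The pipeline's on-disk dialect is tab-separated text with a header row and
``NA`` for missing values.  Canonical column names are::

    snp  chr  pos  ea  oa  eaf  beta  se  pval  n

``ea``/``oa`` are the effect and other allele; ``eaf`` the effect-allele
frequency; ``beta``/``se`` the per-allele association on the trait scale
(log-odds or log-hazard for binary/survival traits).  A ``column_map`` lets
callers ingest arbitrary source headers (Neale-lab style or otherwise).

LD is consumed as a sparse pairwise r-squared table (``snp_a  snp_b  r2``,
optionally with embedded ``chr_a pos_a chr_b pos_b`` position columns); an
absent pair means r2 = 0 and r2 of a SNP with itself is 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n"]
#: columns that must be present (possibly via column_map) in any input file
MANDATORY_COLUMNS = ["snp", "ea", "oa", "beta", "se"]
TRAIT_TYPES = ("continuous", "binary", "survival")
_ACGT = frozenset("ACGT")


class SnpRecord(NamedTuple):
    """One SNP's association with one trait."""

    snp: str
    chrom: str | None
    pos: int | None
    ea: str
    oa: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int | None


@dataclass
class SumStatsTable:
    """Per-SNP association records for one trait.

    ``df`` holds the canonical columns; ``snp`` ids are unique.  Use
    :func:`read_sumstats` / :func:`write_sumstats` for file round-trips and
    :meth:`from_dataframe` to build a validated table in memory.
    """

    trait_name: str
    trait_type: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(f"trait_type must be one of {TRAIT_TYPES}, got {self.trait_type!r}")
        if not self.df["snp"].is_unique:
            dup = self.df["snp"][self.df["snp"].duplicated()].iloc[0]
            raise ValueError(f"duplicate snp id in table: {dup!r}")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, trait_name: str, trait_type: str = "continuous"
    ) -> "SumStatsTable":
        clean, n_dropped = _validate_rows(df)
        if n_dropped:
            log.warning("%s: dropped %d invalid row(s)", trait_name, n_dropped)
        return cls(trait_name, trait_type, clean)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> Iterator[SnpRecord]:
        for row in self.df.itertuples(index=False):
            yield SnpRecord(
                snp=row.snp,
                chrom=None if pd.isna(row.chr) else str(row.chr),
                pos=None if pd.isna(row.pos) else int(row.pos),
                ea=row.ea,
                oa=row.oa,
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=None if pd.isna(row.n) else int(row.n),
            )

    def subset(self, snp_ids) -> "SumStatsTable":
        """Rows whose id is in ``snp_ids``, original order preserved."""
        keep = self.df["snp"].isin(set(snp_ids))
        return SumStatsTable(self.trait_name, self.trait_type, self.df[keep].reset_index(drop=True))


def _coerce_canonical(df: pd.DataFrame) -> pd.DataFrame:
    """Cast a raw frame to canonical dtypes; unparseable numerics become NaN."""
    out = pd.DataFrame(index=df.index)
    out["snp"] = df["snp"].astype(str)
    out["chr"] = df["chr"].astype(str) if "chr" in df else pd.NA
    out["pos"] = pd.to_numeric(df.get("pos"), errors="coerce")
    out["ea"] = df["ea"].astype(str).str.upper()
    out["oa"] = df["oa"].astype(str).str.upper()
    out["eaf"] = pd.to_numeric(df.get("eaf"), errors="coerce")
    out["beta"] = pd.to_numeric(df.get("beta"), errors="coerce")
    out["se"] = pd.to_numeric(df.get("se"), errors="coerce")
    out["pval"] = pd.to_numeric(df.get("pval"), errors="coerce")
    out["n"] = pd.to_numeric(df.get("n"), errors="coerce")
    if "chr" in df:
        out.loc[df["chr"].isna(), "chr"] = pd.NA
    return out


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Enforce per-record invariants, dropping offending rows.

    Missing p-values are recomputed as two-sided normal from beta/se.
    Returns the clean frame (canonical columns, fresh index) and the number
    of rows dropped.
    """
    if len(df) == 0:
        empty = pd.DataFrame({c: pd.Series(dtype="float64") for c in CANONICAL_COLUMNS})
        empty = empty.astype({"snp": object, "chr": object, "ea": object, "oa": object,
                              "pos": "Int64", "n": "Int64"})
        return empty, 0
    out = _coerce_canonical(df)
    n_in = len(out)

    allele_ok = out["ea"].map(lambda a: bool(a) and set(a) <= _ACGT) & out["oa"].map(
        lambda a: bool(a) and set(a) <= _ACGT
    )
    ok = (
        allele_ok
        & (out["ea"] != out["oa"])
        & out["beta"].notna()
        & (out["se"] > 0)
        & (out["eaf"].isna() | ((out["eaf"] >= 0) & (out["eaf"] <= 1)))
        & (out["pos"].isna() | (out["pos"] >= 1))
        & (out["n"].isna() | (out["n"] > 0))
    )
    out = out[ok].copy()

    missing_p = out["pval"].isna()
    if missing_p.any():
        z = np.abs(out.loc[missing_p, "beta"] / out.loc[missing_p, "se"])
        out.loc[missing_p, "pval"] = 2.0 * stats.norm.sf(z)
        log.info("recomputed %d missing p-value(s) from beta/se", int(missing_p.sum()))
    out = out[(out["pval"] > 0) & (out["pval"] <= 1)]

    dup = out["snp"].duplicated()
    if dup.any():
        log.warning("dropping %d duplicate snp id row(s)", int(dup.sum()))
        out = out[~dup]

    out["pos"] = out["pos"].astype("Int64")
    out["n"] = out["n"].round().astype("Int64")
    out = out[CANONICAL_COLUMNS].reset_index(drop=True)
    return out, n_in - len(out)


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str = "trait",
    trait_type: str = "continuous",
    sep: str = "\t",
) -> SumStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    ``column_map`` maps canonical names to source header names, e.g.
    ``{"snp": "variant", "pval": "p_value"}``; unmapped canonical names are
    looked up verbatim.  Rows failing validation are dropped and logged;
    a missing mandatory column is a hard error.
    """
    raw = pd.read_csv(path, sep=sep, na_values=["NA"], dtype=str)
    colmap = dict(column_map or {})
    renamed = {}
    for canon in CANONICAL_COLUMNS:
        src = colmap.get(canon, canon)
        if src in raw.columns:
            renamed[canon] = raw[src]
    for col in MANDATORY_COLUMNS:
        if col not in renamed:
            raise ValueError(f"missing mandatory column {col!r} (source {colmap.get(col, col)!r}) in {path}")
    return SumStatsTable.from_dataframe(pd.DataFrame(renamed), trait_name, trait_type)


def write_sumstats(table: SumStatsTable, path) -> None:
    """Write a table in the canonical TSV dialect (``NA`` for missing)."""
    table.df.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class LDReference:
    """Sparse symmetric pairwise r-squared lookup.

    ``pairs`` is keyed by the sorted id pair; ``positions`` optionally maps
    snp id to (chrom, pos) for clumping distance checks.
    """

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.pairs.get(self._key(a, b), 0.0)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 out of [0,1] for pair ({a},{b}): {r2}")
        if a == b:
            return
        self.pairs[self._key(a, b)] = float(r2)


def read_ld_table(path, positions_path=None, sep: str = "\t") -> LDReference:
    """Read a pairwise LD table (snp_a, snp_b, r2 [, chr_a pos_a chr_b pos_b]).

    Duplicate entries for a pair must agree; conflicting duplicates are a
    hard error naming the pair.  ``positions_path`` may point to a two-plus
    column table (snp, chr, pos) supplying coordinates.
    """
    df = pd.read_csv(path, sep=sep, dtype={"snp_a": str, "snp_b": str})
    for col in ("snp_a", "snp_b", "r2"):
        if col not in df.columns:
            raise ValueError(f"LD table {path} missing column {col!r}")
    ld = LDReference()
    for row in df.itertuples(index=False):
        r2 = float(row.r2)
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 out of [0,1] for pair ({row.snp_a},{row.snp_b}): {r2}")
        key = LDReference._key(row.snp_a, row.snp_b)
        if key in ld.pairs and not np.isclose(ld.pairs[key], r2):
            raise ValueError(f"conflicting duplicate LD entries for pair {key}")
        if row.snp_a != row.snp_b:
            ld.pairs[key] = r2
        if {"chr_a", "pos_a"} <= set(df.columns):
            ld.positions[row.snp_a] = (str(row.chr_a), int(row.pos_a))
        if {"chr_b", "pos_b"} <= set(df.columns):
            ld.positions[row.snp_b] = (str(row.chr_b), int(row.pos_b))
    if positions_path is not None:
        pos = pd.read_csv(positions_path, sep=sep, dtype={"snp": str, "chr": str})
        for row in pos.itertuples(index=False):
            ld.positions[row.snp] = (str(row.chr), int(row.pos))
    return ld


def write_ld_table(ld: LDReference, path) -> None:
    rows = [
        {
            "snp_a": a,
            "snp_b": b,
            "r2": r2,
            "chr_a": ld.positions.get(a, ("NA", 0))[0],
            "pos_a": ld.positions.get(a, ("NA", 0))[1],
            "chr_b": ld.positions.get(b, ("NA", 0))[0],
            "pos_b": ld.positions.get(b, ("NA", 0))[1],
        }
        for (a, b), r2 in sorted(ld.pairs.items())
    ]
    cols = ["snp_a", "snp_b", "r2", "chr_a", "pos_a", "chr_b", "pos_b"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
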