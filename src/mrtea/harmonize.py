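"""Align exposure and outcome summary statistics to a common effect allele.

Two-sample MR needs, per SNP, the exposure and outcome effects expressed for
the same allele on the same strand.  Non-palindromic SNPs are aligned from
allele labels alone (direct match, effect/other swap, or strand complement).
Palindromic SNPs (A/T, C/G) carry no strand information in their labels, so
orientation comes from the effect-allele frequency: both studies' frequencies
must be clearly away from 0.5 (default window 0.08, i.e. eaf < 0.42 or
> 0.58), and the effect is sign-flipped when they sit on opposite sides.
Unresolvable SNPs are dropped, with every input SNP accounted for in the
per-SNP action log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .instruments import InstrumentSet
from .sumstats import SnpRecord, SumStatsTable

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

KEPT = "kept"
FLIPPED = "flipped"
STRAND_CORRECTED = "strand_corrected"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_INCOMPATIBLE = "dropped_incompatible"
DROPPED_MISSING = "dropped_missing"
ACTIONS = (KEPT, FLIPPED, STRAND_CORRECTED, DROPPED_PALINDROMIC, DROPPED_INCOMPATIBLE, DROPPED_MISSING)

DEFAULT_PALINDROME_EAF_WINDOW = 0.08


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff {a1, a2} is {A,T} or {C,G} (strand-ambiguous pair)."""
    if a1 not in _COMP or a2 not in _COMP:
        raise ValueError(f"alleles must be single A/C/G/T, got ({a1!r}, {a2!r})")
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


@dataclass
class HarmonizedSet:
    """Aligned exposure/outcome effect pairs ready for estimation.

    Vectors cover only the retained SNPs; ``actions`` covers every input SNP
    exactly once (retained and dropped alike).
    """

    snp_ids: np.ndarray
    bx: np.ndarray
    sebx: np.ndarray
    by: np.ndarray
    seby: np.ndarray
    actions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.snp_ids)
        for name in ("bx", "sebx", "by", "seby"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n}")
            setattr(self, name, arr)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        if np.any(self.sebx <= 0) or np.any(self.seby <= 0):
            raise ValueError("all standard errors must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, mask) -> "HarmonizedSet":
        mask = np.asarray(mask)
        return HarmonizedSet(
            self.snp_ids[mask], self.bx[mask], self.sebx[mask], self.by[mask], self.seby[mask],
            dict(self.actions),
        )

    @classmethod
    def from_arrays(cls, bx, sebx, by, seby, snp_ids=None) -> "HarmonizedSet":
        bx = np.asarray(bx, dtype=float)
        if snp_ids is None:
            snp_ids = np.array([f"snp{i}" for i in range(len(bx))], dtype=object)
        actions = {str(s): KEPT for s in snp_ids}
        return cls(np.asarray(snp_ids, dtype=object), bx, sebx, by, seby, actions)


def _single_acgt(*alleles: str) -> bool:
    return all(len(a) == 1 and a in _COMP for a in alleles)


def _clear_of_half(eaf: float | None, window: float) -> bool:
    return eaf is not None and abs(eaf - 0.5) > window


def harmonize(
    exposure: InstrumentSet | SumStatsTable,
    outcome: SumStatsTable,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
    drop_all_palindromes: bool = False,
) -> HarmonizedSet:
    """Harmonize outcome effects onto the exposure's effect alleles.

    Matching is by snp id.  Per shared SNP: direct allele match is kept;
    effect/other swap negates the outcome beta; a strand complement on a
    non-palindromic SNP is corrected then matched; palindromic SNPs are
    oriented by allele frequency (see module docstring) or dropped; anything
    irreconcilable (including indels / non-ACGT alleles) is dropped.
    """
    if not 0.0 <= palindrome_eaf_window <= 0.5:
        raise ValueError("palindrome_eaf_window must be in [0, 0.5]")
    exp_table = exposure.table if isinstance(exposure, InstrumentSet) else exposure
    out_by_id: dict[str, SnpRecord] = {rec.snp: rec for rec in outcome.records}

    ids: list[str] = []
    bx: list[float] = []
    sebx: list[float] = []
    by: list[float] = []
    seby: list[float] = []
    actions: dict[str, str] = {}

    for ex in exp_table.records:
        act, orient = _resolve(ex, out_by_id.get(ex.snp), palindrome_eaf_window, drop_all_palindromes)
        actions[ex.snp] = act
        if act in (KEPT, FLIPPED, STRAND_CORRECTED):
            out = out_by_id[ex.snp]
            ids.append(ex.snp)
            bx.append(ex.beta)
            sebx.append(ex.se)
            by.append(orient * out.beta)
            seby.append(out.se)
    return HarmonizedSet(np.array(ids, dtype=object), np.array(bx), np.array(sebx),
                         np.array(by), np.array(seby), actions)


def _resolve(
    ex: SnpRecord, out: SnpRecord | None, window: float, drop_all_palindromes: bool
) -> tuple[str, float]:
    """Classify one SNP; returns (action, orientation in {+1,-1})."""
    if out is None:
        return DROPPED_MISSING, 0.0
    if not _single_acgt(ex.ea, ex.oa, out.ea, out.oa):
        return DROPPED_INCOMPATIBLE, 0.0

    if is_palindromic(ex.ea, ex.oa):
        if drop_all_palindromes:
            return DROPPED_PALINDROMIC, 0.0
        if {out.ea, out.oa} != {ex.ea, ex.oa}:
            return DROPPED_INCOMPATIBLE, 0.0
        # labels carry no strand information: orient by allele frequency
        if not (_clear_of_half(ex.eaf, window) and _clear_of_half(out.eaf, window)):
            return DROPPED_PALINDROMIC, 0.0
        same_side = (ex.eaf - 0.5) * (out.eaf - 0.5) > 0
        # same side: outcome effect allele is physically the exposure's
        # effect allele, whatever the labels say; opposite side: it is the
        # other allele, so the outcome effect is sign-flipped
        return (KEPT, 1.0) if same_side else (FLIPPED, -1.0)

    if (out.ea, out.oa) == (ex.ea, ex.oa):
        return KEPT, 1.0
    if (out.ea, out.oa) == (ex.oa, ex.ea):
        return FLIPPED, -1.0
    comp = (_COMP[out.ea], _COMP[out.oa])
    if comp == (ex.ea, ex.oa):
        return STRAND_CORRECTED, 1.0
    if comp == (ex.oa, ex.ea):
        return STRAND_CORRECTED, -1.0
    return DROPPED_INCOMPATIBLE, 0.0
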