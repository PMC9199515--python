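"""Harmonization: allele alignment branches and global invariants."""

import numpy as np
import pandas as pd
import pytest

from mrtea import SumStatsTable, harmonize, is_palindromic, ivw
from mrtea.harmonize import (
    DROPPED_INCOMPATIBLE,
    DROPPED_MISSING,
    DROPPED_PALINDROMIC,
    FLIPPED,
    KEPT,
    STRAND_CORRECTED,
)
from conftest import make_table

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@pytest.mark.parametrize("a1,a2,expected", [
    ("A", "T", True), ("C", "G", True), ("G", "C", True),
    ("A", "G", False), ("T", "C", False),
])
def test_is_palindromic(a1, a2, expected):
    assert is_palindromic(a1, a2) is expected


def test_is_palindromic_rejects_non_acgt():
    with pytest.raises(ValueError):
        is_palindromic("A", "N")


def _pair(exp_row, out_row):
    exp = make_table([{"snp": "rs1", **exp_row}])
    out = make_table([{"snp": "rs1", **out_row}], name="out")
    return exp, out


class TestBranches:
    def test_direct_match_kept(self):
        h = harmonize(*_pair({"ea": "A", "oa": "G", "beta": 0.1},
                             {"ea": "A", "oa": "G", "beta": 0.05}))
        assert h.actions["rs1"] == KEPT and h.by[0] == 0.05

    def test_swapped_alleles_flip_sign(self):
        h = harmonize(*_pair({"ea": "A", "oa": "G", "beta": 0.1},
                             {"ea": "G", "oa": "A", "beta": 0.05}))
        assert h.actions["rs1"] == FLIPPED and h.by[0] == -0.05

    def test_strand_complement_corrected(self):
        # exposure A/G; outcome reported on the other strand as T/C
        h = harmonize(*_pair({"ea": "A", "oa": "G", "beta": 0.1},
                             {"ea": "T", "oa": "C", "beta": 0.05}))
        assert h.actions["rs1"] == STRAND_CORRECTED and h.by[0] == 0.05

    def test_strand_complement_with_swap_negates(self):
        h = harmonize(*_pair({"ea": "A", "oa": "G", "beta": 0.1},
                             {"ea": "C", "oa": "T", "beta": 0.05}))
        assert h.actions["rs1"] == STRAND_CORRECTED and h.by[0] == -0.05

    def test_ambiguous_palindrome_dropped(self):
        h = harmonize(*_pair({"ea": "A", "oa": "T", "beta": 0.1, "eaf": 0.50},
                             {"ea": "A", "oa": "T", "beta": 0.05, "eaf": 0.50}))
        assert h.actions["rs1"] == DROPPED_PALINDROMIC and h.n_snps == 0

    def test_clear_palindrome_same_side_kept(self):
        h = harmonize(*_pair({"ea": "A", "oa": "T", "beta": 0.1, "eaf": 0.2},
                             {"ea": "A", "oa": "T", "beta": 0.05, "eaf": 0.25}))
        assert h.actions["rs1"] == KEPT and h.by[0] == 0.05

    def test_clear_palindrome_opposite_side_flipped(self):
        # outcome's effect allele is physically the exposure's other allele
        h = harmonize(*_pair({"ea": "A", "oa": "T", "beta": 0.1, "eaf": 0.2},
                             {"ea": "A", "oa": "T", "beta": 0.05, "eaf": 0.8}))
        assert h.actions["rs1"] == FLIPPED and h.by[0] == -0.05

    def test_palindrome_missing_outcome_eaf_dropped(self):
        h = harmonize(*_pair({"ea": "C", "oa": "G", "beta": 0.1, "eaf": 0.2},
                             {"ea": "C", "oa": "G", "beta": 0.05, "eaf": np.nan}))
        assert h.actions["rs1"] == DROPPED_PALINDROMIC

    def test_drop_all_palindromes_flag(self):
        h = harmonize(*_pair({"ea": "C", "oa": "G", "beta": 0.1, "eaf": 0.2},
                             {"ea": "C", "oa": "G", "beta": 0.05, "eaf": 0.2}),
                      drop_all_palindromes=True)
        assert h.actions["rs1"] == DROPPED_PALINDROMIC

    def test_irreconcilable_alleles_dropped(self):
        h = harmonize(*_pair({"ea": "A", "oa": "G", "beta": 0.1},
                             {"ea": "A", "oa": "C", "beta": 0.05}))
        assert h.actions["rs1"] == DROPPED_INCOMPATIBLE

    def test_missing_in_outcome_dropped(self):
        exp = make_table([{"snp": "rs1"}, {"snp": "rs2"}])
        out = make_table([{"snp": "rs1"}], name="out")
        h = harmonize(exp, out)
        assert h.actions["rs2"] == DROPPED_MISSING and h.n_snps == 1

    def test_indel_dropped_incompatible(self):
        h = harmonize(*_pair({"ea": "AT", "oa": "A", "beta": 0.1},
                             {"ea": "AT", "oa": "A", "beta": 0.05}))
        assert h.actions["rs1"] == DROPPED_INCOMPATIBLE


def _random_study_pair(rng, j=8):
    """Exposure plus an outcome whose coding is randomly recoded/scrambled."""
    pairs = [("A", "G"), ("T", "C"), ("A", "T"), ("C", "G")]
    exp_rows, out_rows = [], []
    for i in range(j):
        ea, oa = pairs[rng.integers(len(pairs))]
        eaf = float(rng.uniform(0.05, 0.95))
        bx = float(rng.normal(0, 0.1)) or 0.01
        by = float(rng.normal(0, 0.05))
        exp_rows.append({"snp": f"rs{i}", "ea": ea, "oa": oa, "eaf": eaf,
                         "beta": bx, "se": 0.01})
        o = {"snp": f"rs{i}", "ea": ea, "oa": oa, "eaf": eaf, "beta": by, "se": 0.02}
        if rng.random() < 0.5:  # label swap
            o["ea"], o["oa"] = o["oa"], o["ea"]
            o["eaf"] = 1 - o["eaf"]
            o["beta"] = -o["beta"]
        if rng.random() < 0.5:  # strand flip
            o["ea"], o["oa"] = _COMP[o["ea"]], _COMP[o["oa"]]
        out_rows.append(o)
    return make_table(exp_rows), make_table(out_rows, name="out")


def _realign_outcome(exp, h):
    """Outcome table restated on the exposure's own alleles from h."""
    lookup = dict(zip(map(str, h.snp_ids), zip(h.by, h.seby)))
    rows = []
    for rec in exp.records:
        if rec.snp not in lookup:
            continue
        by, seby = lookup[rec.snp]
        rows.append({"snp": rec.snp, "chr": rec.chrom, "pos": rec.pos, "ea": rec.ea,
                     "oa": rec.oa, "eaf": rec.eaf, "beta": by, "se": seby,
                     "pval": 0.5, "n": 1000})
    return SumStatsTable.from_dataframe(pd.DataFrame(rows), "realigned")


class TestInvariants:
    def test_double_application_is_noop(self, rng):
        for _ in range(60):
            exp, out = _random_study_pair(rng)
            h1 = harmonize(exp, out)
            if h1.n_snps == 0:
                continue
            h2 = harmonize(exp.subset(h1.snp_ids), _realign_outcome(exp, h1))
            np.testing.assert_array_equal(h1.snp_ids, h2.snp_ids)
            np.testing.assert_allclose(h1.by, h2.by)
            np.testing.assert_allclose(h1.bx, h2.bx)

    def test_exposure_recode_negates_pairs_and_preserves_estimates(self, rng):
        """Swapping every exposure allele (beta -> -beta, eaf -> 1-eaf) negates
        (bx, by) elementwise and leaves the causal estimate unchanged."""
        for _ in range(60):
            exp, out = _random_study_pair(rng)
            flipped_df = exp.df.copy()
            flipped_df[["ea", "oa"]] = flipped_df[["oa", "ea"]].to_numpy()
            flipped_df["beta"] = -flipped_df["beta"]
            flipped_df["eaf"] = 1 - flipped_df["eaf"]
            exp_flipped = SumStatsTable(exp.trait_name, exp.trait_type, flipped_df)
            h1 = harmonize(exp, out)
            h2 = harmonize(exp_flipped, out)
            # the same SNPs survive with the same drop reasons (kept/flipped
            # labels may swap for palindromes, whose orientation is frequency-based)
            assert list(h1.snp_ids) == list(h2.snp_ids)
            assert {s: a for s, a in h1.actions.items() if a.startswith("dropped")} == \
                   {s: a for s, a in h2.actions.items() if a.startswith("dropped")}
            np.testing.assert_allclose(h2.bx, -h1.bx)
            np.testing.assert_allclose(h2.by, -h1.by)
            if h1.n_snps >= 2 and not np.all(h1.bx == 0):
                assert ivw(h1).beta == pytest.approx(ivw(h2).beta, rel=1e-12)

    def test_every_snp_accounted_exactly_once(self, rng):
        exp, out = _random_study_pair(rng, j=12)
        h = harmonize(exp, out)
        assert set(h.actions) == {f"rs{i}" for i in range(12)}
        kept = {s for s, a in h.actions.items() if a in (KEPT, FLIPPED, STRAND_CORRECTED)}
        assert kept == set(map(str, h.snp_ids))
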