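"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the study's data regime — a large exposure GWAS
(N = 64,949, green-tea-intake scale) against small outcome GWASs
(N = 4,093, Parkinson's progression scale) — so every pipeline stage is
exercisable without external downloads.  Per instrument SNP j:

* minor-allele frequency maf_j ~ Uniform(maf_range);
* a true exposure effect gamma_j whose expected single-SNP F statistic is
  drawn Uniform over ``f_range`` (default (30, 44), the instrument-strength
  band the selected instruments occupy), sign random unless
  ``gamma_positive``;
* sampling SEs close under a standardized trait:
  sigma_x = (2 maf (1-maf) n_exposure)^(-1/2), sigma_y analogous;
* observed bx_j ~ N(gamma_j, sigma_x);
* a horizontal-pleiotropy effect alpha_j ~ N(pleiotropy_mean, pleiotropy_sd)
  drawn independently of gamma_j (so InSIDE holds), replaced by
  +/- outlier_size * sigma_y for a random ``outlier_fraction`` subset;
* observed by_j ~ N(theta * gamma_j + alpha_j, sigma_y).

P-values are two-sided normal from beta/se.  A configurable fraction of
SNPs is palindromic (A/T or C/G); effect-allele frequencies are reported
identically in both studies.  Optional LD clusters replicate each index SNP
with correlated noise at r2 = ``ld_r2`` and populate the LD reference.
Null background SNPs (gamma = 0) can be appended for threshold-filter
realism.  One global seed expands into per-component streams through
numpy SeedSequence spawning, so adding outcomes never perturbs earlier
streams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sumstats import LDReference, SumStatsTable, write_ld_table, write_sumstats

_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]
_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass
class SimConfig:
    """Ground-truth data-generating parameters for one exposure/outcome pair."""

    j_snps: int = 15
    theta: float = 0.0
    n_exposure: int = 64_949
    n_outcome: int = 4_093
    maf_range: tuple[float, float] = (0.05, 0.45)
    gamma_sd: float = 0.03
    f_range: tuple[float, float] | None = (30.0, 44.0)
    f_floor: float | None = None
    gamma_positive: bool = False
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    outlier_fraction: float = 0.0
    outlier_size: float = 0.0  # in units of the SNP's outcome SE
    palindromic_fraction: float = 0.2
    ld_block_size: int = 1
    ld_r2: float = 0.0
    n_null_snps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("outlier_fraction", "palindromic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.j_snps <= 0 or self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValueError("sizes must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not 0.0 <= self.ld_r2 <= 1.0:
            raise ValueError("ld_r2 must be in [0,1]")
        if self.n_null_snps < 0:
            raise ValueError("n_null_snps must be >= 0")


@dataclass
class TruthRecord:
    """What the generator actually injected, for oracle-style assertions."""

    theta: float
    gamma: dict[str, float]
    alpha: dict[str, float]
    outlier_ids: list[str]
    palindrome_ids: list[str]
    ld_clusters: dict[str, list[str]]
    instrument_ids: list[str]
    null_ids: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class _ExposureDraw:
    """Frozen exposure-side quantities shared by every outcome of a study."""

    snp: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ea: np.ndarray
    oa: np.ndarray
    maf: np.ndarray
    gamma: np.ndarray
    sigma_x: np.ndarray
    bx: np.ndarray
    is_instrument: np.ndarray
    noise_x: np.ndarray  # standardized noise, reused for LD-correlated draws
    clusters: dict[str, list[str]]
    ld: LDReference


def _sigma(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    return np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), np.finfo(float).tiny, 1.0)


def _assign_alleles(rng: np.random.Generator, n: int, palindromic_fraction: float):
    pal = rng.random(n) < palindromic_fraction
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    for i in range(n):
        pool = _PALINDROMIC_PAIRS if pal[i] else _NONPALINDROMIC_PAIRS
        a1, a2 = pool[rng.integers(len(pool))]
        if rng.random() < 0.5:
            a1, a2 = a2, a1
        ea[i], oa[i] = a1, a2
    return ea, oa, pal


def _draw_exposure(cfg: SimConfig, rng: np.random.Generator) -> _ExposureDraw:
    j = cfg.j_snps
    n_total = j * cfg.ld_block_size + cfg.n_null_snps

    maf_idx = rng.uniform(*cfg.maf_range, size=j)
    sigma_idx = _sigma(maf_idx, cfg.n_exposure)
    if cfg.f_range is not None:
        f_target = rng.uniform(*cfg.f_range, size=j)
        gamma_idx = sigma_idx * np.sqrt(np.maximum(f_target - 1.0, 0.0))
        if not cfg.gamma_positive:
            gamma_idx *= rng.choice([-1.0, 1.0], size=j)
    else:
        gamma_idx = rng.normal(0.0, cfg.gamma_sd, size=j)
        if cfg.f_floor is not None:
            for i in range(j):
                while 1.0 + (gamma_idx[i] / sigma_idx[i]) ** 2 < cfg.f_floor:
                    gamma_idx[i] = rng.normal(0.0, cfg.gamma_sd)
        if cfg.gamma_positive:
            gamma_idx = np.abs(gamma_idx)

    snp, chrom, pos, maf, gamma, is_instr = [], [], [], [], [], []
    clusters: dict[str, list[str]] = {}
    ld = LDReference()
    # index SNPs spaced far apart (20 Mb) across chromosomes 1..22 so that
    # independent instruments never fall in one clumping window
    for i in range(j):
        sid = f"rs{1000 + i}"
        c = str(1 + i % 22)
        p = 1_000_000 + (i // 22) * 20_000_000
        snp.append(sid); chrom.append(c); pos.append(p)
        maf.append(maf_idx[i]); gamma.append(gamma_idx[i]); is_instr.append(True)
        ld.positions[sid] = (c, p)
        members = [sid]
        for b in range(1, cfg.ld_block_size):
            tid = f"rs{1000 + i}_{b}"
            tp = p + 5_000 * b
            snp.append(tid); chrom.append(c); pos.append(tp)
            maf.append(maf_idx[i])
            gamma.append(np.sqrt(cfg.ld_r2) * gamma_idx[i])  # tagging attenuation
            is_instr.append(False)
            ld.positions[tid] = (c, tp)
            members.append(tid)
        if len(members) > 1:
            for a in members:
                for b2 in members:
                    if a < b2:
                        ld.set_r2(a, b2, cfg.ld_r2)
            clusters[sid] = members
    for k in range(cfg.n_null_snps):
        sid = f"rsnull{k}"
        c = str(1 + k % 22)
        p = 200_000_000 + (k // 22) * 20_000_000
        snp.append(sid); chrom.append(c); pos.append(p)
        maf.append(rng.uniform(*cfg.maf_range)); gamma.append(0.0); is_instr.append(False)
        ld.positions[sid] = (c, p)

    maf = np.asarray(maf); gamma = np.asarray(gamma)
    sigma_x = _sigma(maf, cfg.n_exposure)
    noise = rng.standard_normal(n_total)
    # satellites share the index SNP's noise at correlation sqrt(ld_r2)
    if cfg.ld_block_size > 1 and cfg.ld_r2 > 0:
        r = np.sqrt(cfg.ld_r2)
        pos_i = 0
        for i in range(j):
            idx_noise = noise[pos_i]
            for b in range(1, cfg.ld_block_size):
                noise[pos_i + b] = r * idx_noise + np.sqrt(1 - r * r) * noise[pos_i + b]
            pos_i += cfg.ld_block_size
    bx = gamma + sigma_x * noise
    ea, oa, _ = _assign_alleles(rng, n_total, cfg.palindromic_fraction)
    return _ExposureDraw(
        snp=np.asarray(snp, dtype=object), chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos), ea=ea, oa=oa, maf=maf, gamma=gamma, sigma_x=sigma_x,
        bx=bx, is_instrument=np.asarray(is_instr), noise_x=noise, clusters=clusters, ld=ld,
    )


def _exposure_table(cfg: SimConfig, draw: _ExposureDraw, name: str = "green_tea_intake") -> SumStatsTable:
    df = pd.DataFrame({
        "snp": draw.snp, "chr": draw.chrom, "pos": draw.pos,
        "ea": draw.ea, "oa": draw.oa, "eaf": draw.maf,
        "beta": draw.bx, "se": draw.sigma_x,
        "pval": _two_sided_p(draw.bx, draw.sigma_x),
        "n": cfg.n_exposure,
    })
    return SumStatsTable.from_dataframe(df, name, "continuous")


def _draw_outcome(
    cfg: SimConfig,
    draw: _ExposureDraw,
    rng: np.random.Generator,
    theta: float,
    name: str,
    trait_type: str,
    scramble_alleles: bool = False,
) -> tuple[SumStatsTable, np.ndarray, np.ndarray]:
    """Outcome table plus the injected (alpha, outlier mask)."""
    n_total = len(draw.snp)
    sigma_y = _sigma(draw.maf, cfg.n_outcome)
    alpha = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n_total)
    outlier = np.zeros(n_total, dtype=bool)
    instr_idx = np.flatnonzero(draw.is_instrument)
    n_out = int(round(cfg.outlier_fraction * len(instr_idx)))
    if n_out > 0 and cfg.outlier_size != 0.0:
        chosen = rng.choice(instr_idx, size=n_out, replace=False)
        outlier[chosen] = True
        alpha[chosen] = rng.choice([-1.0, 1.0], size=n_out) * cfg.outlier_size * sigma_y[chosen]
    by = theta * draw.gamma + alpha + sigma_y * rng.standard_normal(n_total)

    ea, oa, eaf = draw.ea.copy(), draw.oa.copy(), draw.maf.copy().astype(float)
    by_rep = by.copy()
    if scramble_alleles:
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        swap = rng.random(n_total) < 0.5
        strand = rng.random(n_total) < 0.5
        for i in range(n_total):
            if swap[i]:
                ea[i], oa[i] = oa[i], ea[i]
                eaf[i] = 1.0 - eaf[i]
                by_rep[i] = -by_rep[i]
            if strand[i]:
                ea[i], oa[i] = comp[ea[i]], comp[oa[i]]
    df = pd.DataFrame({
        "snp": draw.snp, "chr": draw.chrom, "pos": draw.pos,
        "ea": ea, "oa": oa, "eaf": eaf,
        "beta": by_rep, "se": sigma_y,
        "pval": _two_sided_p(by_rep, sigma_y),
        "n": cfg.n_outcome,
    })
    return SumStatsTable.from_dataframe(df, name, trait_type), alpha, outlier


def simulate_pair(
    config: SimConfig,
    outcome_name: str = "outcome",
    trait_type: str = "survival",
    scramble_outcome_alleles: bool = False,
) -> tuple[SumStatsTable, SumStatsTable, LDReference, TruthRecord]:
    """One exposure GWAS, one outcome GWAS, the LD reference and the truth.

    Deterministic given ``config.seed``.  With ``scramble_outcome_alleles``
    the outcome's allele coding is randomly swapped and strand-flipped
    (consistently with its betas and frequencies), exercising harmonization.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_x, rng_y = (np.random.default_rng(s) for s in ss.spawn(2))
    draw = _draw_exposure(config, rng_x)
    exposure = _exposure_table(config, draw)
    outcome, alpha, outlier = _draw_outcome(
        config, draw, rng_y, config.theta, outcome_name, trait_type,
        scramble_alleles=scramble_outcome_alleles,
    )
    pal = [s for s, a, b in zip(draw.snp, draw.ea, draw.oa) if {a, b} in ({"A", "T"}, {"C", "G"})]
    truth = TruthRecord(
        theta=config.theta,
        gamma=dict(zip(map(str, draw.snp), map(float, draw.gamma))),
        alpha=dict(zip(map(str, draw.snp), map(float, alpha))),
        outlier_ids=[str(s) for s in draw.snp[outlier]],
        palindrome_ids=[str(s) for s in pal],
        ld_clusters=draw.clusters,
        instrument_ids=[str(s) for s in draw.snp[draw.is_instrument]],
        null_ids=[str(s) for s in draw.snp[draw.gamma == 0.0]],
    )
    return exposure, outcome, draw.ld, truth


#: the study's 28-phenotype progression panel: 10 baseline binomial traits,
#: 7 continuous clinical scales, 11 survival (time-to-event) endpoints
DEFAULT_PHENOTYPE_PANEL: list[tuple[str, str, str]] = (
    [(n, "baseline", "binary") for n in (
        "constipation", "dementia", "depression", "dyskinesia", "hy3",
        "hyposmia", "insomnia", "motor_fluctuation", "rbd", "daytime_sleepiness")]
    + [(n, "continuous", "continuous") for n in (
        "hy", "seadl", "updrs1", "updrs2", "updrs3", "updrs4", "updrs_total")]
    + [(n, "survival", "survival") for n in (
        "constipation", "dementia", "depression", "dyskinesia", "hy3",
        "hyposmia", "insomnia", "motor_fluctuation", "rbd", "seadl70",
        "daytime_sleepiness")]
)


def simulate_study(
    config: SimConfig,
    out_dir,
    n_outcomes: int = 28,
    causal_outcome_ids: tuple[int, ...] = (),
    theta_causal: float | None = None,
    include_aao: bool = False,
    scramble_outcome_alleles: bool = True,
    n_boot: int = 1000,
    n_sim: int = 1000,
    verify_significant_only: bool = False,
) -> Path:
    """Write a ready-to-run synthetic study tree; returns the config path.

    One shared exposure GWAS, ``n_outcomes`` outcome GWASs (theta =
    ``theta_causal`` — or config.theta — for causal ids, 0 otherwise), the
    LD table, a truth manifest and a study YAML.  Outcome names/panels come
    from the 28-phenotype panel (cycled/truncated for other counts).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if any(i < 0 or i >= n_outcomes for i in causal_outcome_ids):
        raise ValueError("causal_outcome_ids must index the outcome set")
    theta_causal = config.theta if theta_causal is None else theta_causal

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_outcomes + 2)
    draw = _draw_exposure(config, np.random.default_rng(children[0]))
    exposure = _exposure_table(config, draw)
    write_sumstats(exposure, out_dir / "exposure.tsv")
    write_ld_table(draw.ld, out_dir / "ld.tsv")

    panel = [DEFAULT_PHENOTYPE_PANEL[i % len(DEFAULT_PHENOTYPE_PANEL)] for i in range(n_outcomes)]
    outcomes_meta = []
    truths = {}
    for i, (pheno, pan, ttype) in enumerate(panel):
        theta_i = theta_causal if i in causal_outcome_ids else 0.0
        name = f"{pan}_{pheno}"
        table, alpha, outlier = _draw_outcome(
            config, draw, np.random.default_rng(children[1 + i]), theta_i, name, ttype,
            scramble_alleles=scramble_outcome_alleles,
        )
        fname = f"outcome_{i:02d}_{name}.tsv"
        write_sumstats(table, out_dir / fname)
        outcomes_meta.append({"name": name, "path": fname, "trait_type": ttype, "panel": pan})
        truths[name] = {"theta": theta_i, "n_outliers": int(outlier.sum())}
    family = [m["name"] for m in outcomes_meta]

    if include_aao:
        table, _, _ = _draw_outcome(
            config, draw, np.random.default_rng(children[-1]), 0.0, "age_at_onset",
            "continuous", scramble_alleles=scramble_outcome_alleles,
        )
        write_sumstats(table, out_dir / "outcome_aao.tsv")
        outcomes_meta.append({"name": "age_at_onset", "path": "outcome_aao.tsv",
                              "trait_type": "continuous", "panel": "continuous"})
        truths["age_at_onset"] = {"theta": 0.0, "n_outliers": 0}

    manifest = {
        "seed": config.seed,
        "theta_causal": theta_causal,
        "causal_outcomes": [outcomes_meta[i]["name"] for i in causal_outcome_ids],
        "instrument_ids": [str(s) for s in draw.snp[draw.is_instrument]],
        "outcomes": truths,
    }
    (out_dir / "truth.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    study = {
        "exposure": {"name": "green_tea_intake", "path": "exposure.tsv", "trait_type": "continuous"},
        "ld_path": "ld.tsv",
        "outcomes": outcomes_meta,
        "family": family,
        "thresholds": {"p_threshold": 5e-8, "clump_r2": 0.001, "clump_kb": 10_000,
                       "palindrome_window": 0.08},
        "estimation": {"methods": ["ivw", "egger", "weighted_median", "weighted_mode"],
                       "n_boot": n_boot, "n_sim": n_sim,
                       "verify_significant_only": verify_significant_only},
        "alpha_family": 0.05,
        "seed": config.seed,
    }
    cfg_path = out_dir / "study.yaml"
    cfg_path.write_text(yaml.safe_dump(study, sort_keys=False))
    return cfg_path
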