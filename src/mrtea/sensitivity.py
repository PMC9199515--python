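"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

For one harmonized exposure-outcome pair this module provides:

* Cochran's Q test of heterogeneity across per-SNP causal effects
  (chi-square with J - 1 df under homogeneity);
* MR-PRESSO: a residual-sum-of-squares global pleiotropy test with
  simulation-based per-SNP outlier detection, step-by-step outlier removal,
  and a distortion test comparing the outlier-corrected estimate against
  random removal of the same number of SNPs;
* leave-one-out IVW, one estimate per excluded SNP.

Empirical p-values use the (1 + k) / (1 + n_sim) estimator, so they are
floored at 1/(n_sim + 1) and never exactly zero.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import MREstimate, ivw, egger, q_statistic
from .harmonize import HarmonizedSet

log = logging.getLogger(__name__)


@dataclass
class PressoResult:
    global_p: float
    outliers: list[str]
    distortion_p: float | None
    corrected: MREstimate | None
    per_snp_p: dict[str, float] = field(default_factory=dict)


@dataclass
class SensitivityReport:
    """Table-1-shaped diagnostics for one exposure-outcome pair."""

    q: float
    q_df: int
    q_p: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    presso_global_p: float | None = None
    presso_outliers: list[str] = field(default_factory=list)
    presso_distortion_p: float | None = None
    loo: dict[str, MREstimate] = field(default_factory=dict)


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q about the fixed-effects IVW estimate.

    Returns (Q, J - 1, p) with p from the chi-square distribution.
    """
    if h.n_snps < 2:
        raise ValueError(f"Cochran's Q needs at least 2 SNPs, got {h.n_snps}")
    q = q_statistic(h.bx, h.by, h.seby)
    df = h.n_snps - 1
    return q, df, float(stats.chi2.sf(q, df))


def leave_one_out(h: HarmonizedSet, effects_model: str = "multiplicative_random") -> dict[str, MREstimate]:
    """IVW re-estimated with each SNP excluded in turn; exactly J entries."""
    if h.n_snps < 3:
        raise ValueError(f"leave-one-out needs at least 3 SNPs, got {h.n_snps}")
    out: dict[str, MREstimate] = {}
    idx = np.arange(h.n_snps)
    for j in range(h.n_snps):
        out[str(h.snp_ids[j])] = ivw(h.subset(idx != j), effects_model=effects_model)
    return out


def i2_gx(h: HarmonizedSet) -> float:
    """Instrument-strength heterogeneity statistic for MR-Egger reliability.

    I2_GX = (Q_GX - (J-1)) / Q_GX with Q_GX the Cochran statistic of the
    (|bx|, sebx) estimates about their weighted mean.  It estimates the
    attenuation factor of the Egger slope under exposure measurement error;
    values well below 0.9 indicate the slope is diluted toward zero.
    """
    if h.n_snps < 3:
        raise ValueError("I2_GX needs at least 3 SNPs")
    bx = np.abs(h.bx)
    w = 1.0 / h.sebx**2
    mean = np.sum(w * bx) / np.sum(w)
    q = float(np.sum(w * (bx - mean) ** 2))
    if q <= 0:
        return 0.0
    return max(0.0, (q - (h.n_snps - 1)) / q)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effects IVW slopes, vectorized over the left-out SNP."""
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def _rss_parts(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-SNP weighted residual contributions about the LOO slopes."""
    beta_loo = _loo_slopes(bx, by, w)
    return w * (by - beta_loo * bx) ** 2


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """MR-PRESSO global, outlier, step-by-step removal and distortion tests.

    The observed statistic is the weighted residual sum of squares about
    leave-one-out IVW slopes; its null distribution comes from ``n_sim``
    parametric simulations (by* ~ N(slope_loo * bx, seby), bx* ~ N(bx, sebx))
    with LOO slopes re-derived per simulation.  Per-SNP residual
    contributions give two-sided empirical outlier p-values, Bonferroni
    adjusted by J; outliers are removed worst-first and the tests re-run
    until the surviving set is clean or fewer than 4 SNPs remain.
    """
    if h.n_snps < 4:
        raise ValueError(f"insufficient instruments for MR-PRESSO (need >= 4, got {h.n_snps})")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")

    removed: list[str] = []
    current = h
    global_p: float | None = None
    first_per_snp: dict[str, float] = {}
    while current.n_snps >= 4:
        # stream keyed on (seed, surviving id set): re-running on the
        # survivors reproduces the final round, so termination is clean
        # deterministically, not just for one spawn order
        rng = _id_keyed_rng(seed, current.snp_ids)
        gp, per_snp_p, obs_parts = _presso_round(current, n_sim, rng)
        if global_p is None:
            global_p = gp
            first_per_snp = dict(zip(map(str, current.snp_ids), per_snp_p))
        padj = np.minimum(1.0, per_snp_p * current.n_snps)
        flagged = padj < outlier_alpha
        if not flagged.any():
            break
        worst = int(np.argmin(np.where(flagged, per_snp_p - 1e-12 * obs_parts, np.inf)))
        removed.append(str(current.snp_ids[worst]))
        current = current.subset(np.arange(current.n_snps) != worst)

    corrected = None
    distortion_p = None
    if removed:
        if current.n_snps >= 2:
            corrected = ivw(current)
            rng = _id_keyed_rng(seed, h.snp_ids, salt=1)
            distortion_p = _distortion_test(h, set(removed), corrected.beta, n_sim, rng)
        else:  # removal ate the instrument set; report what survives
            log.warning("MR-PRESSO removal left %d SNP(s); no corrected estimate", current.n_snps)
    return PressoResult(
        global_p=float(global_p), outliers=removed, distortion_p=distortion_p,
        corrected=corrected, per_snp_p=first_per_snp,
    )


def _id_keyed_rng(seed: int, snp_ids, salt: int = 0) -> np.random.Generator:
    key = zlib.crc32("|".join(map(str, snp_ids)).encode())
    return np.random.default_rng(np.random.SeedSequence((int(seed) & 0x7FFFFFFF, key, salt)))


def _presso_round(h: HarmonizedSet, n_sim: int, rng: np.random.Generator):
    w = 1.0 / h.seby**2
    obs_parts = _rss_parts(h.bx, h.by, w)
    rss_obs = obs_parts.sum()

    beta_loo = _loo_slopes(h.bx, h.by, w)
    BX = rng.normal(h.bx, h.sebx, size=(n_sim, h.n_snps))
    BY = rng.normal(beta_loo * h.bx, h.seby, size=(n_sim, h.n_snps))
    sim_parts = _rss_parts(BX, BY, w)
    rss_sim = sim_parts.sum(axis=1)

    global_p = (1.0 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1.0)
    p_hi = (1.0 + np.sum(sim_parts >= obs_parts, axis=0)) / (n_sim + 1.0)
    p_lo = (1.0 + np.sum(sim_parts <= obs_parts, axis=0)) / (n_sim + 1.0)
    per_snp_p = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))
    return float(global_p), per_snp_p, obs_parts


def _distortion_test(h: HarmonizedSet, outlier_ids: set[str], beta_corrected: float,
                     n_sim: int, rng: np.random.Generator) -> float:
    """Empirical p for the outlier-removal shift vs random removal of as many SNPs."""
    full = ivw(h, effects_model="fixed").beta
    d_obs = abs(beta_corrected - full)
    k = len(outlier_ids)
    J = h.n_snps
    if J - k < 2:
        return 1.0
    w = 1.0 / h.seby**2
    count = 0
    for _ in range(n_sim):
        keep = rng.permutation(J)[: J - k]
        beta_r = np.sum(w[keep] * h.bx[keep] * h.by[keep]) / np.sum(w[keep] * h.bx[keep] ** 2)
        if abs(beta_r - full) >= d_obs:
            count += 1
    return (1.0 + count) / (n_sim + 1.0)


def sensitivity_report(
    h: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
    effects_model: str = "multiplicative_random",
) -> SensitivityReport:
    """Run every diagnostic its instrument count allows and collate."""
    q, q_df, q_p = cochran_q(h)
    rep = SensitivityReport(q=q, q_df=q_df, q_p=q_p)
    if h.n_snps >= 3:
        eg = egger(h)
        rep.egger_intercept = eg.intercept
        rep.egger_intercept_se = eg.intercept_se
        rep.egger_intercept_p = eg.intercept_p
        rep.loo = leave_one_out(h, effects_model=effects_model)
    if h.n_snps >= 4:
        pr = mr_presso(h, n_sim=n_sim, outlier_alpha=outlier_alpha, seed=seed)
        rep.presso_global_p = pr.global_p
        rep.presso_outliers = pr.outliers
        rep.presso_distortion_p = pr.distortion_p
    return rep
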