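"""Causal-effect estimators for two-sample MR on a harmonized SNP set.

All estimators combine per-SNP Wald ratios (outcome effect / exposure
effect) under different robustness assumptions:

* ``ivw`` — inverse-variance weighted regression of by on bx through the
  origin; the primary method.  "Random effects" means multiplicative
  overdispersion: the fixed-effects SE is inflated by
  max(1, sqrt(Q / (J - 1))) with Q the Cochran heterogeneity statistic.
* ``egger`` — the same weighted regression with a free intercept; a nonzero
  intercept estimates directional pleiotropy, the slope remains a consistent
  causal estimate under the InSIDE assumption.
* ``weighted_median`` — the 50% point of the inverse-variance-weighted
  empirical CDF of ratios; consistent when >= 50% of weight is valid.
* ``weighted_mode`` — the mode of a weighted kernel density over ratios;
  consistent when the largest group of instruments is valid.

SEs for median and mode come from a seeded parametric bootstrap.  95% CIs
use the fixed 1.96 normal multiplier throughout; Egger p-values use the t
distribution with J - 2 df, all others the normal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .harmonize import HarmonizedSet

log = logging.getLogger(__name__)

Z95 = 1.96  # fixed CI multiplier, matching the printed-CI convention


@dataclass
class MREstimate:
    """One estimator's causal-effect result with uncertainty."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    or_scale: tuple[float, float, float] | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


def _norm_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _estimate(method: str, beta: float, se: float, n_snps: int, pvalue: float | None = None,
              **kw) -> MREstimate:
    return MREstimate(
        method=method, beta=float(beta), se=float(se),
        ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
        pvalue=_norm_p(beta / se) if pvalue is None else float(pvalue),
        n_snps=n_snps, **kw,
    )


def wald_ratio(bx: float, sebx: float, by: float, seby: float,
               second_order: bool = False) -> MREstimate:
    """Single-SNP causal estimate by/bx with delta-method SE.

    First order ignores the exposure SE (|seby/bx|); ``second_order`` adds
    the bx-uncertainty term.
    """
    if bx == 0:
        raise ValueError("wald ratio undefined for bx = 0")
    beta = by / bx
    if second_order:
        se = np.sqrt(seby**2 / bx**2 + by**2 * sebx**2 / bx**4)
    else:
        se = abs(seby / bx)
    return _estimate("wald_ratio", beta, se, 1)


def q_statistic(bx: np.ndarray, by: np.ndarray, seby: np.ndarray) -> float:
    """Cochran heterogeneity Q about the fixed-effects IVW slope.

    Single source of truth: the same Q drives the chi-square heterogeneity
    test and the random-effects IVW inflation.
    """
    w = 1.0 / np.asarray(seby, dtype=float) ** 2
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    beta = np.sum(w * bx * by) / np.sum(w * bx * bx)
    return float(np.sum(w * (by - beta * bx) ** 2))


def ivw(h: HarmonizedSet, effects_model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance weighted estimate (WLS of by on bx through origin).

    weights 1/seby^2; ``multiplicative_random`` (default) inflates the
    fixed-effects SE by max(1, sqrt(Q/(J-1))); ``fixed`` needs J >= 1,
    random effects J >= 2.
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    J = h.n_snps
    if J < 1 or (effects_model == "multiplicative_random" and J < 2):
        raise ValueError(f"IVW ({effects_model}) needs at least {'2' if J >= 1 else '1'} SNPs, got {J}")
    if np.all(h.bx == 0):
        raise ValueError("all exposure effects are zero")
    w = 1.0 / h.seby**2
    sxx = np.sum(w * h.bx**2)
    beta = np.sum(w * h.bx * h.by) / sxx
    se = sxx**-0.5
    method = "ivw_fe"
    if effects_model == "multiplicative_random":
        q = q_statistic(h.bx, h.by, h.seby)
        se *= max(1.0, np.sqrt(q / (J - 1)))
        method = "ivw_re"
    return _estimate(method, beta, se, J)


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression of by on bx with a free intercept.

    SNPs are first oriented so every bx >= 0 (flipping (bx, by) pairs),
    making the intercept identifiable.  Slope and intercept p-values come
    from the t distribution with J - 2 df.
    """
    J = h.n_snps
    if J < 3:
        raise ValueError(f"MR-Egger needs at least 3 SNPs, got {J}")
    sign = np.where(h.bx < 0, -1.0, 1.0)
    bx, by = h.bx * sign, h.by * sign
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / h.seby**2).fit()
    slope, slope_se, slope_p = fit.params[1], fit.bse[1], fit.pvalues[1]
    return _estimate(
        "egger", slope, slope_se, J, pvalue=slope_p,
        intercept=float(fit.params[0]), intercept_se=float(fit.bse[0]),
        intercept_p=float(fit.pvalues[0]),
    )


def _ratios_weights(bx, sebx, by, seby):
    r = by / bx
    w = bx**2 / seby**2
    return r, w


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """50% point of the weighted empirical CDF, linear interpolation."""
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    cw = np.cumsum(w) - 0.5 * w
    if cw[0] >= 0.5:
        return float(r[0])
    if cw[-1] < 0.5:
        return float(r[-1])
    k = int(np.searchsorted(cw, 0.5, side="left")) - 1
    return float(r[k] + (r[k + 1] - r[k]) * (0.5 - cw[k]) / (cw[k + 1] - cw[k]))


def _weighted_median_rows(R: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Row-wise weighted median for bootstrap matrices (n_boot, J)."""
    order = np.argsort(R, axis=1)
    r = np.take_along_axis(R, order, axis=1)
    w = np.take_along_axis(W, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    cw = np.cumsum(w, axis=1) - 0.5 * w
    below = cw < 0.5
    k = below.sum(axis=1) - 1
    n, J = R.shape
    out = np.empty(n)
    lo = k < 0
    hi = k >= J - 1
    out[lo] = r[lo, 0]
    out[hi] = r[hi, -1]
    mid = ~(lo | hi)
    if mid.any():
        i = np.flatnonzero(mid)
        kk = k[i]
        c0 = cw[i, kk]
        c1 = cw[i, kk + 1]
        r0 = r[i, kk]
        r1 = r[i, kk + 1]
        out[i] = r0 + (r1 - r0) * (0.5 - c0) / (c1 - c0)
    return out


def _drop_zero_bx(h: HarmonizedSet, method: str) -> HarmonizedSet:
    if np.any(h.bx == 0):
        n0 = int(np.sum(h.bx == 0))
        warnings.warn(f"{method}: dropping {n0} SNP(s) with bx = 0")
        h = h.subset(h.bx != 0)
    if h.n_snps < 3:
        raise ValueError(f"{method} needs at least 3 SNPs with nonzero bx, got {h.n_snps}")
    return h


def _bootstrap_samples(h: HarmonizedSet, n_boot: int, seed: int):
    rng = np.random.default_rng(seed)
    BX = rng.normal(h.bx, h.sebx, size=(n_boot, h.n_snps))
    BY = rng.normal(h.by, h.seby, size=(n_boot, h.n_snps))
    BX[BX == 0] = np.finfo(float).tiny  # a.s. never hit; guards the division
    return BY / BX, BX**2 / h.seby**2


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimate; SE from a seeded parametric bootstrap.

    Per-SNP ratios by/bx weighted by bx^2/seby^2 (inverse variance of the
    ratio to first order); consistent when valid instruments carry at least
    half the weight.
    """
    h = _drop_zero_bx(h, "weighted_median")
    r, w = _ratios_weights(h.bx, h.sebx, h.by, h.seby)
    est = _weighted_median(r, w)
    R, W = _bootstrap_samples(h, n_boot, seed)
    boots = _weighted_median_rows(R, W)
    se = float(np.std(boots, ddof=1))
    if se == 0:
        se = np.finfo(float).tiny
    return _estimate("weighted_median", est, se, h.n_snps)


def _mode_bandwidth(r: np.ndarray, factor: float) -> float:
    s = np.std(r, ddof=1)
    iqr = np.subtract(*np.percentile(r, [75, 25]))
    base = 0.9 * min(s, abs(iqr) / 1.34) * len(r) ** (-1 / 5)
    return factor * base


def _weighted_mode(r: np.ndarray, w: np.ndarray, bandwidth: float, n_grid: int = 512) -> float:
    if bandwidth <= 0:  # degenerate: all ratios (essentially) identical
        return float(r[0])
    grid = np.linspace(r.min() - 3 * bandwidth, r.max() + 3 * bandwidth, n_grid)
    dens = (w[:, None] * stats.norm.pdf((grid[None, :] - r[:, None]) / bandwidth)).sum(axis=0)
    return float(grid[np.argmax(dens)])


def _weighted_mode_rows(R: np.ndarray, W: np.ndarray, factor: float, n_grid: int = 256) -> np.ndarray:
    """Row-wise weighted KDE mode, chunked to bound memory."""
    n, J = R.shape
    out = np.empty(n)
    s = np.std(R, axis=1, ddof=1)
    iqr = np.abs(np.diff(np.percentile(R, [25, 75], axis=1), axis=0)[0])
    hbw = factor * 0.9 * np.minimum(s, iqr / 1.34) * J ** (-1 / 5)
    hbw[hbw <= 0] = np.finfo(float).tiny
    step = max(1, 2_000_000 // (n_grid * J))
    for lo in range(0, n, step):
        sl = slice(lo, min(lo + step, n))
        Rc, Wc, hc = R[sl], W[sl], hbw[sl]
        gmin = Rc.min(axis=1) - 3 * hc
        gmax = Rc.max(axis=1) + 3 * hc
        grid = gmin[:, None] + (gmax - gmin)[:, None] * np.linspace(0, 1, n_grid)[None, :]
        z = (grid[:, :, None] - Rc[:, None, :]) / hc[:, None, None]
        dens = (Wc[:, None, :] * np.exp(-0.5 * z * z)).sum(axis=2)
        out[sl] = np.take_along_axis(grid, np.argmax(dens, axis=1)[:, None], axis=1)[:, 0]
    return out


def weighted_mode(h: HarmonizedSet, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-mode estimate (normal-kernel density over ratios).

    Bandwidth is the Silverman rule 0.9*min(sd, IQR/1.34)*J^(-1/5) scaled by
    ``bandwidth_factor``; SE is 1.4826 x the median absolute deviation of
    bootstrap modes.
    """
    h = _drop_zero_bx(h, "weighted_mode")
    r, w = _ratios_weights(h.bx, h.sebx, h.by, h.seby)
    est = _weighted_mode(r, w, _mode_bandwidth(r, bandwidth_factor))
    R, W = _bootstrap_samples(h, n_boot, seed)
    boots = _weighted_mode_rows(R, W, bandwidth_factor)
    se = float(1.4826 * np.median(np.abs(boots - np.median(boots))))
    if se == 0:
        se = np.finfo(float).tiny
    return _estimate("weighted_mode", est, se, h.n_snps)


def to_odds_ratio(est: MREstimate) -> MREstimate:
    """Attach the exp-transformed (OR, CI) triple to a log-scale estimate."""
    triple = (float(np.exp(est.beta)),
              float(np.exp(est.beta - Z95 * est.se)),
              float(np.exp(est.beta + Z95 * est.se)))
    return replace(est, or_scale=triple)
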