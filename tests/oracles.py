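"""Independent brute-force oracles used to cross-check the implementation.

Everything here is coded directly from the definitions, over plain dicts and
lists, without importing the corresponding library routines.
"""

from __future__ import annotations

import numpy as np


def clump_oracle(records, ld_pairs, r2_threshold, window_bp):
    """Greedy clumping over plain record dicts.

    ``records``: list of dicts with snp, chrom, pos, pval.
    ``ld_pairs``: dict mapping frozenset({a, b}) -> r2 (absent = 0).
    Returns the kept snp ids as a set.
    """

    def chrom_key(c):
        try:
            return (0, int(c), "")
        except (TypeError, ValueError):
            return (1, 0, str(c))

    def r2(a, b):
        if a == b:
            return 1.0
        return ld_pairs.get(frozenset({a, b}), 0.0)

    remaining = list(records)
    kept = set()
    while remaining:
        best = min(remaining, key=lambda r: (r["pval"], chrom_key(r["chrom"]), r["pos"], r["snp"]))
        kept.add(best["snp"])
        survivors = []
        for r in remaining:
            if r["snp"] == best["snp"]:
                continue
            same_chrom = r["chrom"] == best["chrom"]
            close = same_chrom and abs(r["pos"] - best["pos"]) <= window_bp
            if close and r2(r["snp"], best["snp"]) >= r2_threshold:
                continue
            survivors.append(r)
        remaining = survivors
    return kept


def weighted_median_oracle(ratios, weights):
    """50% point of the weighted empirical CDF by explicit scan."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    cum = 0.0
    points = []
    for wi in w:
        points.append(cum + 0.5 * wi)
        cum += wi
    points = np.asarray(points)
    if points[0] >= 0.5:
        return float(r[0])
    if points[-1] < 0.5:
        return float(r[-1])
    for k in range(len(points) - 1):
        if points[k] < 0.5 <= points[k + 1]:
            frac = (0.5 - points[k]) / (points[k + 1] - points[k])
            return float(r[k] + frac * (r[k + 1] - r[k]))
    raise AssertionError("unreachable")


def mode_grid_oracle(ratios, weights, bandwidth, n_grid=4001):
    """Weighted normal-kernel density mode on a dense explicit grid."""
    r = np.asarray(ratios, dtype=float)
    w = np.asarray(weights, dtype=float)
    xs = np.linspace(r.min() - 4 * bandwidth, r.max() + 4 * bandwidth, n_grid)
    best_x, best_d = xs[0], -np.inf
    for x in xs:
        d = float(np.sum(w * np.exp(-0.5 * ((x - r) / bandwidth) ** 2)))
        if d > best_d:
            best_x, best_d = x, d
    return float(best_x)


def ivw_oracle(bx, by, seby):
    """Hand-rolled weighted least squares through the origin."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    w = 1.0 / np.asarray(seby, dtype=float) ** 2
    num = float(np.sum(w * bx * by))
    den = float(np.sum(w * bx * bx))
    return num / den, den ** -0.5
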