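#!/usr/bin/env python
"""Monte-Carlo calibration summary for the estimators and diagnostics.

Quick-look version of the checks scripts/acceptance.py runs at full size:
IVW type-I error under the null, estimator recovery at theta = -0.14,
MR-PRESSO null calibration and outlier power.  Writes
results/calibration.tsv and prints each line as it is computed.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import mrtea as mr  # noqa: E402

OUT = Path(__file__).resolve().parent.parent / "results" / "calibration.tsv"
N_REP = 200
THETA = -0.14


def _h(seed, **kw):
    exp, out, _, truth = mr.simulate_pair(mr.SimConfig(seed=seed, **kw))
    return mr.harmonize(exp, out), truth


if __name__ == "__main__":
    rows = []

    rej = np.mean([mr.ivw(_h(s, theta=0.0)[0]).pvalue < 0.05 for s in range(N_REP)])
    rows.append(("ivw_type1_error_random_effects", rej, 0.05, N_REP))
    print(f"IVW (RE) type-I error at alpha=0.05: {rej:.3f} over {N_REP} null studies")

    for name, fn in [("ivw", mr.ivw), ("egger", mr.egger),
                     ("weighted_median", lambda h: mr.weighted_median(h, n_boot=50, seed=0)),
                     ("weighted_mode", lambda h: mr.weighted_mode(h, n_boot=50, seed=0))]:
        vals = [fn(_h(1000 + s, theta=THETA)[0]).beta for s in range(N_REP)]
        rows.append((f"{name}_mean_at_theta_-0.14", float(np.mean(vals)), THETA, N_REP))
        print(f"{name}: mean estimate {np.mean(vals):+.4f} (target {THETA})")

    ps = [mr.mr_presso(_h(2000 + s, theta=0.0)[0], n_sim=1000, seed=s).global_p
          for s in range(N_REP)]
    rows.append(("presso_null_mean_global_p", float(np.mean(ps)), 0.5, N_REP))
    print(f"MR-PRESSO null mean global p: {np.mean(ps):.3f}")

    hits = 0
    for s in range(N_REP):
        h, truth = _h(3000 + s, theta=0.2, j_snps=20, outlier_fraction=1 / 20, outlier_size=10.0)
        res = mr.mr_presso(h, n_sim=1000, seed=s)
        hits += (set(truth.outlier_ids) & set(map(str, h.snp_ids))) <= set(res.outliers)
    rows.append(("presso_10se_outlier_detection", hits / N_REP, 0.95, N_REP))
    print(f"MR-PRESSO 10-SE outlier detection rate: {hits / N_REP:.3f}")

    OUT.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["quantity", "value", "reference", "n_rep"]).to_csv(
        OUT, sep="\t", index=False)
    print(f"table written to {OUT}")
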