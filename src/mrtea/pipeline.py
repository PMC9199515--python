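"""Orchestrate the full study: one exposure against many outcome GWASs.

The pipeline mirrors the study design: instruments are selected once from
the exposure GWAS (genome-wide significance + LD clumping), harmonized
against each outcome, and the random-effects IVW estimate is the primary
result per outcome.  Family-wise control is Bonferroni over the configured
outcome family (0.05 / 28 in the original design); the three verification
estimators (Egger, weighted median, weighted mode) run for every outcome by
default, or only for Bonferroni-significant ones when
``verify_significant_only`` replicates the original reporting flow.  Every
outcome also gets the full sensitivity suite its instrument count allows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from .harmonize import HarmonizedSet, harmonize
from .instruments import InstrumentSet, select_instruments
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import LDReference, SumStatsTable, read_ld_table, read_sumstats

log = logging.getLogger(__name__)

FLAG_SIGNIFICANT = "significant"
FLAG_NOMINAL = "nominal"
FLAG_NULL = "null"
FLAG_NOT_ESTIMABLE = "not_estimable"

_PANEL_ORDER = {"baseline": 0, "continuous": 1, "survival": 2}


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m for m tests."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    return alpha / m


@dataclass
class OutcomeSpec:
    name: str
    path: str
    trait_type: str = "survival"
    panel: str = "survival"


@dataclass
class StudyConfig:
    """Everything needed to run the study; loadable from a YAML document."""

    exposure_path: str
    exposure_name: str = "exposure"
    exposure_type: str = "continuous"
    ld_path: str | None = None
    outcomes: list[OutcomeSpec] = field(default_factory=list)
    family: list[str] | None = None  # Bonferroni family; None = all outcomes
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    palindrome_window: float = 0.08
    drop_all_palindromes: bool = False
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median", "weighted_mode")
    n_boot: int = 1000
    n_sim: int = 1000
    verify_significant_only: bool = False
    alpha_family: float = 0.05
    or_scale: str = "auto"  # auto | on | off
    seed: int = 0
    base_dir: Path = Path(".")

    def __post_init__(self) -> None:
        names = [o.name for o in self.outcomes]
        if len(set(names)) != len(names):
            raise ValueError("outcome names must be unique")
        if not 0 < self.alpha_family < 1:
            raise ValueError("alpha_family must be in (0,1)")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text())
        thr = doc.get("thresholds", {})
        estn = doc.get("estimation", {})
        return cls(
            exposure_path=doc["exposure"]["path"],
            exposure_name=doc["exposure"].get("name", "exposure"),
            exposure_type=doc["exposure"].get("trait_type", "continuous"),
            ld_path=doc.get("ld_path"),
            outcomes=[OutcomeSpec(**o) for o in doc.get("outcomes", [])],
            family=doc.get("family"),
            p_threshold=float(thr.get("p_threshold", 5e-8)),
            clump_r2=float(thr.get("clump_r2", 0.001)),
            clump_kb=int(thr.get("clump_kb", 10_000)),
            palindrome_window=float(thr.get("palindrome_window", 0.08)),
            drop_all_palindromes=bool(thr.get("drop_all_palindromes", False)),
            methods=tuple(estn.get("methods", ("ivw", "egger", "weighted_median", "weighted_mode"))),
            n_boot=int(estn.get("n_boot", 1000)),
            n_sim=int(estn.get("n_sim", 1000)),
            verify_significant_only=bool(estn.get("verify_significant_only", False)),
            alpha_family=float(doc.get("alpha_family", 0.05)),
            or_scale=doc.get("or_scale", "auto"),
            seed=int(doc.get("seed", 0)),
            base_dir=path.parent,
        )


@dataclass
class OutcomeResult:
    name: str
    panel: str
    trait_type: str
    flag: str
    n_harmonized: int
    estimates: dict[str, est.MREstimate] = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None
    harmonized: HarmonizedSet | None = None
    harmonization_actions: dict[str, int] = field(default_factory=dict)


@dataclass
class StudyResults:
    outcomes: dict[str, OutcomeResult]
    bonferroni_threshold: float
    family: list[str]
    instruments: InstrumentSet
    seed: int


def _exponentiate(config: StudyConfig, trait_type: str) -> bool:
    if config.or_scale == "on":
        return True
    if config.or_scale == "off":
        return False
    return trait_type in ("binary", "survival")


def _analyse_outcome(
    config: StudyConfig,
    instruments: InstrumentSet,
    spec: OutcomeSpec,
    threshold: float,
    seed: int,
) -> OutcomeResult:
    outcome = read_sumstats(config.base_dir / spec.path, trait_name=spec.name, trait_type=spec.trait_type)
    h = harmonize(instruments, outcome,
                  palindrome_eaf_window=config.palindrome_window,
                  drop_all_palindromes=config.drop_all_palindromes)
    action_counts: dict[str, int] = {}
    for a in h.actions.values():
        action_counts[a] = action_counts.get(a, 0) + 1
    res = OutcomeResult(name=spec.name, panel=spec.panel, trait_type=spec.trait_type,
                        flag=FLAG_NOT_ESTIMABLE, n_harmonized=h.n_snps,
                        harmonized=h, harmonization_actions=action_counts)
    if h.n_snps < 2:
        log.warning("%s: only %d harmonized SNP(s); not estimable", spec.name, h.n_snps)
        return res

    ivw_est = est.ivw(h)
    res.estimates["ivw"] = ivw_est
    if ivw_est.pvalue < threshold:
        res.flag = FLAG_SIGNIFICANT
    elif ivw_est.pvalue < 0.05:
        res.flag = FLAG_NOMINAL
    else:
        res.flag = FLAG_NULL

    run_verification = (not config.verify_significant_only) or res.flag == FLAG_SIGNIFICANT
    if run_verification and h.n_snps >= 3:
        if "egger" in config.methods:
            res.estimates["egger"] = est.egger(h)
        if "weighted_median" in config.methods:
            res.estimates["weighted_median"] = est.weighted_median(h, n_boot=config.n_boot, seed=seed)
        if "weighted_mode" in config.methods:
            res.estimates["weighted_mode"] = est.weighted_mode(h, n_boot=config.n_boot, seed=seed)
    if _exponentiate(config, spec.trait_type):
        res.estimates = {k: est.to_odds_ratio(v) for k, v in res.estimates.items()}
    res.sensitivity = sensitivity_report(h, n_sim=config.n_sim, seed=seed)
    return res


def run_study(config: StudyConfig) -> StudyResults:
    """Run the full multi-outcome analysis; deterministic given config.seed."""
    exposure = read_sumstats(config.base_dir / config.exposure_path,
                             trait_name=config.exposure_name, trait_type=config.exposure_type)
    ld = read_ld_table(config.base_dir / config.ld_path) if config.ld_path else LDReference()
    instruments = select_instruments(
        exposure, ld, p_threshold=config.p_threshold,
        r2_threshold=config.clump_r2, window_bp=config.clump_kb * 1000,
    )
    family = config.family if config.family is not None else [o.name for o in config.outcomes]
    threshold = bonferroni_threshold(config.alpha_family, max(1, len(family)))

    seeds = np.random.SeedSequence(config.seed).spawn(len(config.outcomes))
    results: dict[str, OutcomeResult] = {}
    for spec, child in zip(config.outcomes, seeds):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        res = _analyse_outcome(config, instruments, spec, threshold, child_seed)
        if spec.name not in family and res.flag == FLAG_SIGNIFICANT:
            res.flag = FLAG_NOMINAL  # outside the Bonferroni family
        results[spec.name] = res
    return StudyResults(outcomes=results, bonferroni_threshold=threshold,
                        family=family, instruments=instruments, seed=config.seed)


def export_forest(results: StudyResults) -> pd.DataFrame:
    """Forest-plot table: one row per outcome, baseline panel first.

    ``effect``/CI are on the odds-ratio scale when the estimate carries one,
    else on the beta scale; ``mark`` is "a" for Bonferroni significance,
    "b" for nominal, empty otherwise.
    """
    rows = []
    order = sorted(results.outcomes.values(),
                   key=lambda r: (_PANEL_ORDER.get(r.panel, 9), r.name))
    for r in order:
        e = r.estimates.get("ivw")
        if e is None:
            rows.append({"outcome": r.name, "panel": r.panel, "n_snps": r.n_harmonized,
                         "effect": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "pvalue": np.nan, "scale": "", "mark": "", "flag": r.flag})
            continue
        if e.or_scale is not None:
            effect, lo, hi, scale = *e.or_scale, "OR"
        else:
            effect, lo, hi, scale = e.beta, e.ci_low, e.ci_high, "beta"
        mark = {"significant": "a", "nominal": "b"}.get(r.flag, "")
        rows.append({"outcome": r.name, "panel": r.panel, "n_snps": e.n_snps,
                     "effect": effect, "ci_low": lo, "ci_high": hi,
                     "pvalue": e.pvalue, "scale": scale, "mark": mark, "flag": r.flag})
    return pd.DataFrame(rows)


def export_sensitivity(results: StudyResults) -> pd.DataFrame:
    """Diagnostics table in the heterogeneity/pleiotropy report shape."""
    rows = []
    order = sorted(results.outcomes.values(),
                   key=lambda r: (_PANEL_ORDER.get(r.panel, 9), r.name))
    for r in order:
        s = r.sensitivity
        rows.append({
            "outcome": r.name, "panel": r.panel,
            "q": None if s is None else s.q,
            "q_df": None if s is None else s.q_df,
            "q_p": None if s is None else s.q_p,
            "egger_intercept": None if s is None else s.egger_intercept,
            "egger_intercept_se": None if s is None else s.egger_intercept_se,
            "egger_intercept_p": None if s is None else s.egger_intercept_p,
            "presso_global_p": None if s is None else s.presso_global_p,
            "presso_n_outliers": None if s is None else len(s.presso_outliers),
        })
    return pd.DataFrame(rows)


def export_scatter_funnel(h: HarmonizedSet, estimates: list[est.MREstimate]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP scatter and funnel tables with fitted-slope reference columns.

    The scatter table carries (bx, sebx, by, seby) per SNP plus one constant
    ``slope_<method>`` column per estimate (and ``intercept_egger``); the
    funnel table carries each SNP's Wald ratio and inverse ratio-SE plus
    ``ref_<method>`` vertical-line columns.
    """
    if not estimates:
        raise ValueError("at least one estimate required")
    scatter = pd.DataFrame({
        "snp": h.snp_ids, "bx": h.bx, "sebx": h.sebx, "by": h.by, "seby": h.seby,
    })
    ratio = h.by / h.bx
    inv_se = np.abs(h.bx) / h.seby
    funnel = pd.DataFrame({"snp": h.snp_ids, "wald_ratio": ratio, "inv_se": inv_se})
    for e in estimates:
        scatter[f"slope_{e.method}"] = e.beta
        funnel[f"ref_{e.method}"] = e.beta
        if e.method == "egger" and e.intercept is not None:
            scatter["intercept_egger"] = e.intercept
    return scatter, funnel


def write_study_outputs(results: StudyResults, out_dir, config: StudyConfig | None = None) -> None:
    """Write forest/sensitivity/scatter/funnel TSVs plus a run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    export_forest(results).to_csv(out_dir / "results.tsv", sep="\t", index=False, na_rep="NA")
    export_sensitivity(results).to_csv(out_dir / "sensitivity.tsv", sep="\t", index=False, na_rep="NA")
    manifest = {
        "seed": results.seed,
        "bonferroni_threshold": results.bonferroni_threshold,
        "family_size": len(results.family),
        "n_instruments": len(results.instruments),
        "instrument_f_stats": {k: round(v, 4) for k, v in results.instruments.f_stats.items()},
        "outcomes": {
            name: {"flag": r.flag, "n_harmonized": r.n_harmonized,
                   "harmonization_actions": r.harmonization_actions}
            for name, r in sorted(results.outcomes.items())
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    for name, r in sorted(results.outcomes.items()):
        if r.harmonized is None or not r.estimates:
            continue
        scatter, funnel = export_scatter_funnel(r.harmonized, list(r.estimates.values()))
        safe = name.replace("/", "_")
        scatter.to_csv(out_dir / f"scatter_{safe}.tsv", sep="\t", index=False)
        funnel.to_csv(out_dir / f"funnel_{safe}.tsv", sep="\t", index=False)
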