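"""Config-driven orchestration of the full corrected-PSA analysis.

``run_analysis`` executes, on any conforming cohort (read from disk or
simulated): eligibility filtering -> score construction (4-SNP PSA panel,
optionally the aggressive-disease panel) -> per-SNP association tables ->
allele-count summary -> ROC/AUC comparison of the four score sets (measured
PSA; corrected for the PSA-SNPs; corrected for the aggressive SNPs;
corrected for both) with paired DeLong tests -> fixed-sensitivity operating
points with likelihood ratios -> internal-coefficient logistic models ->
configured sensitivity analyses (age strata, single-SNP correction, extreme
grades, T3-T4 inclusion).  Reports are deterministic under a fixed seed and
carry config/seed provenance.

Score-set definitions: with combined genetic effects ``g4`` (PSA panel) and
``g10`` (aggressive panel), the four score sets are PSA, PSA - g4,
PSA - g10 and PSA - g4*g10 under the canonical subtraction mode (the
division mode divides instead).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    fit_internal_model,
    hwe_test_from_dosages,
    per_snp_linear,
    per_snp_logistic,
    select_stratum,
    unadjusted_variance_explained,
)
from .cohort import CohortTable, classify_risk, filter_eligible, read_cohort
from .discrimination import (
    auc,
    compare_auc_paired,
    roc_curve,
    spec_at_sensitivity,
    with_prior_odds,
)
from .exceptions import ConfigError, DataError, PsaCorrectError
from .scores import Panel, aggressive_panel, combined_genetic_effect, corrected_psa_score, psa_panel, score_table
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis",
           "summarize_allele_counts", "write_report"]


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    cohort_path: str | None = None           # mutually exclusive with simulation
    simulation: SimulationConfig | None = None
    psa_panel: Panel | None = None           # defaults to the bundled panels
    aggressive_panel_: Panel | None = None
    correction_mode: str = "subtract"
    covariates: tuple[str, ...] = ("age", "centre")
    psa_window: tuple[float, float] = (3.0, 10.0)
    target_sensitivity: float = 0.90
    ci_level: float = 0.95
    include_t3t4: bool = False
    run_age_strata: bool = True
    run_single_snp: bool = True
    run_extreme_grades: bool = True
    run_t3t4_inclusion: bool = True
    prior_odds: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.target_sensitivity < 1.0:
            raise ConfigError("target_sensitivity must be in (0,1)")
        if not 0.5 <= self.ci_level < 1.0:
            raise ConfigError("ci_level must be in [0.5, 1)")
        if self.cohort_path is None and self.simulation is None:
            raise ConfigError("either cohort_path or simulation must be given")


@dataclass
class AnalysisReport:
    cohort_summary: dict
    hwe: pd.DataFrame
    psa_associations: pd.DataFrame       # Table-1 analogue
    risk_associations: pd.DataFrame      # Table-2 analogue
    allele_counts: pd.DataFrame          # Table-3 analogue
    allele_count_summary: dict
    auc_block: dict
    lr_block: list
    internal_models: list
    sensitivity: dict
    provenance: dict
    run_log: list


def _digest(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _assoc_row(res) -> dict:
    return {"rsid": res.rsid, "stratum": res.stratum, "n": res.n,
            "effect": res.effect, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p_value": res.p_value, "flag": res.flag}


def summarize_allele_counts(df: pd.DataFrame, count_column: str = "risk_allele_count",
                            value_columns=("psa", "corrected_score")) -> tuple[pd.DataFrame, dict]:
    """Per allele-count stratum: N and mean (SD) of each value column, plus
    overall median and attainable range of the count.

    Both the measured PSA and the corrected score are emitted per stratum;
    which of the two a published per-count table shows is left to the
    reader (the weighted means differ and both are reported)."""
    counts = df[count_column]
    rows = []
    for k, grp in df.groupby(count_column, sort=True):
        row = {"allele_count": int(k), "n": int(len(grp))}
        for col in value_columns:
            row[f"mean_{col}"] = float(grp[col].mean())
            row[f"sd_{col}"] = float(grp[col].std(ddof=1)) if len(grp) > 1 else 0.0
        rows.append(row)
    table = pd.DataFrame(rows)
    summary = {
        "n_total": int(len(df)),
        "median_allele_count": float(counts.median()),
        "range": [int(counts.min()), int(counts.max())],
    }
    for col in value_columns:
        summary[f"mean_{col}"] = float(df[col].mean())
        summary[f"min_{col}"] = float(df[col].min())
        summary[f"max_{col}"] = float(df[col].max())
    return table, summary


def _load_cohort(config: AnalysisConfig) -> CohortTable:
    if config.simulation is not None:
        sim = config.simulation
        if sim.seed != config.seed:
            sim = sim.replace(seed=config.seed)
        return simulate_cohort(sim)
    return read_cohort(config.cohort_path)


def _auc_entry(result) -> dict:
    return {"auc": result.auc, "variance": result.variance,
            "ci": [result.ci_low, result.ci_high],
            "n_pos": result.n_pos, "n_neg": result.n_neg}


def _auc_comparison_block(score_sets: dict, y: np.ndarray, ci_level: float) -> dict:
    block = {"scores": {}, "paired_vs_measured": {}}
    for name, s in score_sets.items():
        block["scores"][name] = _auc_entry(auc(s, y, ci_level=ci_level))
    ref = score_sets["measured_psa"]
    for name, s in score_sets.items():
        if name == "measured_psa":
            continue
        cmp_ = compare_auc_paired(s, ref, y)
        block["paired_vs_measured"][name] = {
            "auc_difference": cmp_.difference, "p_value": cmp_.p_value,
            "method": cmp_.method}
    return block


def _lr_block(score_sets: dict, y: np.ndarray, target: float,
              prior_odds: float | None) -> list:
    out = []
    for name, s in score_sets.items():
        op = spec_at_sensitivity(roc_curve(s, y), target)
        if prior_odds is not None:
            op = with_prior_odds(op, prior_odds)
        out.append({"score_set": name, "target_sensitivity": op.target_sensitivity,
                    "achieved_sensitivity": op.achieved_sensitivity,
                    "specificity": op.specificity, "threshold": op.threshold,
                    "likelihood_ratio": op.likelihood_ratio,
                    "prior_odds": op.prior_odds, "posterior_odds": op.posterior_odds})
    return out


def _score_sets(df: pd.DataFrame, p4: Panel, p10: Panel, mode: str) -> dict:
    g4 = combined_genetic_effect(df, p4).to_numpy()
    psa = df["psa"].to_numpy(dtype=float)
    sets = {
        "measured_psa": psa,
        "corrected_psa_snps": corrected_psa_score(psa, g4, mode=mode),
    }
    if all(r in df.columns for r in p10.rsids):
        g10 = combined_genetic_effect(df, p10).to_numpy()
        sets["corrected_aggressive_snps"] = corrected_psa_score(psa, g10, mode=mode)
        sets["corrected_both"] = corrected_psa_score(psa, g4 * g10, mode=mode)
    return sets


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute the full analysis described in the module docstring."""
    config.validate()
    log: list[dict] = []

    p4 = config.psa_panel or psa_panel()
    p10 = config.aggressive_panel_ or aggressive_panel()
    all_snps = p4.rsids + p10.rsids

    raw = _load_cohort(config)
    log.append({"op": "load_cohort", "rows": len(raw),
                "source": raw.provenance.get("source")})

    table = filter_eligible(raw, psa_window=config.psa_window,
                            require_panel=[s for s in all_snps if s in raw.data.columns],
                            include_t3t4=config.include_t3t4)
    if len(table) == 0:
        raise DataError("no eligible subjects after filtering")
    df = table.data
    log.append({"op": "filter_eligible", "rows": len(df),
                "digest": _digest(df["psa"].to_numpy())})

    # --- scores -----------------------------------------------------------
    stab = score_table(df, p4, mode=config.correction_mode)
    df = pd.concat([df, stab], axis=1)
    score_sets = _score_sets(df, p4, p10, config.correction_mode)
    y = (df["risk_group"] == "high").to_numpy()
    log.append({"op": "score", "digest": _digest(stab["corrected_score"].to_numpy())})

    n_high, n_low = int(y.sum()), int((~y).sum())
    cohort_summary = {
        "n": len(df), "n_high": n_high, "n_low": n_low,
        "low_risk_percent": 100.0 * n_low / len(df),
        "high_risk_percent": 100.0 * n_high / len(df),
        "mean_psa": float(df["psa"].mean()), "sd_psa": float(df["psa"].std(ddof=1)),
        "mean_psa_high": float(df.loc[y, "psa"].mean()),
        "mean_psa_low": float(df.loc[~y, "psa"].mean()),
        "mean_age_high": float(df.loc[y, "age"].mean()),
        "mean_age_low": float(df.loc[~y, "age"].mean()),
    }

    has_aggressive = all(r in df.columns for r in p10.rsids)
    present_snps = [r for r in all_snps if r in df.columns]

    # --- HWE --------------------------------------------------------------
    hwe_rows = []
    for rsid in present_snps:
        r = hwe_test_from_dosages(df[rsid], rsid=rsid)
        hwe_rows.append({"rsid": rsid, "n0": r.counts[0], "n1": r.counts[1],
                         "n2": r.counts[2], "statistic": r.statistic,
                         "p_value": r.p_value, "monomorphic": r.monomorphic})
    hwe = pd.DataFrame(hwe_rows)
    log.append({"op": "hwe", "snps": len(hwe_rows)})

    # --- per-SNP associations (Table-1 / Table-2 analogues) ---------------
    covs = list(config.covariates)
    t1_rows = []
    for rsid in p4.rsids:
        for stratum in ("low_risk", "high_risk"):
            try:
                res = per_snp_linear(table_with(df, table), rsid, covs, stratum,
                                     ci_level=config.ci_level)
                r2, f = unadjusted_variance_explained(table_with(df, table), rsid, stratum)
                row = _assoc_row(res)
                row.update({"r_squared_pct": 100.0 * r2, "f_statistic": f})
            except PsaCorrectError as err:
                row = {"rsid": rsid, "stratum": stratum, "flag": str(err)}
            t1_rows.append(row)
    psa_assoc = pd.DataFrame(t1_rows)

    t2_rows = []
    for rsid in present_snps:
        try:
            res = per_snp_logistic(table_with(df, table), rsid, covs,
                                   ci_level=config.ci_level)
            t2_rows.append(_assoc_row(res))
        except PsaCorrectError as err:
            t2_rows.append({"rsid": rsid, "stratum": "all", "flag": str(err)})
    risk_assoc = pd.DataFrame(t2_rows)
    log.append({"op": "associations", "rows": len(t1_rows) + len(t2_rows)})

    # --- allele-count summary (Table-3 analogue) --------------------------
    allele_tbl, allele_summary = summarize_allele_counts(df)
    log.append({"op": "allele_counts"})

    # --- discrimination ----------------------------------------------------
    auc_block = _auc_comparison_block(score_sets, y, config.ci_level)
    prior = config.prior_odds
    if prior is None:
        prior = n_high / n_low           # cohort prevalence odds, labelled below
    lr_block = _lr_block(score_sets, y, config.target_sensitivity, prior)
    log.append({"op": "discrimination"})

    # --- internal-coefficient models --------------------------------------
    internal = []
    specs = [("model1_psa", dict(include_psa=True)),
             ("model2_psa_psasnps", dict(include_psa=True, psa_snps=p4))]
    if has_aggressive:
        specs += [("model3_psa_aggsnps", dict(include_psa=True, aggressive_snps=p10)),
                  ("model4_all", dict(include_psa=True, psa_snps=p4, aggressive_snps=p10))]
    for name, kw in specs:
        try:
            internal.append(fit_internal_model(table_with(df, table), name=name,
                                               ci_level=config.ci_level, **kw).to_dict())
        except PsaCorrectError as err:
            internal.append({"name": name, "flag": str(err)})
    log.append({"op": "internal_models"})

    # --- sensitivity analyses ----------------------------------------------
    sensitivity: dict = {}
    if config.run_age_strata:
        sensitivity["age_strata"] = {}
        for stratum, mask in (("age<65", df["age"] < 65), ("age>=65", df["age"] >= 65)):
            entry = {}
            for name in ("measured_psa", "corrected_psa_snps"):
                s, ym = score_sets[name][mask.to_numpy()], y[mask.to_numpy()]
                if ym.any() and not ym.all():
                    entry[name] = _auc_entry(auc(s, ym, ci_level=config.ci_level))
                else:
                    entry[name] = {"flag": "single-class stratum"}
            sensitivity["age_strata"][stratum] = entry

    if config.run_single_snp:
        sensitivity["single_snp_correction"] = {}
        psa = df["psa"].to_numpy(dtype=float)
        for snp in p4:
            g1 = combined_genetic_effect(df, p4.subset([snp.rsid])).to_numpy()
            s = corrected_psa_score(psa, g1, mode=config.correction_mode)
            sensitivity["single_snp_correction"][snp.rsid] = _auc_entry(
                auc(s, y, ci_level=config.ci_level))

    if config.run_extreme_grades:
        hi_mask = (df["gleason"] >= 8) & y
        lo_mask = (df["gleason"].between(2, 6)) & ~y
        mask = (hi_mask | lo_mask).to_numpy()
        entry = {"n_very_high": int(hi_mask.sum()), "n_very_low": int(lo_mask.sum())}
        if hi_mask.any() and lo_mask.any():
            for name in ("measured_psa", "corrected_psa_snps", "corrected_both"):
                if name not in score_sets:
                    continue
                entry[name] = _auc_entry(
                    auc(score_sets[name][mask], y[mask], ci_level=config.ci_level))
        else:
            entry["flag"] = "extreme-grade contrast empty"
        sensitivity["extreme_grades"] = entry

    if config.run_t3t4_inclusion and not config.include_t3t4:
        t3t4 = filter_eligible(raw, psa_window=config.psa_window,
                               require_panel=[s for s in all_snps if s in raw.data.columns],
                               include_t3t4=True)
        dft = pd.concat([t3t4.data,
                         score_table(t3t4.data, p4, mode=config.correction_mode)], axis=1)
        yt = (dft["risk_group"] == "high").to_numpy()
        sets_t = _score_sets(dft, p4, p10, config.correction_mode)
        entry = {"n": len(dft), "n_high": int(yt.sum())}
        if yt.any() and not yt.all():
            for name in ("measured_psa", "corrected_psa_snps"):
                entry[name] = _auc_entry(auc(sets_t[name], yt, ci_level=config.ci_level))
        sensitivity["t3t4_inclusion"] = entry
    log.append({"op": "sensitivity_analyses", "blocks": sorted(sensitivity)})

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _config_json(config),
        "panels": {"psa": p4.name, "aggressive": p10.name},
        "cohort_provenance": table.provenance,
        "prior_odds_source": ("configured" if config.prior_odds is not None
                              else "cohort prevalence odds (n_high/n_low)"),
    }
    return AnalysisReport(cohort_summary, hwe, psa_assoc, risk_assoc,
                          allele_tbl, allele_summary, auc_block, lr_block,
                          internal, sensitivity, provenance, log)


def table_with(df: pd.DataFrame, template: CohortTable) -> CohortTable:
    """Wrap a derived frame in a CohortTable sharing the template's metadata."""
    return CohortTable(df, panel_ids=list(template.panel_ids),
                       provenance=template.provenance)


def _config_json(config: AnalysisConfig) -> dict:
    d: dict = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, Panel):
            v = v.name
        elif isinstance(v, SimulationConfig):
            v = dataclasses.asdict(v)
            v["selection_window"] = list(v["selection_window"])
            v["age_range"] = list(v["age_range"])
        elif isinstance(v, tuple):
            v = list(v)
        d[f.name] = v
    return d


def write_report(report: AnalysisReport, outdir) -> Path:
    """Write the report: TSV tables plus a summary JSON (sorted keys, repr
    floats) so that identical runs produce byte-identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.hwe.to_csv(outdir / "hwe.tsv", sep="\t", index=False)
    report.psa_associations.to_csv(outdir / "psa_associations.tsv", sep="\t", index=False)
    report.risk_associations.to_csv(outdir / "risk_associations.tsv", sep="\t", index=False)
    report.allele_counts.to_csv(outdir / "allele_counts.tsv", sep="\t", index=False)
    summary = {
        "cohort_summary": report.cohort_summary,
        "allele_count_summary": report.allele_count_summary,
        "auc_block": report.auc_block,
        "lr_block": report.lr_block,
        "internal_models": report.internal_models,
        "sensitivity": report.sensitivity,
        "provenance": report.provenance,
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_jsonify) + "\n")
    (outdir / "run_log.jsonl").write_text(
        "\n".join(json.dumps(e, sort_keys=True, default=_jsonify) for e in report.run_log) + "\n")
    return outdir


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if obj is None or obj != obj:   # NaN
        return None
    raise TypeError(f"not JSON serialisable: {type(obj)}")
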