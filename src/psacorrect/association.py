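"""Per-SNP association stages: linear PSA regressions, variance explained,
case-control logistic regressions, Hardy-Weinberg checks, and the
internal-coefficient logistic models.

Conventions (matching the published analysis): PSA is regressed on dosage in
ng/mL (additive coding) adjusting for age, study centre (fixed-effect
indicators) and principal-component covariates; odds ratios for high- vs
low-risk disease come from maximum-likelihood logistic fits with Wald 95%
confidence intervals; per-SNP p-values are reported raw (no multiplicity
correction); R^2 and F for variance explained come from the unadjusted
single-predictor regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CohortTable
from .exceptions import ConfigError, DataError, SeparationError
from .scores import Panel, _exponents_vector

__all__ = [
    "AssociationResult",
    "HWEResult",
    "hwe_test",
    "hwe_test_from_dosages",
    "per_snp_linear",
    "unadjusted_variance_explained",
    "per_snp_logistic",
    "fit_internal_model",
    "covariate_balance_check",
    "select_stratum",
    "STRATA",
]

STRATA = ("all", "low_risk", "high_risk", "age<65", "age>=65")


@dataclass
class AssociationResult:
    rsid: str
    outcome: str                  # "psa_level" or "risk_group"
    stratum: str
    n: int
    effect: float                 # beta (ng/mL per allele) or odds ratio
    ci_low: float
    ci_high: float
    p_value: float
    covariates: list[str] = field(default_factory=list)
    r_squared: float | None = None
    f_statistic: float | None = None
    flag: str | None = None


@dataclass
class HWEResult:
    counts: tuple[int, int, int]   # (n0, n1, n2) by effect-allele dosage
    statistic: float | None
    p_value: float | None
    monomorphic: bool
    method: str
    rsid: str | None = None


def hwe_test(n0: int, n1: int, n2: int, method: str = "chisq",
             rsid: str | None = None) -> HWEResult:
    """Test genotype counts for departure from Hardy-Weinberg proportions.

    ``chisq`` (default): 1-df goodness of fit against p^2 : 2pq : q^2 with
    the allele frequency estimated from the counts.  ``exact``: conditional
    exact test summing heterozygote-count probabilities no larger than the
    observed one — preferable for small or sparse counts.

    A monomorphic SNP (no heterozygotes and only one homozygote class) has
    no defined test and is flagged instead.
    """
    counts = (int(n0), int(n1), int(n2))
    if any(c < 0 for c in counts):
        raise ConfigError(f"genotype counts must be non-negative: {counts}")
    n = sum(counts)
    if n == 0:
        raise ConfigError("total genotype count must be positive")
    if counts[1] == 0 and (counts[0] == 0 or counts[2] == 0):
        return HWEResult(counts, None, None, True, method, rsid)

    if method == "chisq":
        p = (counts[1] + 2 * counts[2]) / (2 * n)
        expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2]) * n
        observed = np.array(counts, dtype=float)
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        pval = float(stats.chi2.sf(chi2, df=1))
        return HWEResult(counts, chi2, pval, False, "chisq", rsid)
    if method == "exact":
        return HWEResult(counts, None, _hwe_exact_p(*counts), False, "exact", rsid)
    raise ConfigError(f"unknown HWE method {method!r}")


def _hwe_exact_p(n0: int, n1: int, n2: int) -> float:
    """Conditional exact HWE p-value: sum of probabilities of heterozygote
    counts (given allele counts) no more probable than the observed one."""
    n = n0 + n1 + n2
    rare = min(2 * n0 + n1, 2 * n2 + n1)
    # log P(het = h | allele counts) up to a constant, h stepping by 2
    hs = np.arange(rare % 2, rare + 1, 2)
    logp = []
    for h in hs:
        r_hom = (rare - h) // 2
        c_hom = n - h - r_hom
        lp = (h * math.log(2)
              + math.lgamma(n + 1)
              - math.lgamma(h + 1) - math.lgamma(r_hom + 1) - math.lgamma(c_hom + 1))
        logp.append(lp)
    logp = np.array(logp)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hs == n1][0]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def hwe_test_from_dosages(dosages, method: str = "chisq",
                          rsid: str | None = None) -> HWEResult:
    d = pd.Series(dosages).dropna().astype(int)
    return hwe_test((d == 0).sum(), (d == 1).sum(), (d == 2).sum(),
                    method=method, rsid=rsid)


# ---------------------------------------------------------------------------
# Design-matrix helpers


def select_stratum(table: CohortTable, stratum: str = "all") -> pd.DataFrame:
    df = table.data
    if stratum == "all":
        return df
    if stratum == "low_risk":
        return df[df["risk_group"] == "low"]
    if stratum == "high_risk":
        return df[df["risk_group"] == "high"]
    if stratum == "age<65":
        return df[df["age"] < 65]
    if stratum == "age>=65":
        return df[df["age"] >= 65]
    raise ConfigError(f"unknown stratum {stratum!r}; expected one of {STRATA}")


def _covariate_matrix(df: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str]]:
    """Expand covariate names into numeric columns; 'centre' becomes
    fixed-effect indicator variables (first level dropped)."""
    cols, names = [], []
    for cov in covariates:
        if cov == "centre":
            dummies = pd.get_dummies(df["centre"], prefix="centre", drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(c)
        else:
            if cov not in df.columns:
                raise ConfigError(f"covariate column {cov!r} not in table")
            cols.append(df[cov].to_numpy(dtype=float))
            names.append(cov)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


def _wald_ci(est: float, se: float, level: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2)
    return est - z * se, est + z * se


def per_snp_linear(table: CohortTable, rsid: str, covariates=(), stratum: str = "all",
                   ci_level: float = 0.95) -> AssociationResult:
    """OLS of PSA (ng/mL) on additive dosage plus covariates; per-allele beta."""
    df = select_stratum(table, stratum).dropna(subset=[rsid, "psa"])
    if len(df) == 0:
        raise DataError(f"stratum {stratum!r} empty for {rsid}")
    dosage = df[rsid].to_numpy(dtype=float)
    if np.ptp(dosage) == 0:
        return AssociationResult(rsid, "psa_level", stratum, len(df),
                                 math.nan, math.nan, math.nan, math.nan,
                                 list(covariates), flag="constant_dosage")
    Xc, names = _covariate_matrix(df, covariates)
    X = sm.add_constant(np.column_stack([dosage, Xc]))
    fit = sm.OLS(df["psa"].to_numpy(dtype=float), X).fit()
    beta, se = fit.params[1], fit.bse[1]
    lo, hi = _wald_ci(beta, se, ci_level)
    return AssociationResult(rsid, "psa_level", stratum, int(fit.nobs),
                             float(beta), float(lo), float(hi),
                             float(fit.pvalues[1]), names)


def unadjusted_variance_explained(table: CohortTable, rsid: str,
                                  stratum: str = "all") -> tuple[float, float]:
    """(R^2, F) from the unadjusted single-predictor regression of PSA on dosage."""
    df = select_stratum(table, stratum).dropna(subset=[rsid, "psa"])
    if len(df) == 0:
        raise DataError(f"stratum {stratum!r} empty for {rsid}")
    dosage = df[rsid].to_numpy(dtype=float)
    y = df["psa"].to_numpy(dtype=float)
    if np.ptp(dosage) == 0 or np.ptp(y) == 0:
        return 0.0, 0.0
    fit = sm.OLS(y, sm.add_constant(dosage)).fit()
    return float(fit.rsquared), float(fit.fvalue)


def _check_separation(fit, threshold: float = 15.0) -> None:
    if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > threshold):
        raise SeparationError(
            "logistic fit shows signs of (quasi-)complete separation; "
            "coefficients or standard errors diverged"
        )


def _logit_fit(y: np.ndarray, X: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            fit = model.fit(disp=0, maxiter=200)
        except Exception as err:  # PerfectSeparationError and numerical failures
            raise SeparationError(f"logistic fit failed: {err}") from err
    _check_separation(fit)
    return fit


def per_snp_logistic(table: CohortTable, rsid: str, covariates=(),
                     coding: str = "additive", ci_level: float = 0.95) -> AssociationResult:
    """ML logistic regression of high- vs low-risk on the coded genotype.

    ``coding`` is a genetic-model contrast (additive dosage by default;
    dominant/recessive indicator codings for grouped-genotype ORs).  The
    effect is reported as an odds ratio with a Wald CI.
    """
    df = table.data.dropna(subset=[rsid])
    df = df[df["risk_group"].isin(["low", "high"])]
    y = (df["risk_group"] == "high").to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise DataError("both outcome classes must be present")
    from .scores import SNPDefinition
    snp = SNPDefinition(rsid, "X", "O", 1.0, coding)
    x = _exponents_vector(df[rsid].to_numpy(), snp, df["subject_id"].to_numpy()).astype(float)
    if np.ptp(x) == 0:
        return AssociationResult(rsid, "risk_group", "all", len(df),
                                 math.nan, math.nan, math.nan, math.nan,
                                 list(covariates), flag="constant_dosage")
    Xc, names = _covariate_matrix(df, covariates)
    X = sm.add_constant(np.column_stack([x, Xc]))
    fit = _logit_fit(y, X)
    beta, se = fit.params[1], fit.bse[1]
    lo, hi = _wald_ci(beta, se, ci_level)
    return AssociationResult(rsid, "risk_group", "all", int(fit.nobs),
                             float(np.exp(beta)), float(np.exp(lo)), float(np.exp(hi)),
                             float(fit.pvalues[1]), names)


@dataclass
class InternalModelResult:
    """A fitted internal-coefficient logistic model and its in-sample AUC."""

    name: str
    predictors: list[str]
    params: dict[str, float]
    n: int
    auc: "object"                  # AUCResult from the discrimination module
    linear_predictor: np.ndarray

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "predictors": self.predictors,
            "params": self.params,
            "n": self.n,
            "auc": self.auc.auc,
            "auc_ci": [self.auc.ci_low, self.auc.ci_high],
        }


def fit_internal_model(table: CohortTable, *, include_psa: bool = True,
                       psa_snps: Panel | None = None,
                       aggressive_snps: Panel | None = None,
                       covariates=(), name: str = "model",
                       ci_level: float = 0.95) -> InternalModelResult:
    """Fit a logistic model of high/low risk on internally estimated
    coefficients and score its in-sample discrimination.

    The predictor set mirrors the internal-coefficient sensitivity analysis:
    measured PSA alone; plus PSA-SNP dosages; plus aggressive-SNP dosages;
    or all three.  The AUC is computed on the fitted linear predictor.
    """
    from .discrimination import auc as _auc

    cols: list[str] = []
    if psa_snps is not None:
        cols += psa_snps.rsids
    if aggressive_snps is not None:
        cols += aggressive_snps.rsids
    df = table.data.dropna(subset=cols) if cols else table.data
    df = df[df["risk_group"].isin(["low", "high"])]
    y = (df["risk_group"] == "high").to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise DataError("both outcome classes must be present")

    pieces, names = [], []
    if include_psa:
        pieces.append(df["psa"].to_numpy(dtype=float))
        names.append("psa")
    for c in cols:
        pieces.append(df[c].to_numpy(dtype=float))
        names.append(c)
    Xc, cov_names = _covariate_matrix(df, covariates)
    X = sm.add_constant(np.column_stack(pieces + ([Xc] if Xc.size else [])))
    fit = _logit_fit(y, X)
    lin = X @ fit.params
    params = dict(zip(["const"] + names + cov_names, map(float, fit.params)))
    return InternalModelResult(name, names, params, int(fit.nobs),
                               _auc(lin, y.astype(bool), ci_level=ci_level), lin)


def covariate_balance_check(table: CohortTable, value_column: str,
                            pcs=None) -> pd.DataFrame:
    """Regress each principal-component covariate on a dosage/score column;
    returns per-PC slope and p-value (a screen for population-stratification
    confounding).  Constant PCs are flagged with no estimate."""
    df = table.data.dropna(subset=[value_column])
    if pcs is None:
        pcs = [c for c in df.columns if c.startswith("PC")]
    x = df[value_column].to_numpy(dtype=float)
    rows = []
    for pc in pcs:
        y = df[pc].to_numpy(dtype=float)
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            rows.append({"pc": pc, "beta": math.nan, "p_value": math.nan,
                         "flag": "constant"})
            continue
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        rows.append({"pc": pc, "beta": float(fit.params[1]),
                     "p_value": float(fit.pvalues[1]), "flag": None})
    return pd.DataFrame(rows)
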