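"""Screening-performance calculus: empirical ROC curves, AUC with DeLong
variance, paired AUC comparison, fixed-sensitivity operating points,
likelihood ratios and posterior odds.

Conventions, pinned by tests:

* Higher score means more likely high-risk.  Negatively oriented scores are
  reported as-is (AUC < 0.5) with a warning, never auto-flipped.
* Tied scores are grouped at a single operating point, which makes the
  trapezoidal AUC equal to the Mann-Whitney statistic
  P(score_pos > score_neg) + 1/2 P(tie).
* The fixed-sensitivity operating point uses the empirical step function:
  the largest threshold whose achieved sensitivity still meets the target
  (so the achieved sensitivity sits just above the target, e.g. 90.2% for a
  90% target); linear interpolation is opt-in.
* AUC variance and the paired two-sided test use DeLong's nonparametric
  estimator; a paired-bootstrap alternative is provided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from .exceptions import ConfigError, DataError

__all__ = [
    "ROCCurve",
    "AUCResult",
    "LRResult",
    "PairedAUCComparison",
    "roc_curve",
    "auc",
    "compare_auc_paired",
    "spec_at_sensitivity",
    "likelihood_ratio",
    "posterior_odds",
    "with_prior_odds",
]


@dataclass
class ROCCurve:
    """Empirical operating characteristic.

    Thresholds are descending, starting at +inf (sens 0, spec 1) and ending
    at the minimum score (sens 1, spec 0); a subject is test-positive when
    score >= threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int
    tie_convention: str = "grouped"


@dataclass
class AUCResult:
    auc: float
    variance: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_pos: int
    n_neg: int


@dataclass
class LRResult:
    """An operating point with its diagnostic likelihood ratio.

    The invariant likelihood_ratio == achieved_sensitivity / (1 -
    specificity) holds bit-exactly; an infinite LR (specificity 1) is
    represented as IEEE +inf.
    """

    target_sensitivity: float
    achieved_sensitivity: float
    specificity: float
    threshold: float
    likelihood_ratio: float
    prior_odds: float | None = None
    posterior_odds: float | None = None


@dataclass
class PairedAUCComparison:
    auc_a: float
    auc_b: float
    difference: float
    variance: float
    p_value: float
    method: str


def _validate(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype != bool:
        y = y.astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ConfigError("scores and labels must be 1-d arrays of equal length")
    if np.any(~np.isfinite(s)):
        raise DataError("scores must be finite")
    if y.all() or not y.any():
        raise DataError("both classes must be present")
    return s, y


def roc_curve(scores, labels) -> ROCCurve:
    """Empirical ROC over all distinct score thresholds (ties grouped)."""
    s, y = _validate(scores, labels)
    pos = np.sort(s[y])
    neg = np.sort(s[~y])
    uniq = np.unique(s)
    thresholds = np.concatenate(([np.inf], uniq[::-1]))
    # sens(t) = P(pos >= t), spec(t) = P(neg < t)
    sens = 1.0 - np.searchsorted(pos, thresholds, side="left") / len(pos)
    spec = np.searchsorted(neg, thresholds, side="left") / len(neg)
    return ROCCurve(thresholds, sens, spec, int(y.sum()), int((~y).sum()))


def _delong_components(s: np.ndarray, y: np.ndarray):
    """AUC and DeLong structural components via midranks (O(n log n))."""
    pos, neg = s[y], s[~y]
    m, n = len(pos), len(neg)
    tx = rankdata(s)                   # midranks in the pooled sample
    tp = rankdata(pos)                 # midranks within positives
    tn = rankdata(neg)                 # midranks within negatives
    v10 = (tx[y] - tp) / n             # per-positive placement values
    v01 = 1.0 - (tx[~y] - tn) / m      # per-negative placement values
    return float(v10.mean()), v10, v01


def _var(v: np.ndarray) -> float:
    return float(np.var(v, ddof=1)) if len(v) > 1 else 0.0


def auc(scores, labels, ci_level: float = 0.95) -> AUCResult:
    """Trapezoidal AUC (= Mann-Whitney statistic with ties counted half)
    with DeLong variance and a normal-approximation CI truncated to [0,1]."""
    s, y = _validate(scores, labels)
    a, v10, v01 = _delong_components(s, y)
    var = _var(v10) / len(v10) + _var(v01) / len(v01)
    if a < 0.5:
        warnings.warn(
            f"AUC {a:.3f} < 0.5: the score appears negatively oriented; "
            "it is reported as-is", stacklevel=2)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    half = z * math.sqrt(var)
    return AUCResult(a, var, max(0.0, a - half), min(1.0, a + half),
                     ci_level, int(y.sum()), int((~y).sum()))


def compare_auc_paired(scores_a, scores_b, labels, method: str = "delong",
                       n_boot: int = 2000, seed: int | None = None) -> PairedAUCComparison:
    """Two-sided test of AUC_a == AUC_b on the same subjects.

    ``delong`` (default): the correlated-curve DeLong test.  ``bootstrap``:
    paired resampling of subjects; the p-value uses the normal approximation
    with the bootstrap standard error of the difference.
    """
    sa, y = _validate(scores_a, labels)
    sb, y2 = _validate(scores_b, labels)
    if not np.array_equal(y, y2):
        raise ConfigError("labels must be identical for a paired comparison")

    aa, v10a, v01a = _delong_components(sa, y)
    ab, v10b, v01b = _delong_components(sb, y)
    diff = aa - ab

    if method == "delong":
        m, n = len(v10a), len(v01a)
        var = (_var(v10a) + _var(v10b) - 2 * _cov(v10a, v10b)) / m \
            + (_var(v01a) + _var(v01b) - 2 * _cov(v01a, v01b)) / n
        var = max(var, 0.0)
        if var == 0.0:
            p = 1.0 if diff == 0.0 else 0.0
        else:
            z = diff / math.sqrt(var)
            p = float(2 * stats.norm.sf(abs(z)))
        return PairedAUCComparison(aa, ab, diff, var, p, "delong")

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx_all = np.arange(len(y))
        diffs = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.choice(idx_all, size=len(y), replace=True)
            yb = y[idx]
            if yb.all() or not yb.any():
                diffs[b] = np.nan
                continue
            diffs[b] = _fast_auc(sa[idx], yb) - _fast_auc(sb[idx], yb)
        diffs = diffs[~np.isnan(diffs)]
        sd = diffs.std(ddof=1)
        if sd == 0.0:
            p = 1.0 if diff == 0.0 else 0.0
        else:
            p = float(2 * stats.norm.sf(abs(diff) / sd))
        return PairedAUCComparison(aa, ab, diff, float(sd ** 2), p, "bootstrap")

    raise ConfigError(f"unknown method {method!r}")


def _cov(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.cov(a, b, ddof=1)[0, 1]) if len(a) > 1 else 0.0


def _fast_auc(s: np.ndarray, y: np.ndarray) -> float:
    r = rankdata(s)
    m = int(y.sum())
    n = len(y) - m
    return (r[y].sum() - m * (m + 1) / 2) / (m * n)


def spec_at_sensitivity(curve: ROCCurve, target: float,
                        interpolate: bool = False) -> LRResult:
    """Operating point at a fixed target sensitivity.

    Step convention (default): the largest threshold whose achieved
    sensitivity is >= target — i.e. the smallest achieved sensitivity at or
    above the target, which maximises specificity subject to the sensitivity
    constraint.  With ``interpolate=True`` the specificity and threshold are
    linearly interpolated to hit the target exactly.
    """
    if not 0.0 < target < 1.0:
        raise ConfigError(f"target sensitivity must be in (0,1): {target}")
    sens, spec, thr = curve.sensitivity, curve.specificity, curve.thresholds
    ok = np.nonzero(sens >= target)[0]
    if len(ok) == 0:
        raise DataError(f"target sensitivity {target} not reachable")
    i = ok[0]                       # thresholds descend; first hit = largest
    if interpolate and sens[i] > target and i > 0:
        f = (target - sens[i - 1]) / (sens[i] - sens[i - 1])
        sp = spec[i - 1] + f * (spec[i] - spec[i - 1])
        th = thr[i - 1] + f * (thr[i] - thr[i - 1]) if np.isfinite(thr[i - 1]) else thr[i]
        return LRResult(target, target, float(sp), float(th),
                        likelihood_ratio(target, float(sp)))
    return LRResult(target, float(sens[i]), float(spec[i]), float(thr[i]),
                    likelihood_ratio(float(sens[i]), float(spec[i])))


def likelihood_ratio(sensitivity: float, specificity: float) -> float:
    """Positive diagnostic likelihood ratio, sensitivity / (1 - specificity).

    A specificity of exactly 1 yields IEEE +inf (flagging an infinite LR)
    rather than raising or returning NaN.
    """
    if not 0.0 <= sensitivity <= 1.0 or not 0.0 <= specificity <= 1.0:
        raise ConfigError("sensitivity and specificity must lie in [0,1]")
    if specificity == 1.0:
        return math.inf
    return sensitivity / (1.0 - specificity)


def posterior_odds(prior_odds: float, lr: float) -> float:
    """Posterior odds of high-risk disease: prior odds times likelihood ratio."""
    if prior_odds <= 0 or lr <= 0:
        raise ConfigError("prior odds and likelihood ratio must be positive")
    return prior_odds * lr


def with_prior_odds(result: LRResult, prior_odds: float) -> LRResult:
    """Attach prior and posterior odds to an operating point."""
    return LRResult(result.target_sensitivity, result.achieved_sensitivity,
                    result.specificity, result.threshold, result.likelihood_ratio,
                    prior_odds, posterior_odds(prior_odds, result.likelihood_ratio))
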