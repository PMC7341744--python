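"""Rural-urban inequality metrics: weighted prevalence, risk differences,
odds-ratio homogeneity tests and random-effects pooling.

The inequality measure is the risk difference (RD), rural minus urban SAM
prevalence scaled per 1,000 children.  RD > 0 with a confidence interval
excluding zero is "pro-rural" inequality (rural children worse off),
RD < 0 with CI below zero is "pro-urban", anything else is classified as
no significant inequality.

Survey weights enter through weighted prevalences and Kish effective
sample sizes; country RDs are pooled with a DerSimonian-Laird
random-effects model, the analogue of a forest plot's diamond.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GroupPrevalence",
    "RiskDifferenceResult",
    "HomogeneityTestResult",
    "MetaAnalysisResult",
    "weighted_prevalence",
    "risk_difference",
    "classify_inequality",
    "mh_homogeneity_test",
    "pool_random_effects",
]

logger = logging.getLogger(__name__)

PRO_RURAL = "pro-rural"
PRO_URBAN = "pro-urban"
NO_INEQUALITY = "none"


@dataclass(frozen=True)
class GroupPrevalence:
    """Weighted prevalence for one residence group.

    ``kish_deff`` is the design effect n * sum(w^2) / (sum w)^2 induced by
    unequal weights; ``weighted_n`` is the Kish effective sample size
    raw_n / deff used for variance calculations.
    """

    group: str
    raw_n: int
    weighted_n: float
    prevalence: float
    kish_deff: float


@dataclass(frozen=True)
class RiskDifferenceResult:
    rd_per_1000: float
    ci_low: float
    ci_high: float
    variance: float  # on the proportion scale
    classification: str
    alpha: float
    p_value: float


@dataclass(frozen=True)
class HomogeneityTestResult:
    statistic: float
    df: int
    p_value: float
    common_or: float


@dataclass(frozen=True)
class MetaAnalysisResult:
    pooled_rd_per_1000: float
    ci_low: float
    ci_high: float
    tau2: float
    q_statistic: float
    study_weights: dict = field(default_factory=dict)  # label -> percent


def weighted_prevalence(outcomes, weights, group: str = "all") -> GroupPrevalence:
    """Survey-weighted prevalence with Kish effective sample size."""
    y = np.asarray(outcomes, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.size == 0:
        raise ValueError("empty outcome vector")
    if y.shape != w.shape:
        raise ValueError("outcomes and weights must have the same length")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    sw = w.sum()
    prevalence = float((w * y).sum() / sw)
    deff = float(y.size * (w**2).sum() / sw**2)
    return GroupPrevalence(
        group=group,
        raw_n=int(y.size),
        weighted_n=float(y.size / deff),
        prevalence=prevalence,
        kish_deff=deff,
    )


def _classify(rd_per_1000: float, ci_low: float, ci_high: float) -> str:
    if ci_low > 0:
        return PRO_RURAL
    if ci_high < 0:
        return PRO_URBAN
    return NO_INEQUALITY


def risk_difference(
    rural: GroupPrevalence, urban: GroupPrevalence, alpha: float = 0.05
) -> RiskDifferenceResult:
    """Rural-minus-urban risk difference per 1,000 with a Wald CI.

    The variance uses each group's Kish effective sample size:
    p(1-p)/n_eff summed over groups.
    """
    if rural.weighted_n <= 0 or urban.weighted_n <= 0:
        raise ValueError("both groups need positive effective sample size")
    diff = rural.prevalence - urban.prevalence
    var = (
        rural.prevalence * (1 - rural.prevalence) / rural.weighted_n
        + urban.prevalence * (1 - urban.prevalence) / urban.weighted_n
    )
    se = np.sqrt(var)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    lo, hi = (diff - zcrit * se) * 1000, (diff + zcrit * se) * 1000
    rd = diff * 1000
    if se > 0:
        p = 2 * stats.norm.sf(abs(diff) / se)
    else:
        p = 1.0 if diff == 0 else 0.0
    return RiskDifferenceResult(
        rd_per_1000=float(rd),
        ci_low=float(lo),
        ci_high=float(hi),
        variance=float(var),
        classification=_classify(rd, lo, hi),
        alpha=alpha,
        p_value=float(p),
    )


def classify_inequality(rd: RiskDifferenceResult) -> str:
    """Pro-rural / pro-urban / none, from the CI's position relative to 0."""
    return _classify(rd.rd_per_1000, rd.ci_low, rd.ci_high)


def mh_homogeneity_test(strata) -> HomogeneityTestResult:
    """Homogeneity of the odds ratio across 2x2 strata.

    Computes the Mantel-Haenszel common odds ratio and the Breslow-Day
    statistic with Tarone's correction against it (the standard test of OR
    homogeneity in a stratified analysis).  Strata containing a zero cell
    get 0.5 added to every cell (logged continuity correction).
    """
    from statsmodels.stats.contingency_tables import StratifiedTable

    tables = [np.asarray(t, dtype=float) for t in strata]
    if len(tables) < 2:
        raise ValueError("homogeneity test needs at least 2 strata")
    fixed = []
    n_corrected = 0
    for t in tables:
        if t.shape != (2, 2):
            raise ValueError("each stratum must be a 2x2 table")
        if np.any(t == 0):
            t = t + 0.5
            n_corrected += 1
        fixed.append(t)
    if n_corrected:
        logger.warning("mh_homogeneity_test: continuity-corrected %d strata with zero cells", n_corrected)
    st = StratifiedTable(np.stack(fixed, axis=-1))
    res = st.test_equal_odds(adjust=True)
    return HomogeneityTestResult(
        statistic=float(res.statistic),
        df=len(fixed) - 1,
        p_value=float(res.pvalue),
        common_or=float(st.oddsratio_pooled),
    )


def pool_random_effects(studies) -> MetaAnalysisResult:
    """DerSimonian-Laird random-effects pooling of per-country RDs.

    ``studies`` is an iterable of (label, rd_per_1000, variance) with the
    variance on the same per-1,000 squared scale.  The between-study
    variance is the DL moment estimator tau^2 = max(0, (Q - df)/C) with
    C = sum(w) - sum(w^2)/sum(w) on fixed-effect weights w = 1/v; the
    pooled estimate uses weights 1/(v + tau^2) and a Wald 95% CI.
    """
    studies = list(studies)
    if not studies:
        raise ValueError("no studies to pool")
    labels = [s[0] for s in studies]
    est = np.array([s[1] for s in studies], dtype=float)
    var = np.array([s[2] for s in studies], dtype=float)
    if np.any(var <= 0):
        raise ValueError("study variances must be positive")
    w = 1.0 / var
    theta_fe = (w * est).sum() / w.sum()
    q = float((w * (est - theta_fe) ** 2).sum())
    df = len(studies) - 1
    if df == 0:
        tau2 = 0.0
    else:
        c = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - df) / c)
    w_re = 1.0 / (var + tau2)
    pooled = float((w_re * est).sum() / w_re.sum())
    pooled_var = 1.0 / w_re.sum()
    half = 1.959963984540054 * np.sqrt(pooled_var)
    pct = 100.0 * w_re / w_re.sum()
    return MetaAnalysisResult(
        pooled_rd_per_1000=pooled,
        ci_low=float(pooled - half),
        ci_high=float(pooled + half),
        tau2=float(tau2),
        q_statistic=q,
        study_weights=dict(zip(labels, pct)),
    )
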