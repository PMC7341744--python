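"""Non-linear two-fold Blinder-Oaxaca decomposition of the rural-urban gap
in SAM probability.

For a binary outcome the group mean is a non-linear function of the
covariates, E[y | group g] = mean_i F(x_i' beta_g) with F the logistic CDF,
so the classic linear decomposition is generalised to

    gap        = wmean_R F(X_R beta_R) - wmean_U F(X_U beta_U)
    explained  = wmean_R F(X_R beta*)  - wmean_U F(X_U beta*)
    unexplained = gap - explained

where beta* is a reference coefficient vector (default: a pooled model
over both groups including a group indicator, the indicator's effect being
assigned to the unexplained part).  The explained ("compositional") part
reflects differences in covariate distributions; the unexplained
("structural") part reflects differences in coefficients.

Per-covariate detailed contributions use Yun's linear-index weights

    W_k = (xbar_Rk - xbar_Uk) beta*_k / sum_j (xbar_Rj - xbar_Uj) beta*_j

applied to the explained component (deterministic and additive), with the
randomised Fairlie sequential-substitution method available as an
alternative.  Inference is by cluster (PSU) bootstrap.

Sign convention: gap = rural - urban, so positive components widen
pro-rural inequality, matching the risk-difference convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ModelSpec",
    "DesignData",
    "LogitFit",
    "DecompositionResult",
    "BootstrapResult",
    "SeparationError",
    "ConvergenceError",
    "ZeroLinearGapError",
    "build_design",
    "fit_weighted_logit",
    "decompose_two_fold",
    "yun_detailed",
    "fairlie_detailed",
    "bootstrap_components",
    "percent_contributions",
]

logger = logging.getLogger(__name__)

MAX_ITER = 100
LOGLIK_RTOL = 1e-10
_SEPARATION_COEF_NORM = 1e4


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation: coefficients diverge."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


class ZeroLinearGapError(ZeroDivisionError):
    """The linear-index gap sum is zero; Yun weights are undefined."""


@dataclass(frozen=True)
class ModelSpec:
    """Covariate, group, weight and cluster specification for decomposition.

    ``covariates`` maps each term name to ``"continuous"`` or
    ``"categorical"``.  Categorical terms are expanded to deviation-contrast
    (sum-to-zero) columns by default (``normalize=True``) so detailed
    contributions do not depend on the arbitrary base category; set
    ``normalize=False`` for conventional drop-first dummies.
    """

    outcome: str
    covariates: Mapping[str, str]
    group: str = "residence"
    group_levels: tuple[str, str] = ("rural", "urban")
    weight: str = "weight"
    cluster: str = "cluster_id"
    normalize: bool = True

    def __post_init__(self):
        for name, kind in self.covariates.items():
            if kind not in ("continuous", "categorical"):
                raise ValueError(f"covariate {name!r}: kind must be continuous or categorical")
        if len(self.group_levels) != 2:
            raise ValueError("group variable must have exactly 2 levels (rural, urban)")


@dataclass
class DesignData:
    """Per-group design matrices with a shared column layout.

    Column 0 is the intercept; ``terms`` maps each covariate name to its
    column indices.  Built once and reused by the bootstrap.
    """

    X_rural: np.ndarray
    y_rural: np.ndarray
    w_rural: np.ndarray
    clusters_rural: np.ndarray
    X_urban: np.ndarray
    y_urban: np.ndarray
    w_urban: np.ndarray
    clusters_urban: np.ndarray
    columns: list[str]
    terms: dict[str, list[int]]
    n_excluded: int


@dataclass(frozen=True)
class LogitFit:
    params: np.ndarray
    vcov: np.ndarray
    names: list[str]
    n: int
    converged: bool
    loglik: float
    link: str = "logit"

    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))


@dataclass
class DecompositionResult:
    gap: float
    explained: float
    unexplained: float
    detailed: dict  # covariate -> {"contribution": x, "percent_of_gap": p}
    reference: str
    fits: dict = field(default_factory=dict)
    n_excluded: int = 0
    ci: dict | None = None


@dataclass
class BootstrapResult:
    intervals: dict  # component -> (lo, hi)
    n_replicates: int
    n_failed: int
    level: float

    @property
    def failure_rate(self) -> float:
        return self.n_failed / (self.n_replicates + self.n_failed)


# ---------------------------------------------------------------------------
# design construction


def build_design(records: pd.DataFrame, spec: ModelSpec) -> DesignData:
    """Dummy- or deviation-coded design matrices, one per residence group.

    Complete cases only: rows with a missing outcome, weight, group or
    covariate value are dropped and counted in ``n_excluded``.  A
    categorical level observed in only one group makes the counterfactual
    evaluation ill-posed and raises a ``ValueError`` naming the level.
    """
    needed = [spec.outcome, spec.group, spec.weight, spec.cluster, *spec.covariates]
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise KeyError(f"records missing columns: {missing}")
    sub = records.loc[:, needed]
    complete = sub.dropna()
    n_excluded = len(sub) - len(complete)
    if n_excluded:
        logger.info("build_design: excluded %d incomplete rows", n_excluded)

    rural_level, urban_level = spec.group_levels
    grp = complete[spec.group]
    bad = ~grp.isin([rural_level, urban_level])
    if bad.any():
        raise ValueError(f"unexpected group levels: {sorted(grp[bad].unique())}")
    is_rural = (grp == rural_level).to_numpy()
    if not is_rural.any() or is_rural.all():
        raise ValueError("both residence groups must be non-empty after filtering")

    columns = ["intercept"]
    terms: dict[str, list[int]] = {}
    blocks = [np.ones((len(complete), 1))]
    for name, kind in spec.covariates.items():
        col = complete[name]
        if kind == "continuous":
            terms[name] = [len(columns)]
            columns.append(name)
            blocks.append(col.to_numpy(float)[:, None])
            continue
        levels = sorted(col.unique(), key=str)
        if len(levels) < 2:
            raise ValueError(f"categorical {name!r} has a single level")
        for g_name, g_mask in (("rural", is_rural), ("urban", ~is_rural)):
            present = set(col[g_mask].unique())
            only = [lv for lv in levels if lv not in present]
            if only:
                raise ValueError(
                    f"categorical {name!r}: level(s) {only} absent from the {g_name} group"
                )
        base, rest = levels[0], levels[1:]
        idx = []
        for lv in rest:
            vec = (col == lv).to_numpy(float)
            if spec.normalize:
                vec = vec - (col == base).to_numpy(float)  # deviation contrast
            idx.append(len(columns))
            columns.append(f"{name}[{lv}]")
            blocks.append(vec[:, None])
        terms[name] = idx
    X = np.hstack(blocks)
    y = complete[spec.outcome].to_numpy(float)
    w = complete[spec.weight].to_numpy(float)
    if np.any(w <= 0):
        raise ValueError("sampling weights must be strictly positive")
    clusters = complete[spec.cluster].to_numpy()
    r, u = is_rural, ~is_rural
    return DesignData(
        X_rural=X[r], y_rural=y[r], w_rural=w[r], clusters_rural=clusters[r],
        X_urban=X[u], y_urban=y[u], w_urban=w[u], clusters_urban=clusters[u],
        columns=columns, terms=terms, n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# weighted logit (pseudo-likelihood IRLS) with cluster-robust sandwich


def _irls_logit(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Newton/IRLS solve of the weighted logistic pseudo-likelihood.

    Returns (beta, final Hessian XtWX, loglik).  Raises SeparationError or
    ConvergenceError.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll_prev = -np.inf
    H = None
    for _ in range(MAX_ITER):
        eta = X @ beta
        mu = expit(eta)
        mu_c = np.clip(mu, 1e-12, 1 - 1e-12)
        ll = float(np.sum(w * (y * np.log(mu_c) + (1 - y) * np.log(1 - mu_c))))
        s = w * mu * (1 - mu)
        grad = X.T @ (w * (y - mu))
        H = X.T @ (X * s[:, None])
        if abs(ll - ll_prev) < LOGLIK_RTOL * (abs(ll) + 1.0):
            if np.abs(eta).max() > 30:
                # fitted probabilities numerically at 0/1: the likelihood
                # has plateaued on a separating ray, not at an interior MLE
                raise SeparationError(
                    "linear predictor diverged (max |eta| > 30); "
                    "perfect or quasi-perfect separation"
                )
            return beta, H, ll
        ll_prev = ll
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix (collinear columns or separation)"
            ) from exc
        beta = beta + step
        if np.linalg.norm(beta) > _SEPARATION_COEF_NORM:
            worst = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"coefficients diverging (|beta| > {_SEPARATION_COEF_NORM:g}); "
                f"likely perfect separation involving column index {worst}"
            )
    raise ConvergenceError(f"IRLS did not converge in {MAX_ITER} iterations")


def _cluster_sandwich(X, y, w, mu, H, clusters) -> np.ndarray:
    """Cluster-robust (or HC-robust if clusters is None) covariance."""
    bread = np.linalg.inv(H)
    score = X * (w * (y - mu))[:, None]
    if clusters is None:
        meat = score.T @ score
    else:
        codes, _ = pd.factorize(clusters)
        g = codes.max() + 1
        sums = np.zeros((g, X.shape[1]))
        np.add.at(sums, codes, score)
        meat = sums.T @ sums
        if g > 1:
            meat *= g / (g - 1)
    return bread @ meat @ bread


def fit_weighted_logit(X, y, w, clusters=None, names=None, link: str = "logit") -> LogitFit:
    """Survey-weighted binary regression with robust covariance.

    ``link="logit"`` fits the weighted logistic pseudo-likelihood by IRLS
    (relative log-likelihood tolerance 1e-10, 100 iterations, divergence
    detected as separation).  ``link="identity"`` is the weighted
    least-squares linear probability model, used for the linear-limit
    checks of the decomposition.  The covariance is a sandwich clustered on
    ``clusters`` (heteroskedasticity-robust when no clusters are given).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if X.ndim != 2 or len(y) != X.shape[0] or len(w) != X.shape[0]:
        raise ValueError("X, y, w must be conformable")
    uniq = np.unique(y)
    if not np.isin(uniq, [0.0, 1.0]).all():
        raise ValueError("y must be binary 0/1")
    if link == "logit" and len(uniq) < 2:
        raise ValueError("outcome is constant; logit undefined")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if link == "logit":
        beta, H, ll = _irls_logit(X, y, w)
        mu = expit(X @ beta)
    elif link == "identity":
        H = X.T @ (X * w[:, None])
        try:
            beta = np.linalg.solve(H, X.T @ (w * y))
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular design in weighted least squares") from exc
        mu = X @ beta
        ll = float(-np.sum(w * (y - mu) ** 2))
    else:
        raise ValueError(f"unknown link {link!r}")
    vcov = _cluster_sandwich(X, y, w, mu, H, clusters)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    return LogitFit(
        params=beta, vcov=vcov, names=list(names), n=X.shape[0],
        converged=True, loglik=ll, link=link,
    )


# ---------------------------------------------------------------------------
# two-fold decomposition


def _link_fn(link: str):
    if link == "logit":
        return expit
    if link == "identity":
        return lambda eta: eta
    raise ValueError(f"unknown link {link!r}")


def _wmean(v: np.ndarray, w: np.ndarray) -> float:
    return float((v * w).sum() / w.sum())


def _reference_beta(dd: DesignData, reference: str, link: str, fits: dict) -> np.ndarray:
    if reference == "pooled":
        # pooled model with a centered group indicator (+1/2 rural, -1/2
        # urban); the indicator column is dropped from beta*, pushing the
        # pure group effect into the unexplained component.  Centering makes
        # the convention symmetric: exchanging group labels exactly negates
        # every component.
        Xp = np.vstack([dd.X_rural, dd.X_urban])
        ind = np.concatenate(
            [np.full(len(dd.X_rural), 0.5), np.full(len(dd.X_urban), -0.5)]
        )
        Xp = np.hstack([Xp, ind[:, None]])
        yp = np.concatenate([dd.y_rural, dd.y_urban])
        wp = np.concatenate([dd.w_rural, dd.w_urban])
        fit = fit_weighted_logit(Xp, yp, wp, names=[*dd.columns, "_group"], link=link)
        fits["pooled"] = fit
        return fit.params[:-1]
    if reference in ("rural", "urban"):
        if reference not in fits:
            X, y, w, cl = (
                (dd.X_rural, dd.y_rural, dd.w_rural, dd.clusters_rural)
                if reference == "rural"
                else (dd.X_urban, dd.y_urban, dd.w_urban, dd.clusters_urban)
            )
            fits[reference] = fit_weighted_logit(X, y, w, clusters=cl, names=dd.columns, link=link)
        return fits[reference].params
    raise ValueError("reference must be 'pooled', 'rural' or 'urban'")


def _decompose_design(
    dd: DesignData,
    reference: str = "pooled",
    link: str = "logit",
    fit_groups: bool = False,
) -> DecompositionResult:
    F = _link_fn(link)
    fits: dict = {}
    if fit_groups:
        fits["rural"] = fit_weighted_logit(
            dd.X_rural, dd.y_rural, dd.w_rural, clusters=dd.clusters_rural,
            names=dd.columns, link=link,
        )
        fits["urban"] = fit_weighted_logit(
            dd.X_urban, dd.y_urban, dd.w_urban, clusters=dd.clusters_urban,
            names=dd.columns, link=link,
        )
    # the weighted mean of each group's own fitted values equals its
    # weighted observed prevalence (score identity of the weighted MLE with
    # an intercept), so the gap never depends on the group fits
    gap = _wmean(dd.y_rural, dd.w_rural) - _wmean(dd.y_urban, dd.w_urban)
    beta_star = _reference_beta(dd, reference, link, fits)
    explained = _wmean(F(dd.X_rural @ beta_star), dd.w_rural) - _wmean(
        F(dd.X_urban @ beta_star), dd.w_urban
    )
    unexplained = gap - explained
    xbar_r = (dd.X_rural * dd.w_rural[:, None]).sum(0) / dd.w_rural.sum()
    xbar_u = (dd.X_urban * dd.w_urban[:, None]).sum(0) / dd.w_urban.sum()
    try:
        detailed = yun_detailed(xbar_r, xbar_u, beta_star, explained, dd.terms)
    except ZeroLinearGapError:
        if abs(explained) < 1e-12:
            # identical covariate composition: nothing to apportion
            detailed = {
                name: {"weight": np.nan, "contribution": 0.0} for name in dd.terms
            }
        else:
            raise
    for name, entry in detailed.items():
        entry["percent_of_gap"] = (
            entry["contribution"] / gap * 100.0 if gap != 0 else np.nan
        )
    return DecompositionResult(
        gap=gap, explained=explained, unexplained=unexplained,
        detailed=detailed, reference=reference, fits=fits,
        n_excluded=dd.n_excluded,
    )


def decompose_two_fold(
    records: pd.DataFrame,
    spec: ModelSpec,
    reference: str = "pooled",
    link: str = "logit",
) -> DecompositionResult:
    """Two-fold decomposition of the rural-urban outcome gap.

    Returns the gap (rural minus urban, probability scale), its explained
    and unexplained components under the chosen reference-coefficient
    convention, and Yun detailed per-covariate contributions with percent
    shares.  ``explained + unexplained == gap`` holds to machine precision
    by construction.
    """
    dd = build_design(records, spec)
    return _decompose_design(dd, reference=reference, link=link, fit_groups=True)


def yun_detailed(
    xbar_rural,
    xbar_urban,
    beta_star,
    explained: float,
    terms: Mapping[str, list[int]] | None = None,
) -> dict:
    """Yun linear-index apportioning of the explained component.

    Each term's weight is its share of the linear-index gap
    (xbar_R - xbar_U)' beta*; dummy columns belonging to one categorical
    are aggregated into a single named contribution.  Weights sum to 1 and
    contributions sum to the explained component.  A zero linear-index gap
    leaves the weights undefined and raises ``ZeroLinearGapError``.
    """
    xbar_rural = np.asarray(xbar_rural, float)
    xbar_urban = np.asarray(xbar_urban, float)
    beta_star = np.asarray(beta_star, float)
    d = (xbar_rural - xbar_urban) * beta_star
    if terms is None:
        terms = {f"x{i}": [i] for i in range(len(d))}
    term_gap = {name: float(sum(d[c] for c in cols)) for name, cols in terms.items()}
    denom = sum(term_gap.values())
    scale = max(1.0, sum(abs(v) for v in term_gap.values()))
    if abs(denom) < 1e-12 * scale:
        raise ZeroLinearGapError(
            "linear-index gap sums to zero; Yun weights undefined "
            "(consider fairlie_detailed as a fallback)"
        )
    out = {}
    for name, g in term_gap.items():
        w_k = g / denom
        out[name] = {"weight": w_k, "contribution": w_k * explained}
    return out


def fairlie_detailed(
    records: pd.DataFrame,
    spec: ModelSpec,
    reference: str = "pooled",
    replications: int = 100,
    seed: int | None = None,
    link: str = "logit",
) -> dict:
    """Fairlie sequential-substitution detailed decomposition.

    The larger group is randomly matched (weight-proportional draw) to the
    smaller, both sides ranked by predicted probability under the reference
    coefficients, and covariates are switched from their urban to their
    rural values one term at a time in a random order; a term's
    contribution is the mean change in predicted probability at its switch,
    averaged over ``replications`` random matchings/orderings.  Returns
    ``{term: {"contribution": c, "mc_se": se}}``; the contributions sum to
    the explained component up to matching noise.
    """
    if replications < 1:
        raise ValueError("replications must be >= 1")
    rng = np.random.default_rng(seed)
    dd = build_design(records, spec)
    fits: dict = {}
    beta_star = _reference_beta(dd, reference, link, fits)
    F = _link_fn(link)
    n_r, n_u = len(dd.X_rural), len(dd.X_urban)
    n_min = min(n_r, n_u)
    term_names = list(dd.terms)
    draws = {name: np.empty(replications) for name in term_names}
    p_r_full = F(dd.X_rural @ beta_star)
    p_u_full = F(dd.X_urban @ beta_star)
    for rep in range(replications):
        ri = np.arange(n_r)
        ui = np.arange(n_u)
        if n_u > n_min:
            ui = rng.choice(n_u, size=n_min, replace=True, p=dd.w_urban / dd.w_urban.sum())
        elif n_r > n_min:
            ri = rng.choice(n_r, size=n_min, replace=True, p=dd.w_rural / dd.w_rural.sum())
        # rank-match by predicted probability under the reference model
        ri = ri[np.argsort(p_r_full[ri], kind="mergesort")]
        ui = ui[np.argsort(p_u_full[ui], kind="mergesort")]
        Xr, Xu = dd.X_rural[ri], dd.X_urban[ui]
        cur = Xu.copy()
        p_prev = F(cur @ beta_star)
        order = rng.permutation(len(term_names))
        for t in order:
            cols = dd.terms[term_names[t]]
            cur[:, cols] = Xr[:, cols]
            p_new = F(cur @ beta_star)
            draws[term_names[t]][rep] = (p_new - p_prev).mean()
            p_prev = p_new
    return {
        name: {
            "contribution": float(v.mean()),
            "mc_se": float(v.std(ddof=1) / np.sqrt(replications)) if replications > 1 else np.nan,
        }
        for name, v in draws.items()
    }


def bootstrap_components(
    records: pd.DataFrame,
    spec: ModelSpec,
    B: int = 200,
    seed: int | None = None,
    reference: str = "pooled",
    link: str = "logit",
    level: float = 0.95,
) -> BootstrapResult:
    """Cluster-bootstrap percentile CIs for every decomposition component.

    Clusters (PSUs) are resampled with replacement within each residence
    group and the full decomposition recomputed per replicate.  Replicates
    whose fits fail (separation/convergence) are skipped and counted.
    Requires ``B >= 100``.
    """
    if B < 100:
        raise ValueError("bootstrap needs B >= 100 replicates")
    rng = np.random.default_rng(seed)
    dd = build_design(records, spec)
    groups = {}
    for side in ("rural", "urban"):
        cl = getattr(dd, f"clusters_{side}")
        codes, uniques = pd.factorize(cl)
        idx_lists = [np.flatnonzero(codes == k) for k in range(len(uniques))]
        groups[side] = idx_lists
    draws: dict[str, list[float]] = {"gap": [], "explained": [], "unexplained": []}
    for name in dd.terms:
        draws[name] = []
    n_failed = 0
    for _ in range(B):
        idx = {}
        for side in ("rural", "urban"):
            lists = groups[side]
            pick = rng.integers(0, len(lists), size=len(lists))
            idx[side] = np.concatenate([lists[k] for k in pick])
        rep = DesignData(
            X_rural=dd.X_rural[idx["rural"]], y_rural=dd.y_rural[idx["rural"]],
            w_rural=dd.w_rural[idx["rural"]], clusters_rural=dd.clusters_rural[idx["rural"]],
            X_urban=dd.X_urban[idx["urban"]], y_urban=dd.y_urban[idx["urban"]],
            w_urban=dd.w_urban[idx["urban"]], clusters_urban=dd.clusters_urban[idx["urban"]],
            columns=dd.columns, terms=dd.terms, n_excluded=0,
        )
        try:
            res = _decompose_design(rep, reference=reference, link=link, fit_groups=False)
        except (SeparationError, ConvergenceError, ZeroLinearGapError, ValueError):
            n_failed += 1
            continue
        draws["gap"].append(res.gap)
        draws["explained"].append(res.explained)
        draws["unexplained"].append(res.unexplained)
        for name in dd.terms:
            draws[name].append(res.detailed[name]["contribution"])
    if n_failed:
        logger.warning("bootstrap_components: %d/%d replicates failed and were skipped", n_failed, B)
    if not draws["gap"]:
        raise RuntimeError("all bootstrap replicates failed")
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    intervals = {
        name: (float(np.percentile(v, lo_q)), float(np.percentile(v, hi_q)))
        for name, v in draws.items()
    }
    return BootstrapResult(
        intervals=intervals, n_replicates=len(draws["gap"]), n_failed=n_failed, level=level
    )


def percent_contributions(result: DecompositionResult) -> dict:
    """Percent-of-gap shares for explained, unexplained and each covariate.

    Explained and unexplained percents sum to 100; detailed percents sum to
    the explained percent.  Undefined (raises) when the gap is zero.
    """
    if result.gap == 0:
        raise ValueError("gap is zero; percent contributions undefined")
    out = {
        "explained": result.explained / result.gap * 100.0,
        "unexplained": result.unexplained / result.gap * 100.0,
    }
    for name, entry in result.detailed.items():
        out[name] = entry["contribution"] / result.gap * 100.0
    return out
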