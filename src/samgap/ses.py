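"""Neighbourhood socioeconomic disadvantage score and quintiles.

Each survey cluster (primary sampling unit, the operational
"neighbourhood") is profiled by the proportions of its respondents who are
illiterate, poor and unemployed.  The disadvantage score is the first
principal component of the correlation matrix of the three standardized
proportions, oriented so that higher scores mean more disadvantage.
Clusters are then cut into child-count-weighted quintiles, quintile 5
being the most disadvantaged fifth of children.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_INDICATORS",
    "aggregate_neighbourhoods",
    "disadvantage_scores",
    "assign_quintiles",
    "attach_ses",
]

logger = logging.getLogger(__name__)

DEFAULT_INDICATORS = ("illiterate", "poor", "unemployed")


def aggregate_neighbourhoods(
    records: pd.DataFrame,
    cluster_col: str = "cluster_id",
    indicators: tuple[str, ...] = DEFAULT_INDICATORS,
) -> pd.DataFrame:
    """Per-cluster indicator proportions (unweighted within cluster).

    Rows with any missing indicator are skipped; the skipped count is
    logged.  Returns one row per cluster with columns
    ``cluster_id, prop_<indicator>..., n_respondents``.
    """
    cols = [cluster_col, *indicators]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise KeyError(f"records missing columns: {missing}")
    sub = records.loc[:, cols]
    complete = sub.dropna(subset=list(indicators))
    n_skipped = len(sub) - len(complete)
    if n_skipped:
        logger.warning("aggregate_neighbourhoods: skipped %d records with missing indicators", n_skipped)
    grouped = complete.groupby(cluster_col, sort=True)
    profiles = grouped[list(indicators)].mean()
    profiles.columns = [f"prop_{c}" for c in indicators]
    profiles["n_respondents"] = grouped.size()
    return profiles.reset_index().rename(columns={cluster_col: "cluster_id"})


def disadvantage_scores(profiles: pd.DataFrame) -> pd.DataFrame:
    """First-principal-component disadvantage score per cluster.

    The proportion columns are standardized (mean 0, sd 1) and the first
    eigenvector of their correlation matrix gives the loadings.  The sign
    is fixed so the loadings sum positive: a cluster scores higher when any
    disadvantage indicator is higher.  Indicators with zero variance carry
    no information and are dropped (logged); if all are constant the score
    is undefined and a ``ValueError`` is raised.
    """
    prop_cols = [c for c in profiles.columns if c.startswith("prop_")]
    if len(profiles) < 3:
        raise ValueError("need at least 3 clusters to compute a disadvantage score")
    X = profiles[prop_cols].to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    # relative floor: a numerically-constant column is degenerate
    keep = sd > 1e-12 * (np.abs(X.mean(axis=0)) + 1.0)
    if not keep.any():
        raise ValueError("all indicators constant across clusters; score undefined")
    if not keep.all():
        dropped = [c for c, k in zip(prop_cols, keep) if not k]
        logger.warning("disadvantage_scores: dropping zero-variance indicators %s", dropped)
    Xk = X[:, keep]
    Z = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0, ddof=1)
    corr = np.corrcoef(Z, rowvar=False)
    corr = np.atleast_2d(corr)
    eigvals, eigvecs = np.linalg.eigh(corr)
    loadings = eigvecs[:, -1]
    if loadings.sum() < 0:
        loadings = -loadings
    scores = Z @ loadings
    out = profiles[["cluster_id"]].copy()
    out["score"] = scores
    return out


def assign_quintiles(
    indices: pd.DataFrame,
    weights: np.ndarray | pd.Series | None = None,
) -> pd.DataFrame:
    """Weighted quintile categories on the disadvantage score.

    ``weights`` are per-cluster child counts (defaults to equal).  Cut
    points are the 20/40/60/80% points of the weighted ECDF (smallest score
    at which the cumulative weight reaches the target); a score exactly on
    a cut point falls in the lower quintile.  Quintile 5 = most
    disadvantaged.
    """
    scores = indices["score"].to_numpy(float)
    if len(np.unique(scores)) < 5:
        raise ValueError("need at least 5 distinct scores to form quintiles")
    if weights is None:
        w = np.ones(len(scores))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != scores.shape or np.any(w <= 0):
            raise ValueError("weights must be positive and match the number of clusters")
    order = np.argsort(scores, kind="mergesort")
    cum = np.cumsum(w[order]) / w.sum()
    cuts = [scores[order][np.searchsorted(cum, p)] for p in (0.2, 0.4, 0.6, 0.8)]
    quintile = 1 + np.sum(scores[:, None] > np.asarray(cuts)[None, :], axis=1)
    out = indices.copy()
    out["quintile"] = quintile.astype(int)
    return out


def attach_ses(
    records: pd.DataFrame,
    cluster_col: str = "cluster_id",
    indicators: tuple[str, ...] = DEFAULT_INDICATORS,
    by_country: bool = True,
    country_col: str = "country",
) -> pd.DataFrame:
    """Compute the disadvantage index and merge score + quintile onto records.

    By default the PCA and the quintile cut points are computed within each
    country (set ``by_country=False`` to pool all clusters).  Adds columns
    ``ses_score`` and ``ses_quintile``.
    """
    def _one(block: pd.DataFrame) -> pd.DataFrame:
        profiles = aggregate_neighbourhoods(block, cluster_col, indicators)
        scored = disadvantage_scores(profiles)
        counts = block.groupby(cluster_col).size()
        scored = assign_quintiles(scored, counts.loc[scored["cluster_id"]].to_numpy())
        scored = scored.rename(
            columns={"score": "ses_score", "quintile": "ses_quintile", "cluster_id": cluster_col}
        )
        return scored

    if by_country and country_col in records.columns:
        parts = []
        for country, block in records.groupby(country_col, sort=False):
            scored = _one(block)
            scored[country_col] = country
            parts.append(scored)
        merged = pd.concat(parts, ignore_index=True)
        return records.merge(merged, on=[country_col, cluster_col], how="left")
    return records.merge(_one(records), on=cluster_col, how="left")
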