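"""End-to-end orchestration: SAM derivation, per-country inequality,
significance screening, random-effects pooling, and decomposition of the
significant countries.

The analysis proceeds in six stages: (1) pool the eligible child records,
(2) derive or pass through the SAM outcome, (3) compute weighted
prevalences by residence within country, (4) compute each country's risk
difference and classify it, (5) keep the significantly pro-rural and
pro-urban countries, and (6) run the two-fold decomposition for each of
them.  ``run_full_pipeline`` writes tidy CSV outputs and a JSON run
manifest; all randomness is controlled by explicit seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import inequality
from .anthropometry import LMSTable, compute_whz_table
from .decomposition import (
    ModelSpec,
    bootstrap_components,
    decompose_two_fold,
    percent_contributions,
)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "derive_outcomes",
    "summarize_countries",
    "select_decomposition_countries",
    "run_full_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and knobs for a full run.

    Provide either ``input_csv`` (a flat child table) or ``synthetic``
    (a list of GeneratorConfig, one per country).  ``bootstrap_B = 0``
    skips decomposition CIs.
    """

    model: ModelSpec
    input_csv: str | Path | None = None
    synthetic: list | None = None
    out_dir: str | Path = "samgap_out"
    alpha: float = 0.05
    reference: str = "pooled"
    bootstrap_B: int = 0
    seed: int = 0
    decompose_all: bool = False
    lms_table: LMSTable | None = None

    def __post_init__(self):
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of input_csv or synthetic")


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    n_input_rows: int = 0
    exclusions: dict = field(default_factory=dict)
    countries_analyzed: list = field(default_factory=list)
    countries_skipped: list = field(default_factory=list)
    selected_pro_rural: list = field(default_factory=list)
    selected_pro_urban: list = field(default_factory=list)
    outputs: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def derive_outcomes(
    records: pd.DataFrame, lms: LMSTable | None = None
) -> tuple[pd.DataFrame, int]:
    """Ensure a ``sam`` column, deriving it from raw anthropometry if needed.

    Records already carrying ``sam`` pass through with zero exclusions.
    Otherwise ``weight_kg``, ``height_cm`` and ``sex`` plus an LMS table
    are required; implausible WHZ rows (|WHZ| > 5 or out of reference
    range) are dropped and counted.
    """
    if "sam" in records.columns:
        return records, 0
    raw = {"weight_kg", "height_cm", "sex"}
    if not raw.issubset(records.columns) or lms is None:
        raise ValueError(
            "records carry neither a sam column nor raw anthropometry "
            "(weight_kg, height_cm, sex) with an LMS table"
        )
    scored = compute_whz_table(records, lms)
    keep = ~scored["implausible"]
    n_excluded = int((~keep).sum())
    out = scored.loc[keep].copy()
    out["sam"] = out["sam"].astype(int)
    return out, n_excluded


def summarize_countries(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-country weighted prevalences and classified risk differences.

    Countries lacking either residence group are skipped with a warning.
    Returns one row per analysable country with columns
    ``country, n_children, pct_rural, prev_overall, prev_rural, prev_urban,
    rd_per_1000, ci_low, ci_high, variance, p_value, classification``.
    """
    rows = []
    for country, block in records.groupby("country", sort=True):
        res = block["residence"]
        if not {"rural", "urban"}.issubset(set(res.unique())):
            logger.warning("summarize_countries: %s lacks a residence group; skipped", country)
            continue
        y = block["sam"].to_numpy(float)
        w = block["weight"].to_numpy(float)
        overall = inequality.weighted_prevalence(y, w, "all")
        r_mask = (res == "rural").to_numpy()
        rural = inequality.weighted_prevalence(y[r_mask], w[r_mask], "rural")
        urban = inequality.weighted_prevalence(y[~r_mask], w[~r_mask], "urban")
        rd = inequality.risk_difference(rural, urban, alpha=alpha)
        rows.append(
            {
                "country": country,
                "n_children": len(block),
                "pct_rural": 100.0 * w[r_mask].sum() / w.sum(),
                "prev_overall": overall.prevalence,
                "prev_rural": rural.prevalence,
                "prev_urban": urban.prevalence,
                "rd_per_1000": rd.rd_per_1000,
                "ci_low": rd.ci_low,
                "ci_high": rd.ci_high,
                "variance": rd.variance,
                "p_value": rd.p_value,
                "classification": rd.classification,
            }
        )
    if not rows:
        raise ValueError("no country has both rural and urban records")
    return pd.DataFrame(rows)


def select_decomposition_countries(summaries: pd.DataFrame) -> tuple[list, list]:
    """Countries with significant pro-rural / pro-urban inequality."""
    pro_rural = summaries.loc[
        summaries["classification"] == inequality.PRO_RURAL, "country"
    ].tolist()
    pro_urban = summaries.loc[
        summaries["classification"] == inequality.PRO_URBAN, "country"
    ].tolist()
    return pro_rural, pro_urban


def run_full_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the six-stage analysis and write the output bundle.

    Writes ``country_summary.csv``, ``pooled_random_effects.csv``,
    ``decomposition_<country>.csv`` per selected country and
    ``manifest.json`` under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={
            "alpha": config.alpha,
            "reference": config.reference,
            "bootstrap_B": config.bootstrap_B,
            "decompose_all": config.decompose_all,
            "mode": "synthetic" if config.synthetic is not None else "csv",
        },
        seeds={"pipeline": config.seed},
    )

    # stage 1: assemble records
    if config.synthetic is not None:
        from .synthetic import generate_population

        parts = [generate_population(gc).records for gc in config.synthetic]
        records = pd.concat(parts, ignore_index=True)
    else:
        records = pd.read_csv(config.input_csv)
    manifest.n_input_rows = len(records)

    # stage 2: outcome derivation
    records, n_excluded = derive_outcomes(records, config.lms_table)
    manifest.exclusions["implausible_whz"] = n_excluded

    # stages 3-4: per-country inequality
    summaries = summarize_countries(records, alpha=config.alpha)
    manifest.countries_analyzed = summaries["country"].tolist()
    manifest.countries_skipped = sorted(
        set(records["country"].unique()) - set(manifest.countries_analyzed)
    )
    path = out_dir / "country_summary.csv"
    summaries.to_csv(path, index=False)
    manifest.outputs.append(str(path))

    # pooling (forest-plot analogue); RD variance moved to the per-1,000^2 scale
    studies = [
        (row.country, row.rd_per_1000, row.variance * 1e6)
        for row in summaries.itertuples()
    ]
    pooled = inequality.pool_random_effects(studies)
    pooled_df = pd.DataFrame(
        {
            "study": [*pooled.study_weights, "RE pooled"],
            "rd_per_1000": [*summaries["rd_per_1000"], pooled.pooled_rd_per_1000],
            "ci_low": [*summaries["ci_low"], pooled.ci_low],
            "ci_high": [*summaries["ci_high"], pooled.ci_high],
            "percent_weight": [*pooled.study_weights.values(), 100.0],
        }
    )
    path = out_dir / "pooled_random_effects.csv"
    pooled_df.to_csv(path, index=False)
    manifest.outputs.append(str(path))

    # stage 5: screening
    pro_rural, pro_urban = select_decomposition_countries(summaries)
    manifest.selected_pro_rural = pro_rural
    manifest.selected_pro_urban = pro_urban
    selected = (
        manifest.countries_analyzed if config.decompose_all else pro_rural + pro_urban
    )
    if not selected:
        logger.info("run_full_pipeline: no significant countries; decomposition skipped")

    # stage 6: decomposition per selected country
    rng = np.random.default_rng(config.seed)
    for country in selected:
        block = records.loc[records["country"] == country]
        result = decompose_two_fold(block, config.model, reference=config.reference)
        ci = None
        if config.bootstrap_B >= 100:
            boot_seed = int(rng.integers(0, 2**31 - 1))
            manifest.seeds[f"bootstrap:{country}"] = boot_seed
            ci = bootstrap_components(
                block, config.model, B=config.bootstrap_B, seed=boot_seed,
                reference=config.reference,
            ).intervals
        pct = percent_contributions(result) if result.gap != 0 else {}
        rows = [
            {"component": "gap", "covariate": "", "estimate": result.gap,
             "percent_of_gap": 100.0},
            {"component": "explained", "covariate": "", "estimate": result.explained,
             "percent_of_gap": pct.get("explained", np.nan)},
            {"component": "unexplained", "covariate": "", "estimate": result.unexplained,
             "percent_of_gap": pct.get("unexplained", np.nan)},
        ]
        for name, entry in result.detailed.items():
            rows.append(
                {"component": "detailed", "covariate": name,
                 "estimate": entry["contribution"],
                 "percent_of_gap": entry["percent_of_gap"]}
            )
        tidy = pd.DataFrame(rows)
        if ci is not None:
            key = tidy.apply(
                lambda r: r["covariate"] if r["component"] == "detailed" else r["component"],
                axis=1,
            )
            tidy["ci_low"] = [ci.get(k, (np.nan, np.nan))[0] for k in key]
            tidy["ci_high"] = [ci.get(k, (np.nan, np.nan))[1] for k in key]
        path = out_dir / f"decomposition_{country}.csv"
        tidy.to_csv(path, index=False)
        manifest.outputs.append(str(path))

    path = out_dir / "manifest.json"
    path.write_text(manifest.to_json())
    manifest.outputs.append(str(path))
    return manifest
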