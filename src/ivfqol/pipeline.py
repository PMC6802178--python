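"""End-to-end orchestration: ingest -> eligibility -> integration ->
subfield mTDs -> Rasch scoring -> correlation screen -> forest importance
-> reports.

Every number in the output tables is produced by one module operation;
this module only sequences them and writes artifacts.  A run is fully
determined by its config and seed (the manifest records both), so
re-running a manifest reproduces the artifact set byte-for-byte; wall
-clock timings go only to the log.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import (
    EligibilityCriteria,
    anova_scheffe,
    correlation_table,
    descriptives,
    eligibility_filter,
    paired_t,
    spearman_matrix,
)
from .forest_importance import (
    FEATURE_COLUMNS,
    RESPONSE_COLUMNS,
    fit_forest,
    importance_pvalues,
)
from .ivf_integration import read_fields_csv
from .rasch import default_schema, fit_rasch, score_cohort
from .synthetic_data import (
    SyntheticCohortConfig,
    build_feature_table,
    simulate_cohort,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source: either ``synthetic`` (a generator config)
    or the three CSV paths.  The seed drives every stochastic stage.
    """

    out_dir: str = "run"
    seed: int = 0
    synthetic: SyntheticCohortConfig | None = None
    fields_csv: str | None = None
    patients_csv: str | None = None
    responses_csv: str | None = None
    rasch_model: str = "rating_scale"
    n_trees: int = 1000
    max_features: int | str = "third"
    min_samples_leaf: int = 5
    n_null: int = 2000
    alpha: float = 0.05
    responses_to_analyze: tuple[str, ...] = tuple(RESPONSE_COLUMNS)
    eligibility: EligibilityCriteria = field(default_factory=EligibilityCriteria)

    def validate(self):
        csv_source = all(p is not None for p in
                         (self.fields_csv, self.patients_csv,
                          self.responses_csv))
        if (self.synthetic is None) == (not csv_source):
            raise PipelineError(
                "config", "exactly one input source required: synthetic "
                "config or all three CSV paths")


def _hist_table(abilities: pd.DataFrame, n_bins: int = 12) -> pd.DataFrame:
    """Histogram-ready counts of each RADPAI column (Fig.-style export)."""
    cols = [c for c in abilities.columns if c.startswith("radpai_")]
    vals = abilities[cols].to_numpy()
    lo, hi = float(np.floor(vals.min())), float(np.ceil(vals.max()))
    edges = np.linspace(lo, hi, n_bins + 1)
    rows = []
    for c in cols:
        counts, _ = np.histogram(abilities[c], bins=edges)
        for b in range(n_bins):
            rows.append({"score": c, "bin_left": edges[b],
                         "bin_right": edges[b + 1], "count": int(counts[b])})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a dict of in-memory artifacts
    and writes them under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name):
        logger.info("stage %-14s t=%.1fs", name, time.time() - t0)

    # ---- ingest
    stage("ingest")
    if config.synthetic is not None:
        cohort = simulate_cohort(config.synthetic, seed=config.seed)
        patients, fields, responses = (cohort.patients, cohort.fields,
                                       cohort.responses)
    else:
        try:
            fields = read_fields_csv(config.fields_csv)
            patients = pd.read_csv(config.patients_csv, index_col=0)
            responses = pd.read_csv(config.responses_csv, index_col=0)
        except Exception as exc:
            raise PipelineError("ingest", str(exc)) from exc

    # ---- eligibility
    stage("eligibility")
    eligible, excluded = eligibility_filter(patients, config.eligibility)
    excluded.to_csv(out / "excluded.csv")
    eligible.to_csv(out / "eligible.csv")
    if len(eligible) == 0:
        _write_manifest(config, out, status="aborted:no-eligible-patients")
        raise PipelineError("eligibility", "no eligible patients; "
                            "eligibility report written")
    fields = [f for f in fields if f.patient_id in set(eligible.index)]
    responses = responses.loc[eligible.index]

    # ---- integration and subfield mTDs
    stage("integration")
    features = build_feature_table(fields, eligible)
    features.to_csv(out / "subfield_mtd.csv")

    # ---- Rasch scoring
    stage("rasch")
    schema = default_schema()
    fit = fit_rasch(responses, schema, model=config.rasch_model)
    abilities = score_cohort(responses, schema, fit=fit)
    abilities.to_csv(out / "abilities.csv")
    with open(out / "rasch_fit.json", "w") as fh:
        json.dump(fit.summary(), fh, indent=1, sort_keys=True)

    # ---- classical statistics
    stage("cohort-stats")
    corr = spearman_matrix(features, abilities, alpha=config.alpha)
    corr.to_csv(out / "correlations_long.csv", index=False)
    correlation_table(corr).to_csv(out / "correlations.csv")
    quad_cols = [c for c in FEATURE_COLUMNS if c.startswith("mtd_10_2")]
    F, p_anova, scheffe = anova_scheffe(
        {c: features[c].to_numpy() for c in quad_cols})
    t, p_t, dmean = paired_t(features["mtd_24_2_upper"],
                             features["mtd_24_2_lower"])
    desc = descriptives(eligible)
    desc.to_csv(out / "descriptives.csv")
    with open(out / "classical_stats.json", "w") as fh:
        json.dump({"anova_F": F, "anova_p": p_anova,
                   "scheffe_p": scheffe.to_dict(),
                   "paired_t": t, "paired_t_p": p_t,
                   "upper_minus_lower_mtd": dmean}, fh, indent=1,
                  sort_keys=True)

    # ---- forest importance
    stage("forest")
    importance = {}
    for resp in config.responses_to_analyze:
        table = pd.concat([features, abilities[[resp]]], axis=1)
        model = fit_forest(table, resp, n_estimators=config.n_trees,
                           max_features=config.max_features,
                           min_samples_leaf=config.min_samples_leaf,
                           seed=config.seed)
        report = importance_pvalues(model, n_null=config.n_null,
                                    response=resp)
        importance[resp] = report
    imp_rows = []
    for resp, rep in importance.items():
        for rec in rep.to_records():
            imp_rows.append({"response": resp, **rec})
    imp_df = pd.DataFrame(imp_rows,
                          columns=["response", "rank", "variable", "p_value"])
    imp_df.to_csv(out / "importance.csv", index=False)
    with open(out / "importance.json", "w") as fh:
        json.dump({r: rep.to_records() for r, rep in importance.items()},
                  fh, indent=1, sort_keys=True)

    # ---- histogram export + manifest
    stage("report")
    _hist_table(abilities).to_csv(out / "radpai_histograms.csv", index=False)
    _write_manifest(config, out, status="ok")
    stage("done")
    return {"patients": patients, "eligible": eligible, "features": features,
            "abilities": abilities, "rasch_fit": fit, "correlations": corr,
            "anova": (F, p_anova, scheffe), "paired_t": (t, p_t, dmean),
            "importance": importance, "descriptives": desc}


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    if hasattr(obj, "__dict__") or hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(obj).items()} \
            if hasattr(obj, "__dataclass_fields__") else str(obj)
    return obj


def _write_manifest(config: RunConfig, out: Path, status: str):
    cfg = asdict(config)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"status": status, "seed": config.seed,
                   "ivfqol_version": __version__,
                   "config": json.loads(json.dumps(cfg, default=str))},
                  fh, indent=1, sort_keys=True)
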