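"""Seeded synthetic cohorts of advanced-glaucoma patients.

No patient-level data from the motivating study were ever released, so
every stage of the pipeline is exercised on simulated cohorts built to
have the same statistical structure the analysis assumes:

* per-eye total-deviation maps with advanced, upper-field-dominant loss
  (better-eye MD centred near -17 dB, worse-eye near -26 dB, the scale of
  the published demographics table);
* acuity (logMAR) tied to central damage of the same eye;
* questionnaire responses drawn from the rating-scale Rasch model, with
  each task's latent ability a configurable linear combination of the 13
  explanatory variables (the recoverable ground truth) plus noise.

The spatial model is: per-eye global damage level + hemifield offset
(upper worse) + a shared random effect per subfield + independent
per-point noise, truncated to the perimeter's [-35, 5] dB display range.
Age never drives ability in the default truth map; it is the built-in
null variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .ivf_integration import MonocularField, Reliability
from .rasch import QuestionnaireSchema, default_schema
from .vf_geometry import (
    assign_subfields,
    default_scheme,
    generate_grid,
)

TD_FLOOR, TD_CEIL = -35.0, 5.0

#: default per-task loadings over the 13 explanatory variables.  Positive
#: on mTDs (less damage -> higher ability), negative on logMAR acuity
#: (higher logMAR -> worse ability).  Chosen once to mirror the pattern of
#: task-subfield relationships the analysis is meant to detect, at effect
#: sizes giving marginal Spearman correlations around 0.4-0.5.
DEFAULT_TRUTH_MAP: dict[str, dict[str, float]] = {
    "letters": {"bcva_better": -1.0},
    "sentences": {"mtd_10_2_inner_lower_right": 0.6,
                  "mtd_10_2_outer_lower_right": 0.6,
                  "bcva_better": -0.5},
    "walking": {"mtd_10_2_inner_lower_left": 0.7, "mtd_24_2_lower": 0.7},
    "going_out": {"mtd_10_2_inner_lower_left": 0.6,
                  "mtd_10_2_inner_lower_right": 0.6,
                  "mtd_24_2_lower": 0.5},
    "dining": {"mtd_10_2_inner_lower_right": 0.7,
               "mtd_10_2_outer_lower_right": 0.7,
               "mtd_24_2_lower": 0.5},
    "dressing": {"bcva_better": -1.0},
    "miscellaneous": {"bcva_better": -0.6, "mtd_24_2_lower": 0.6},
}


class SyntheticConfigError(ValueError):
    pass


@dataclass
class SyntheticCohortConfig:
    """Knobs of the generator; defaults emulate the published cohort scale."""

    n_patients: int = 172
    # demographics (mean +/- SD of the published table)
    age_mean: float = 62.5
    age_sd: float = 12.2
    refraction_mean: float = -2.8
    refraction_sd: float = 4.0
    iop_mean: float = 12.8
    iop_sd: float = 2.8
    # damage model
    md_better_mean: float = -17.0
    md_better_sd: float = 8.2
    md_worse_mean: float = -26.3
    md_worse_sd: float = 3.0
    upper_offset_db: float = -6.0       # upper-minus-lower hemifield damage
    subfield_effect_sd: float = 2.0     # shared random effect per subfield
    point_noise_sd: float = 3.0         # independent per-point noise
    # acuity model: logMAR = intercept + slope * central mTD + noise
    bcva_slope: float = -0.010
    bcva_intercept: float = -0.15
    bcva_noise_sd: float = 0.08
    bcva_logmar_bounds: tuple[float, float] = (-0.30, 0.30)
    # reliability indices (fractions); default draws below eligibility caps
    max_fl_draw: float = 0.15
    max_fp_draw: float = 0.10
    max_fn_draw: float = 0.25
    reliability_violation_rate: float = 0.0
    # questionnaire model
    truth_map: dict[str, dict[str, float]] = dc_field(
        default_factory=lambda: {t: dict(v)
                                 for t, v in DEFAULT_TRUTH_MAP.items()})
    theta_noise_sd: float = 0.8
    item_difficulty_range: tuple[float, float] = (-1.5, 1.5)
    thresholds: tuple[float, ...] = (-0.8, 0.8)

    def validate(self, schema: QuestionnaireSchema) -> None:
        if self.n_patients < 1:
            raise SyntheticConfigError("n_patients must be >= 1")
        missing = [t for t in schema.tasks if t not in self.truth_map]
        if missing:
            raise SyntheticConfigError(f"truth map lacks tasks: {missing}")
        for t, coefs in self.truth_map.items():
            if not all(np.isfinite(list(coefs.values()))):
                raise SyntheticConfigError(f"non-finite coefficient in {t}")

    def item_difficulties(self, schema: QuestionnaireSchema) -> np.ndarray:
        lo, hi = self.item_difficulty_range
        d = np.linspace(lo, hi, len(schema.items))
        return d - d.mean()


@dataclass
class SyntheticCohort:
    """Everything one simulated run produces, plus its ground truth."""

    config: SyntheticCohortConfig
    seed: int
    patients: pd.DataFrame          # demographics, per-eye MD/BCVA, reliability
    fields: list[MonocularField]    # 10-2 x 2 dates and 24-2, both eyes
    responses: pd.DataFrame         # patients x items
    theta: pd.DataFrame             # latent ability per task (ground truth)
    features: pd.DataFrame          # true explanatory-variable table


_GRIDS = {
    ("10-2", None): generate_grid("10-2"),
    ("24-2", "right"): generate_grid("24-2", "right"),
    ("24-2", "left"): generate_grid("24-2", "left"),
}


def _label_arrays():
    out = {}
    for key, grid in _GRIDS.items():
        scheme = default_scheme(grid.pattern)
        labels = assign_subfields(grid, scheme)
        out[key] = np.array([labels[p] for p in grid])
    return out


_LABELS = _label_arrays()
_UPPER_MASKS = {key: np.array([p.y > 0 for p in grid])
                for key, grid in _GRIDS.items()}


def _simulate_eye_points(rng, level, upper_offset, subfield_effects, key,
                         point_noise_sd):
    grid = _GRIDS[key]
    labels = _LABELS[key]
    upper = _UPPER_MASKS[key]
    td = np.full(len(grid), level)
    td += np.where(upper, upper_offset / 2.0, -upper_offset / 2.0)
    td += np.array([subfield_effects[lab] for lab in labels])
    td += rng.normal(0.0, point_noise_sd, size=len(grid))
    return np.clip(td, TD_FLOOR, TD_CEIL)


def simulate_fields(config: SyntheticCohortConfig, patient_id: str,
                    rng: np.random.Generator) -> tuple[list[MonocularField], dict]:
    """All perimetry for one patient: two 10-2 tests and one 24-2 test per
    eye.  Returns (fields, per-eye metadata)."""
    level_better = min(rng.normal(config.md_better_mean, config.md_better_sd),
                       -2.0)
    level_worse = min(rng.normal(config.md_worse_mean, config.md_worse_sd),
                      -20.0)
    if level_worse > level_better:
        level_better, level_worse = level_worse, level_better
    better_is_od = bool(rng.random() < 0.5)
    levels = {"OD": level_better if better_is_od else level_worse,
              "OS": level_worse if better_is_od else level_better}
    lateralities = {"OD": "right", "OS": "left"}
    all_labels = sorted({lab for arr in _LABELS.values() for lab in arr})

    fields: list[MonocularField] = []
    meta: dict = {"better_eye": "OD" if better_is_od else "OS"}
    for eye in ("OD", "OS"):
        effects = {lab: rng.normal(0.0, config.subfield_effect_sd)
                   for lab in all_labels}
        if rng.random() < config.reliability_violation_rate:
            rel = Reliability(fixation_loss=float(rng.uniform(0.20, 0.40)),
                              false_positive=float(rng.uniform(0, config.max_fp_draw)),
                              false_negative=float(rng.uniform(0, config.max_fn_draw)))
        else:
            rel = Reliability(
                fixation_loss=float(rng.uniform(0, config.max_fl_draw)),
                false_positive=float(rng.uniform(0, config.max_fp_draw)),
                false_negative=float(rng.uniform(0, config.max_fn_draw)))
        central_tds = []
        for date in ("2006-01-15", "2006-07-15"):
            key = ("10-2", None)
            td = _simulate_eye_points(rng, levels[eye], config.upper_offset_db,
                                      effects, key, config.point_noise_sd)
            fields.append(MonocularField(patient_id, eye, date, _GRIDS[key],
                                         td, rel, md=levels[eye]))
            inner = np.array([p.eccentricity <= 5.0 for p in _GRIDS[key]])
            central_tds.append(td[inner].mean())
        key = ("24-2", lateralities[eye])
        td = _simulate_eye_points(rng, levels[eye], config.upper_offset_db,
                                  effects, key, config.point_noise_sd)
        fields.append(MonocularField(patient_id, eye, "2006-04-15",
                                     _GRIDS[key], td, rel, md=levels[eye]))
        lo, hi = config.bcva_logmar_bounds
        logmar = float(np.clip(
            config.bcva_intercept + config.bcva_slope * np.mean(central_tds)
            + rng.normal(0.0, config.bcva_noise_sd), lo, hi))
        meta[eye] = {"md": levels[eye], "bcva_logmar": logmar,
                     "reliability": rel}
    return fields, meta


def simulate_responses(config: SyntheticCohortConfig, features: pd.DataFrame,
                       rng: np.random.Generator,
                       schema: QuestionnaireSchema | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw questionnaire categories from the rating-scale model.

    Latent per-task ability is the standardized truth-map combination of
    the feature columns plus Gaussian noise; items respond to their
    task's ability through the fitted-model family itself.
    """
    if schema is None:
        schema = default_schema()
    config.validate(schema)
    n = len(features)
    z = (features - features.mean()) / features.std(ddof=0).replace(0.0, 1.0)
    theta = pd.DataFrame(index=features.index)
    for task in schema.tasks:
        coefs = config.truth_map[task]
        unknown = [k for k in coefs if k not in features.columns]
        if unknown:
            raise SyntheticConfigError(
                f"truth map for {task!r} names unknown features {unknown}")
        signal = np.zeros(n)
        for k, c in coefs.items():
            signal += c * z[k].to_numpy()
        norm = np.sqrt(sum(c * c for c in coefs.values())) or 1.0
        theta[task] = signal / norm + rng.normal(0, config.theta_noise_sd,
                                                 size=n)

    delta = config.item_difficulties(schema)
    cumtau = np.concatenate([[0.0], np.cumsum(config.thresholds)])
    K1 = len(cumtau)
    k = np.arange(K1)
    responses = pd.DataFrame(index=features.index, columns=list(schema.items),
                             dtype=float)
    for j, item in enumerate(schema.items):
        th = theta[schema.item_task[item]].to_numpy()
        eta = k[None, :] * (th[:, None] - delta[j]) - cumtau[None, :]
        eta -= eta.max(axis=1, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=1, keepdims=True)
        u = rng.random(n)
        responses[item] = (P.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return responses.astype(int), theta


def build_feature_table(cohort_fields: list[MonocularField],
                        patients: pd.DataFrame) -> pd.DataFrame:
    """Assemble the 13-variable explanatory table from raw fields.

    Runs the real pipeline operations: best-location integration per
    pattern, averaging of the two 10-2 assessments, then subfield mTDs.
    """
    from .ivf_integration import (average_available, integrate_best_location,
                                  subfield_mtd)

    by_patient: dict[str, dict] = {}
    for f in cohort_fields:
        by_patient.setdefault(f.patient_id, {"10-2": {}, "24-2": {}})
        slot = by_patient[f.patient_id][f.pattern]
        slot.setdefault(f.date, {})[f.eye] = f

    rows = {}
    for pid, slots in by_patient.items():
        ivfs_10 = []
        for date in sorted(slots["10-2"]):
            eyes = slots["10-2"][date]
            ivfs_10.append(integrate_best_location(eyes["OD"], eyes["OS"]))
        ivf_10 = average_available(ivfs_10)
        summ_10 = subfield_mtd(ivf_10)
        (date,) = sorted(slots["24-2"]) or [None]
        eyes = slots["24-2"][date]
        ivf_24 = integrate_best_location(eyes["OD"], eyes["OS"])
        summ_24 = subfield_mtd(ivf_24)
        row = {f"mtd_10_2_{lab}": v for lab, v in summ_10.mtd.items()}
        row.update({f"mtd_24_2_{lab}": v for lab, v in summ_24.mtd.items()})
        rows[pid] = row

    feats = pd.DataFrame.from_dict(rows, orient="index").loc[patients.index]
    feats.insert(0, "age", patients["age"])
    logmar = patients[["bcva_logmar_od", "bcva_logmar_os"]].to_numpy()
    feats.insert(1, "bcva_better", logmar.min(axis=1))
    feats.insert(2, "bcva_worse", logmar.max(axis=1))
    return feats


def simulate_cohort(config: SyntheticCohortConfig | None = None,
                    seed: int = 0,
                    schema: QuestionnaireSchema | None = None
                    ) -> SyntheticCohort:
    """One fully seeded synthetic cohort, reproducible bit-for-bit."""
    if config is None:
        config = SyntheticCohortConfig()
    if schema is None:
        schema = default_schema()
    config.validate(schema)
    rng = np.random.default_rng(seed)

    fields: list[MonocularField] = []
    pat_rows = {}
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        pfields, meta = simulate_fields(config, pid, rng)
        fields.extend(pfields)
        od, os_ = meta["OD"], meta["OS"]
        pat_rows[pid] = {
            "age": float(np.clip(rng.normal(config.age_mean, config.age_sd),
                                 20, 95)),
            "sex": "F" if rng.random() < 117 / 172 else "M",
            "refraction_od": rng.normal(config.refraction_mean,
                                        config.refraction_sd),
            "refraction_os": rng.normal(config.refraction_mean,
                                        config.refraction_sd),
            "iop_od": rng.normal(config.iop_mean, config.iop_sd),
            "iop_os": rng.normal(config.iop_mean, config.iop_sd),
            "md_od": od["md"], "md_os": os_["md"],
            "bcva_logmar_od": od["bcva_logmar"],
            "bcva_logmar_os": os_["bcva_logmar"],
            "bcva_decimal_od": 10 ** -od["bcva_logmar"],
            "bcva_decimal_os": 10 ** -os_["bcva_logmar"],
            "max_fl": max(od["reliability"].fixation_loss,
                          os_["reliability"].fixation_loss),
            "max_fp": max(od["reliability"].false_positive,
                          os_["reliability"].false_positive),
            "max_fn": max(od["reliability"].false_negative,
                          os_["reliability"].false_negative),
            "better_eye": meta["better_eye"],
        }
    patients = pd.DataFrame.from_dict(pat_rows, orient="index")
    patients.index.name = "patient_id"

    features = build_feature_table(fields, patients)
    responses, theta = simulate_responses(config, features, rng, schema)
    return SyntheticCohort(config=config, seed=seed, patients=patients,
                           fields=fields, responses=responses, theta=theta,
                           features=features)
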