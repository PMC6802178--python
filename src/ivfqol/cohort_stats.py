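"""Eligibility filtering and classical statistics for the cohort.

Eligibility mirrors the clinical enrolment rules for advanced glaucoma:
reproducible mean deviation of -20 dB or worse in at least one eye,
decimal best-corrected acuity of at least 0.5 (20/40) in both eyes, and
reliable perimetry on every test (fixation loss < 20%, false positives
< 15%, false negatives < 33%).

The screening statistics are the conventional ones: Spearman correlations
between the 13 explanatory variables and the 8 ability scores with a
Bonferroni family of 104 comparisons (per-comparison threshold
0.05/104 = 0.00048), one-way ANOVA with Scheffe post-hoc contrasts across
the eight 10-2 subfield mTDs, and a paired t-test on the 24-2 hemifield
mTDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .forest_importance import FEATURE_COLUMNS, RESPONSE_COLUMNS


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class EligibilityCriteria:
    md_threshold_db: float = -20.0       # either eye at or below this
    min_decimal_bcva: float = 0.5        # both eyes at or above this
    max_fixation_loss: float = 0.20      # strict caps per test
    max_false_positive: float = 0.15
    max_false_negative: float = 0.33


REQUIRED_RECORD_FIELDS = [
    "md_od", "md_os", "bcva_decimal_od", "bcva_decimal_os",
    "max_fl", "max_fp", "max_fn",
]


def eligibility_filter(records: pd.DataFrame,
                       criteria: EligibilityCriteria | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split patient records into (eligible, excluded-with-reason).

    ``records`` needs per-eye MD, per-eye decimal BCVA and the worst
    reliability indices over the patient's tests (``max_fl``/``max_fp``/
    ``max_fn``).  Each exclusion carries the first failed rule, checked
    in the order MD, BCVA, reliability.
    """
    if criteria is None:
        criteria = EligibilityCriteria()
    missing = [c for c in REQUIRED_RECORD_FIELDS if c not in records.columns]
    if missing:
        raise StatsError(f"records lack required fields: {missing}")
    bad = records[REQUIRED_RECORD_FIELDS].isna().any(axis=1)
    if bad.any():
        raise StatsError(
            f"records with missing eligibility fields: {list(records.index[bad])[:5]}")

    reasons = pd.Series("", index=records.index, dtype=object)
    md_ok = (records.md_od <= criteria.md_threshold_db) | \
            (records.md_os <= criteria.md_threshold_db)
    bcva_ok = (records.bcva_decimal_od >= criteria.min_decimal_bcva) & \
              (records.bcva_decimal_os >= criteria.min_decimal_bcva)
    rel_ok = (records.max_fl < criteria.max_fixation_loss) & \
             (records.max_fp < criteria.max_false_positive) & \
             (records.max_fn < criteria.max_false_negative)
    reasons[~rel_ok] = "reliability"
    reasons[~bcva_ok] = "bcva"
    reasons[~md_ok] = "md"
    eligible = records[md_ok & bcva_ok & rel_ok]
    excluded = records[~(md_ok & bcva_ok & rel_ok)].copy()
    excluded["exclusion_reason"] = reasons[excluded.index]
    return eligible, excluded


# ----------------------------------------------------------- correlations


def bonferroni_threshold(alpha: float = 0.05, family_size: int = 104) -> float:
    """Per-comparison threshold for the 13-variable x 8-score screen."""
    return alpha / family_size


def spearman_matrix(features: pd.DataFrame, abilities: pd.DataFrame,
                    alpha: float = 0.05,
                    family_size: int | None = None) -> pd.DataFrame:
    """Spearman screen of every explanatory variable against every ability.

    Returns a long table (variable, response, rho, p_value, significant);
    the significance flag applies Bonferroni at ``alpha / family_size``
    where the family defaults to variables x responses.  Constant columns
    yield NaN rho with a warning.
    """
    fcols = [c for c in FEATURE_COLUMNS if c in features.columns]
    rcols = [c for c in RESPONSE_COLUMNS if c in abilities.columns]
    if not fcols or not rcols:
        raise StatsError("no recognised feature or response columns")
    n = len(features)
    if n < 10 or len(abilities) != n:
        raise StatsError("need >= 10 complete paired cases")
    if family_size is None:
        family_size = len(fcols) * len(rcols)
    thr = bonferroni_threshold(alpha, family_size)
    rows = []
    for f in fcols:
        for r in rcols:
            x = features[f].to_numpy(dtype=float)
            y = abilities[r].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                import warnings
                warnings.warn(f"constant column in ({f}, {r}); rho undefined",
                              stacklevel=2)
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(x, y)  # average ranks, t approx
            rows.append({"variable": f, "response": r, "rho": rho,
                         "p_value": p,
                         "significant": bool(p < thr) if np.isfinite(p) else False})
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = thr
    out.attrs["family_size"] = family_size
    return out


def correlation_table(long: pd.DataFrame, decimals: int = 3) -> pd.DataFrame:
    """Pivot the long Spearman screen into the wide variables x responses
    layout, with 'NS' for correlations not surviving Bonferroni."""
    wide = long.pivot(index="variable", columns="response", values="rho")
    sig = long.pivot(index="variable", columns="response", values="significant")
    disp = wide.round(decimals).astype(object)
    disp[~sig] = "NS"
    return disp


# ------------------------------------------------------------ group tests


def anova_scheffe(groups: dict[str, np.ndarray], alpha: float = 0.05):
    """One-way ANOVA across subfield mTD groups plus Scheffe contrasts.

    Returns (F, p, pairwise DataFrame of Scheffe p-values).  A pairwise
    contrast's statistic is (mean_i - mean_j)^2 / (MSW (1/n_i + 1/n_j));
    its Scheffe p is P[F_{k-1, N-k} >= stat / (k-1)].
    """
    labels = list(groups)
    arrs = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise StatsError("need >= 2 groups with >= 2 observations each")
    if np.ptp(np.concatenate(arrs)) == 0:
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(*arrs)
        if not np.isfinite(F):
            F, p = 0.0, 1.0
    k = len(arrs)
    N = sum(len(a) for a in arrs)
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrs) / (N - k)
    pair = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, gi in enumerate(labels):
        for j, gj in enumerate(labels):
            if j <= i:
                continue
            a, b = arrs[i], arrs[j]
            if msw == 0:
                pp = 1.0 if a.mean() == b.mean() else 0.0
            else:
                statv = (a.mean() - b.mean()) ** 2 / (
                    msw * (1 / len(a) + 1 / len(b)))
                pp = float(stats.f.sf(statv / (k - 1), k - 1, N - k))
            pair.loc[gi, gj] = pair.loc[gj, gi] = pp
    return float(F), float(p), pair


def paired_t(upper: np.ndarray, lower: np.ndarray):
    """Two-sided paired t-test; returns (t, p, mean difference upper-lower)."""
    upper = np.asarray(upper, dtype=float)
    lower = np.asarray(lower, dtype=float)
    if upper.shape != lower.shape or len(upper) < 2:
        raise StatsError("need equal-length paired vectors, n >= 2")
    d = upper - lower
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0, 0.0
        raise StatsError("zero variance of nonzero differences")
    t, p = stats.ttest_rel(upper, lower)
    return float(t), float(p), float(d.mean())


# ------------------------------------------------------------ descriptives


def assign_better_eye(row: pd.Series) -> str:
    """Better eye = lower logMAR BCVA; ties broken by higher MD, then OD."""
    if row["bcva_logmar_od"] != row["bcva_logmar_os"]:
        return "OD" if row["bcva_logmar_od"] < row["bcva_logmar_os"] else "OS"
    if row["md_od"] != row["md_os"]:
        return "OD" if row["md_od"] > row["md_os"] else "OS"
    return "OD"


DESCRIPTIVE_PAIRS = [
    ("refraction", "refraction_{}"),
    ("iop", "iop_{}"),
    ("md", "md_{}"),
    ("bcva_logmar", "bcva_logmar_{}"),
]


def descriptives(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD summary in the demographics-table layout.

    Per-eye quantities are re-keyed to better/worse eye using the logMAR
    convention above before summarising.  SD is the population SD of the
    sample when n = 1 (i.e. 0), else the n-1 sample SD.
    """
    rows = {}
    if "age" in cohort:
        rows["age"] = cohort["age"]
    better = cohort.apply(assign_better_eye, axis=1) \
        if {"bcva_logmar_od", "bcva_logmar_os"}.issubset(cohort.columns) \
        else pd.Series("OD", index=cohort.index)
    for name, tmpl in DESCRIPTIVE_PAIRS:
        od, os_ = tmpl.format("od"), tmpl.format("os")
        if od not in cohort or os_ not in cohort:
            continue
        vals_b = np.where(better == "OD", cohort[od], cohort[os_])
        vals_w = np.where(better == "OD", cohort[os_], cohort[od])
        rows[f"{name}_better_eye"] = pd.Series(vals_b, index=cohort.index)
        rows[f"{name}_worse_eye"] = pd.Series(vals_w, index=cohort.index)
    for extra in ("mtd_24_2", "mtd_10_2"):
        if extra in cohort:
            rows[extra] = cohort[extra]
    out = pd.DataFrame({
        "mean": {k: v.mean() for k, v in rows.items()},
        "sd": {k: (v.std(ddof=1) if len(v) > 1 else 0.0)
               for k, v in rows.items()},
        "n": {k: int(v.notna().sum()) for k, v in rows.items()},
    })
    if "sex" in cohort:
        out.attrs["sex_counts"] = cohort["sex"].value_counts().to_dict()
    return out
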