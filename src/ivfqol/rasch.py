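"""Polytomous Rasch scoring of the 30-item, 7-task VRQoL questionnaire.

Each item is answered on a three-category difficulty scale
(0 = greatly disabled, 1 = slightly disabled, 2 = not disabled).  The
rating-scale model puts person n's probability of answering category k on
item i at

    P(X_ni = k) = exp(k*(theta_n - delta_i) - cumtau_k) / Z_ni

where theta_n is person ability (logits), delta_i item difficulty,
tau_1..tau_K shared category thresholds with cumtau_k = tau_1 + .. + tau_k
and cumtau_0 = 0.  The partial-credit variant gives every item its own
thresholds.  Items are reported as easiness parameters (RADEP = -delta);
persons as the Rasch-derived person ability index (RADPAI), the maximum
likelihood theta implied by a raw score, with extreme raw scores pulled in
by half a score unit so every patient gets a finite ability.

Estimation is joint (unconditional) maximum likelihood with extreme
persons/items excluded and the identifiability constraint mean(delta) = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

TASKS = ("letters", "sentences", "walking", "going_out", "dining",
         "dressing", "miscellaneous")

#: item counts per task for the default synthetic schema (the published
#: questionnaire's item-to-task allocation is not reproduced here; this
#: allocation is plumbing that preserves the 30-item / 7-task structure)
_DEFAULT_ALLOCATION = {
    "letters": 4, "sentences": 4, "walking": 5, "going_out": 5,
    "dining": 4, "dressing": 3, "miscellaneous": 5,
}

N_CATEGORIES = 3


class RaschError(ValueError):
    pass


class InvalidCategoryError(RaschError):
    pass


class ConvergenceError(RaschError):
    def __init__(self, msg, last_fit=None):
        super().__init__(msg)
        self.last_fit = last_fit


@dataclass(frozen=True)
class QuestionnaireSchema:
    """Task structure of the questionnaire: 30 items over 7 tasks."""

    tasks: tuple[str, ...]
    items: tuple[str, ...]
    item_task: dict[str, str]
    n_categories: int = N_CATEGORIES

    def __post_init__(self):
        if set(self.item_task) != set(self.items):
            raise RaschError("item_task must cover exactly the item list")
        missing = [t for t in self.tasks if t not in set(self.item_task.values())]
        if missing:
            raise RaschError(f"tasks without items: {missing}")

    def task_items(self, task: str) -> list[str]:
        return [i for i in self.items if self.item_task[i] == task]

    @property
    def max_category(self) -> int:
        return self.n_categories - 1

    def to_yaml(self, path) -> None:
        data = {t: self.task_items(t) for t in self.tasks}
        with open(path, "w") as fh:
            yaml.safe_dump({"tasks": data, "n_categories": self.n_categories},
                           fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "QuestionnaireSchema":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        tasks = tuple(data["tasks"])
        items, item_task = [], {}
        for t, ids in data["tasks"].items():
            for i in ids:
                items.append(i)
                item_task[i] = t
        return cls(tasks=tasks, items=tuple(items), item_task=item_task,
                   n_categories=int(data.get("n_categories", N_CATEGORIES)))


def default_schema() -> QuestionnaireSchema:
    items, item_task = [], {}
    for task in TASKS:
        for j in range(1, _DEFAULT_ALLOCATION[task] + 1):
            iid = f"{task}_{j}"
            items.append(iid)
            item_task[iid] = task
    return QuestionnaireSchema(tasks=TASKS, items=tuple(items),
                               item_task=item_task)


def validate_responses(responses: pd.DataFrame,
                       schema: QuestionnaireSchema) -> pd.DataFrame:
    """Check a patients x items matrix against the schema; returns it
    reindexed to schema item order (missing allowed as NaN)."""
    missing_cols = [i for i in schema.items if i not in responses.columns]
    if missing_cols:
        raise RaschError(f"response matrix lacks items: {missing_cols[:5]} ...")
    X = responses[list(schema.items)].astype(float)
    vals = X.to_numpy()
    ok = np.isnan(vals) | np.isin(vals, np.arange(schema.n_categories))
    if not ok.all():
        bad = vals[~ok]
        raise InvalidCategoryError(
            f"responses outside categories 0..{schema.max_category}: "
            f"{np.unique(bad)[:5]}"
        )
    return X


def raw_scores(responses: pd.DataFrame, schema: QuestionnaireSchema
               ) -> tuple[pd.DataFrame, pd.Series]:
    """Task raw scores (simple addition of category scores) and patient
    raw scores (sum of task raw scores).  Missing items contribute 0."""
    X = validate_responses(responses, schema)
    n_missing = int(X.isna().to_numpy().sum())
    if n_missing:
        logger.info("raw_scores: %d missing responses treated as 0", n_missing)
    task_raw = pd.DataFrame(index=X.index)
    for t in schema.tasks:
        task_raw[t] = X[schema.task_items(t)].sum(axis=1, skipna=True).astype(int)
    patient_raw = task_raw.sum(axis=1).astype(int)
    patient_raw.name = "raw_total"
    return task_raw, patient_raw


# ------------------------------------------------------------- model core


def _category_logprobs(theta: np.ndarray, delta: np.ndarray,
                       cumtau: np.ndarray) -> np.ndarray:
    """log P[n, i, k]; cumtau is (K+1,) shared or (m, K+1) per item."""
    K1 = cumtau.shape[-1]
    k = np.arange(K1)
    eta = k[None, None, :] * (theta[:, None, None] - delta[None, :, None])
    eta = eta - np.broadcast_to(cumtau, (len(delta), K1))[None, :, :]
    return eta - logsumexp_last(eta)


def logsumexp_last(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=-1, keepdims=True)
    return m + np.log(np.exp(a - m).sum(axis=-1, keepdims=True))


def _moments(theta, delta, cumtau):
    """P, E[X], Var[X] arrays over persons x items."""
    logp = _category_logprobs(theta, delta, cumtau)
    P = np.exp(logp)
    k = np.arange(P.shape[-1])
    E = (P * k).sum(-1)
    V = (P * k**2).sum(-1) - E**2
    return P, E, V


class RatingScaleRaschModel(BaseEstimator):
    """Joint-maximum-likelihood polytomous Rasch model.

    Parameters
    ----------
    model : {"rating_scale", "partial_credit"}
        Shared category thresholds across items, or item-specific ones.
    tol : float
        Convergence tolerance on the largest absolute parameter change,
        in logits.
    max_iter : int
        Maximum alternating Newton sweeps.
    extreme_adjust : float
        Raw-score adjustment (score units) applied to zero/perfect raw
        scores before solving for ability, so every person gets a finite
        estimate.

    Attributes
    ----------
    difficulties_ : ndarray (n_items,), mean zero over estimable items
    easiness_ : ndarray, -difficulties_ (the RADEP scale)
    thresholds_ : ndarray (K,) or (n_items, K)
    theta_ : ndarray (n_persons,), finite for extreme scorers too
    loglik_ : float, joint log-likelihood at the solution
    converged_ : bool
    n_iter_ : int
    """

    def __init__(self, model: str = "rating_scale", tol: float = 1e-6,
                 max_iter: int = 200, extreme_adjust: float = 0.5):
        self.model = model
        self.tol = tol
        self.max_iter = max_iter
        self.extreme_adjust = extreme_adjust

    # -- helpers -----------------------------------------------------

    def _cumtau(self, tau: np.ndarray) -> np.ndarray:
        K = tau.shape[-1]
        if tau.ndim == 1:
            return np.concatenate([[0.0], np.cumsum(tau)])
        return np.concatenate([np.zeros((tau.shape[0], 1)),
                               np.cumsum(tau, axis=1)], axis=1)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
            raise RaschError("need at least 2 persons and 2 items")
        obs = ~np.isnan(X)
        Kmax = np.nanmax(X)
        if Kmax < 2 or len(np.unique(X[obs])) < 3:
            raise RaschError("need all 3 response categories observed")
        K = int(Kmax)  # highest category index
        n, m = X.shape

        row_raw = np.nansum(X, axis=1)
        row_max = obs.sum(axis=1) * K
        person_ok = (row_raw > 0) & (row_raw < row_max)
        col_min = np.array([np.nanmin(X[:, i]) for i in range(m)])
        col_max = np.array([np.nanmax(X[:, i]) for i in range(m)])
        item_ok = col_max > col_min
        if person_ok.sum() < 2 or item_ok.sum() < 2:
            raise RaschError(
                "degenerate data: fewer than 2 non-extreme persons or items")

        Xe = X[np.ix_(person_ok, item_ok)]
        w = (~np.isnan(Xe)).astype(float)
        Xz = np.nan_to_num(Xe)

        theta = np.zeros(person_ok.sum())
        delta = np.zeros(item_ok.sum())
        tau = (np.zeros(K) if self.model == "rating_scale"
               else np.zeros((item_ok.sum(), K)))

        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            old = np.concatenate([theta, delta, np.ravel(tau)])

            cumtau = self._cumtau(tau)
            _, E, V = _moments(theta, delta, cumtau)
            score = ((Xz - E) * w).sum(axis=1)
            info = (V * w).sum(axis=1)
            theta = theta + np.clip(score / np.maximum(info, 1e-10), -1.0, 1.0)

            cumtau = self._cumtau(tau)
            _, E, V = _moments(theta, delta, cumtau)
            score_i = ((E - Xz) * w).sum(axis=0)
            info_i = (V * w).sum(axis=0)
            delta = delta + np.clip(score_i / np.maximum(info_i, 1e-10),
                                    -1.0, 1.0)
            c = delta.mean()
            delta -= c
            theta -= c

            tau = self._update_tau(Xz, w, theta, delta, tau)

            new = np.concatenate([theta, delta, np.ravel(tau)])
            if np.max(np.abs(new - old)) < self.tol:
                converged = True
                break

        cumtau = self._cumtau(tau)
        logp = _category_logprobs(theta, delta, cumtau)
        idx = np.clip(Xz.astype(int), 0, K)
        ll = float((np.take_along_axis(logp, idx[..., None], axis=2)[..., 0]
                    * w).sum())

        full_delta = np.full(m, np.nan)
        full_delta[item_ok] = delta
        self.n_categories_ = K + 1
        self.item_estimable_ = item_ok
        self.difficulties_ = full_delta
        self.easiness_ = -full_delta
        self.thresholds_ = tau
        self.loglik_ = ll
        self.n_iter_ = it
        self.converged_ = converged

        # finite ability for everybody, from raw scores (sufficiency)
        self.theta_ = np.array([
            self.ability_from_raw(row_raw[p], item_subset=None)
            for p in range(n)
        ])
        if not converged:
            raise ConvergenceError(
                f"no convergence in {self.max_iter} iterations", last_fit=self)
        return self

    def _update_tau(self, Xz, w, theta, delta, tau):
        K = self.n_categories_ - 1 if hasattr(self, "n_categories_") \
            else (tau.shape[-1])
        cumtau = self._cumtau(tau)
        logp = _category_logprobs(theta, delta, cumtau)
        P = np.exp(logp)
        kk = np.arange(P.shape[-1])
        # indicators g_j = 1[X >= j], j = 1..K
        if tau.ndim == 1:
            grad = np.zeros(tau.shape[-1])
            H = np.zeros((tau.shape[-1], tau.shape[-1]))
            Eg = np.stack([(P[:, :, j:]).sum(-1) for j in
                           range(1, P.shape[-1])], axis=-1)  # n,m,K
            gx = np.stack([(Xz >= j).astype(float) for j in
                           range(1, P.shape[-1])], axis=-1)
            grad = ((Eg - gx) * w[..., None]).sum(axis=(0, 1))
            # Hessian of -loglik wrt tau: sum of Cov(g_j, g_l)
            for j in range(tau.shape[-1]):
                for l in range(tau.shape[-1]):
                    Egl = (P[:, :, max(j, l) + 1:]).sum(-1)  # E[g_j g_l]
                    cov = Egl - Eg[..., j] * Eg[..., l]
                    H[j, l] = (cov * w).sum()
            step = np.linalg.solve(H + 1e-10 * np.eye(len(H)), grad)
            return tau + np.clip(step, -1.0, 1.0)
        # partial credit: independent K-vector per item
        new = tau.copy()
        Eg = np.stack([(P[:, :, j:]).sum(-1) for j in
                       range(1, P.shape[-1])], axis=-1)
        gx = np.stack([(Xz >= j).astype(float) for j in
                       range(1, P.shape[-1])], axis=-1)
        for i in range(tau.shape[0]):
            grad = ((Eg[:, i, :] - gx[:, i, :]) * w[:, i, None]).sum(axis=0)
            H = np.zeros((tau.shape[1], tau.shape[1]))
            for j in range(tau.shape[1]):
                for l in range(tau.shape[1]):
                    Egl = (P[:, i, max(j, l) + 1:]).sum(-1)
                    cov = Egl - Eg[:, i, j] * Eg[:, i, l]
                    H[j, l] = (cov * w[:, i]).sum()
            step = np.linalg.solve(H + 1e-10 * np.eye(len(H)), grad)
            new[i] = tau[i] + np.clip(step, -1.0, 1.0)
        return new

    # -- scoring -----------------------------------------------------

    def _subset_params(self, item_subset):
        delta = self.difficulties_
        if item_subset is None:
            item_subset = np.arange(len(delta))
        item_subset = np.asarray(item_subset)
        d = delta[item_subset]
        if np.isnan(d).any():
            # items with constant observed columns carry no estimate; score
            # them at average difficulty so raw-score ranges stay intact
            logger.warning("scoring %d inestimable item(s) at difficulty 0",
                           int(np.isnan(d).sum()))
            d = np.nan_to_num(d)
        if self.model == "partial_credit":
            full = np.zeros((len(delta), self.thresholds_.shape[1]))
            full[self.item_estimable_] = self.thresholds_
            cumtau = self._cumtau(full[item_subset])
        else:
            cumtau = self._cumtau(self.thresholds_)
        return d, cumtau

    def expected_score(self, theta: float, item_subset=None) -> float:
        """Sum over the item subset of E[X_i | theta]."""
        d, cumtau = self._subset_params(item_subset)
        _, E, _ = _moments(np.array([theta]), d, cumtau)
        return float(E.sum())

    def ability_from_raw(self, raw: float, item_subset=None) -> float:
        """ML ability for a raw score on an item subset (RADPAI, logits).

        The raw score is sufficient for theta, so this solves
        sum_i E[X_i | theta] = raw.  Extreme scores (0 or the maximum)
        are first pulled in by ``extreme_adjust`` score units.
        """
        d, cumtau = self._subset_params(item_subset)
        max_raw = len(d) * (self.n_categories_ - 1)
        if raw < 0 or raw > max_raw:
            raise RaschError(f"raw score {raw} outside [0, {max_raw}]")
        if raw <= 0:
            raw = self.extreme_adjust
        elif raw >= max_raw:
            raw = max_raw - self.extreme_adjust

        def f(t):
            _, E, _ = _moments(np.array([t]), d, cumtau)
            return float(E.sum()) - raw

        lo, hi = -10.0, 10.0
        while f(lo) > 0 and lo > -700:
            lo *= 2
        while f(hi) < 0 and hi < 700:
            hi *= 2
        return float(brentq(f, lo, hi, xtol=1e-10))


# ----------------------------------------------------------- fit wrapper


@dataclass
class RaschFit:
    """Fitted item bank plus raw-score-to-ability lookup tables."""

    schema: QuestionnaireSchema
    estimator: RatingScaleRaschModel
    easiness: pd.Series = field(init=False)   # RADEP per item (logits)
    lookup: dict[str, dict[int, float]] = field(init=False)

    def __post_init__(self):
        self.easiness = pd.Series(self.estimator.easiness_,
                                  index=list(self.schema.items), name="radep")
        items = list(self.schema.items)
        self.lookup = {}
        for task in self.schema.tasks:
            sub = [items.index(i) for i in self.schema.task_items(task)]
            mx = len(sub) * self.schema.max_category
            self.lookup[task] = {
                r: self.estimator.ability_from_raw(r, sub)
                for r in range(mx + 1)
            }
        mx = len(items) * self.schema.max_category
        self.lookup["total"] = {
            r: self.estimator.ability_from_raw(r, None) for r in range(mx + 1)
        }

    @property
    def thresholds(self) -> np.ndarray:
        return self.estimator.thresholds_

    @property
    def converged(self) -> bool:
        return self.estimator.converged_

    @property
    def loglik(self) -> float:
        return self.estimator.loglik_

    def summary(self) -> dict:
        return {
            "model": self.estimator.model,
            "converged": bool(self.converged),
            "n_iter": int(self.estimator.n_iter_),
            "loglik": float(self.loglik),
            "radep": {k: float(v) for k, v in self.easiness.items()},
            "thresholds": np.asarray(self.thresholds).tolist(),
        }


def fit_rasch(responses: pd.DataFrame, schema: QuestionnaireSchema | None = None,
              model: str = "rating_scale", tol: float = 1e-6,
              max_iter: int = 200) -> RaschFit:
    if schema is None:
        schema = default_schema()
    X = validate_responses(responses, schema)
    est = RatingScaleRaschModel(model=model, tol=tol, max_iter=max_iter)
    est.fit(X.to_numpy())
    return RaschFit(schema=schema, estimator=est)


def ability_from_raw(fit: RaschFit, raw: int, task: str | None = None) -> float:
    """RADPAI for a raw score, on one task's items or on all items."""
    key = task if task is not None else "total"
    return fit.lookup[key][int(raw)]


def score_cohort(responses: pd.DataFrame,
                 schema: QuestionnaireSchema | None = None,
                 model: str = "rating_scale",
                 fit: RaschFit | None = None) -> pd.DataFrame:
    """Per-patient ability table: raw scores and RADPAI per task + overall."""
    if schema is None:
        schema = fit.schema if fit is not None else default_schema()
    if fit is None:
        fit = fit_rasch(responses, schema, model=model)
    task_raw, patient_raw = raw_scores(responses, schema)
    out = pd.DataFrame(index=responses.index)
    for t in schema.tasks:
        out[f"raw_{t}"] = task_raw[t]
        out[f"radpai_{t}"] = task_raw[t].map(fit.lookup[t])
    out["raw_total"] = patient_raw
    out["radpai_total"] = patient_raw.map(fit.lookup["total"])
    return out
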