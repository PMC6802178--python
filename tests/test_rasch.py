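"""Questionnaire schema, raw scoring and rating-scale Rasch estimation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ivfqol.rasch import (
    InvalidCategoryError,
    QuestionnaireSchema,
    RaschError,
    RatingScaleRaschModel,
    ability_from_raw,
    default_schema,
    fit_rasch,
    raw_scores,
    score_cohort,
)
from ivfqol.synthetic_data import SyntheticCohortConfig, simulate_cohort


@pytest.fixture(scope="module")
def schema():
    return default_schema()


@pytest.fixture(scope="module")
def small_cohort():
    cfg = SyntheticCohortConfig(n_patients=250)
    return simulate_cohort(cfg, seed=7)


class TestSchema:
    def test_default_structure(self, schema):
        assert len(schema.items) == 30
        assert len(schema.tasks) == 7
        assert schema.n_categories == 3
        assert sum(len(schema.task_items(t)) for t in schema.tasks) == 30

    def test_yaml_roundtrip(self, tmp_path, schema):
        path = tmp_path / "schema.yaml"
        schema.to_yaml(path)
        back = QuestionnaireSchema.from_yaml(path)
        assert back.items == schema.items
        assert back.tasks == schema.tasks
        assert back.item_task == schema.item_task

    def test_item_task_mismatch_rejected(self):
        with pytest.raises(RaschError):
            QuestionnaireSchema(tasks=("a",), items=("i1", "i2"),
                                item_task={"i1": "a"})


class TestRawScores:
    def test_all_not_disabled_gives_60(self, schema):
        resp = pd.DataFrame(2, index=["p1"], columns=list(schema.items))
        task_raw, patient_raw = raw_scores(resp, schema)
        assert patient_raw.loc["p1"] == 60
        assert all(task_raw.loc["p1", t] == 2 * len(schema.task_items(t))
                   for t in schema.tasks)

    def test_all_greatly_disabled_gives_0(self, schema):
        resp = pd.DataFrame(0, index=["p1"], columns=list(schema.items))
        _, patient_raw = raw_scores(resp, schema)
        assert patient_raw.loc["p1"] == 0

    def test_mixed_matrix_matches_manual_sums(self, schema):
        rng = np.random.default_rng(5)
        resp = pd.DataFrame(rng.integers(0, 3, size=(4, 30)),
                            index=list("abcd"), columns=list(schema.items))
        task_raw, patient_raw = raw_scores(resp, schema)
        for pat, t in itertools.product("abcd", schema.tasks):
            manual = sum(resp.loc[pat, i] for i in schema.task_items(t))
            assert task_raw.loc[pat, t] == manual
        assert (patient_raw == resp.sum(axis=1)).all()

    def test_invalid_category_rejected(self, schema):
        resp = pd.DataFrame(2, index=["p1"], columns=list(schema.items))
        resp.iloc[0, 0] = 3
        with pytest.raises(InvalidCategoryError):
            raw_scores(resp, schema)


def _simulate_rsm(n, delta, tau, rng, theta=None):
    """Independent simulator for the rating-scale model (used as oracle)."""
    if theta is None:
        theta = rng.normal(0, 1.2, size=n)
    cumtau = np.concatenate([[0.0], np.cumsum(tau)])
    k = np.arange(len(cumtau))
    X = np.empty((n, len(delta)), dtype=int)
    for i, d in enumerate(delta):
        eta = k[None, :] * (theta[:, None] - d) - cumtau[None, :]
        P = np.exp(eta - eta.max(1, keepdims=True))
        P /= P.sum(1, keepdims=True)
        X[:, i] = (P.cumsum(1) < rng.random(n)[:, None]).sum(1)
    return X, theta


class TestFit:
    def test_identical_items_equal_easiness(self):
        rng = np.random.default_rng(0)
        X, _ = _simulate_rsm(300, np.array([-0.5, 0.5]), [-0.7, 0.7], rng)
        X = np.column_stack([X, X[:, 0]])  # duplicate first item
        m = RatingScaleRaschModel().fit(X)
        assert m.easiness_[0] == pytest.approx(m.easiness_[2], abs=1e-6)

    def test_mean_difficulty_constraint(self):
        rng = np.random.default_rng(1)
        X, _ = _simulate_rsm(200, np.linspace(-1, 1, 5), [-0.5, 0.5], rng)
        m = RatingScaleRaschModel().fit(X)
        assert np.nanmean(m.difficulties_) == pytest.approx(0.0, abs=1e-8)

    def test_parameter_recovery(self):
        """Known item bank at n = 500: high correlation, small RMSE."""
        rng = np.random.default_rng(42)
        delta = np.linspace(-1.5, 1.5, 30)
        X, theta = _simulate_rsm(500, delta, [-0.8, 0.8], rng)
        m = RatingScaleRaschModel().fit(X)
        r = np.corrcoef(delta, m.difficulties_)[0, 1]
        rmse = float(np.sqrt(np.mean((m.difficulties_ - delta) ** 2)))
        assert r >= 0.95
        assert rmse <= 0.2

    def test_tiny_case_matches_grid_search_oracle(self):
        """JML solution at least as good as a dense grid search over
        (difficulties, thresholds, abilities) on a 3-patient, 2-item case
        with no extreme scorers."""
        X = np.array([[0, 1], [1, 2], [2, 0]], dtype=float)
        m = RatingScaleRaschModel(tol=1e-9, max_iter=500).fit(X)
        grid = np.arange(-3.0, 3.01, 0.25)
        th_grid = np.arange(-4.0, 4.01, 0.25)
        k = np.arange(3)
        best = -np.inf
        for d1 in grid:
            delta = np.array([d1, -d1])  # mean-zero constraint
            for t1 in grid:
                for t2 in grid:
                    cumtau = np.array([0.0, t1, t1 + t2])
                    eta = (k[None, None, :]
                           * (th_grid[:, None, None] - delta[None, :, None])
                           - cumtau[None, None, :])
                    mx = eta.max(-1, keepdims=True)
                    logZ = np.log(np.exp(eta - mx).sum(-1)) + mx.squeeze(-1)
                    ll = 0.0
                    for p in range(3):  # profile out each person's ability
                        per_theta = sum(
                            eta[:, i, int(X[p, i])] - logZ[:, i]
                            for i in range(2))
                        ll += per_theta.max()
                    best = max(best, ll)
        assert m.loglik_ >= best - 0.05

    def test_degenerate_data_rejected(self):
        with pytest.raises(RaschError):
            RatingScaleRaschModel().fit(np.array([[0, 0], [2, 2]]))
        with pytest.raises(RaschError):
            RatingScaleRaschModel().fit(np.array([[0, 1], [0, 1], [0, 1]]))

    def test_partial_credit_variant_recovers(self):
        rng = np.random.default_rng(3)
        delta = np.linspace(-1, 1, 8)
        X, _ = _simulate_rsm(400, delta, [-0.6, 0.6], rng)
        m = RatingScaleRaschModel(model="partial_credit").fit(X)
        assert np.corrcoef(delta, m.difficulties_)[0, 1] >= 0.9
        assert m.thresholds_.shape == (8, 2)


class TestAbilityFromRaw:
    @pytest.fixture
    def symmetric_model(self):
        m = RatingScaleRaschModel()
        m.n_categories_ = 3
        m.difficulties_ = np.zeros(4)
        m.easiness_ = np.zeros(4)
        m.thresholds_ = np.array([-0.9, 0.9])
        m.item_estimable_ = np.ones(4, dtype=bool)
        return m

    def test_half_max_raw_gives_zero_theta(self, symmetric_model):
        assert symmetric_model.ability_from_raw(4) == pytest.approx(0.0,
                                                                    abs=1e-8)

    def test_strictly_increasing_in_raw(self, symmetric_model):
        thetas = [symmetric_model.ability_from_raw(r) for r in range(9)]
        assert all(b > a for a, b in zip(thetas, thetas[1:]))

    def test_matches_bisection_oracle(self):
        """Independent bisection on an independently coded expected score."""
        delta = np.array([-0.4, 0.1, 0.4])
        symmetric_model = RatingScaleRaschModel()
        symmetric_model.n_categories_ = 3
        symmetric_model.thresholds_ = np.array([-0.9, 0.9])
        symmetric_model.difficulties_ = delta
        symmetric_model.item_estimable_ = np.ones(3, dtype=bool)

        def expected(theta):
            cumtau = np.array([0.0, -0.9, 0.0])
            tot = 0.0
            for d in delta:
                eta = np.arange(3) * (theta - d) - cumtau
                p = np.exp(eta - eta.max())
                p /= p.sum()
                tot += (p * np.arange(3)).sum()
            return tot

        for raw in [1, 2, 3, 4, 5]:
            lo, hi = -20.0, 20.0
            for _ in range(60):
                mid = (lo + hi) / 2
                if expected(mid) < raw:
                    lo = mid
                else:
                    hi = mid
            assert symmetric_model.ability_from_raw(raw) == \
                pytest.approx((lo + hi) / 2, abs=1e-6)

    def test_out_of_range_raw(self, symmetric_model):
        with pytest.raises(RaschError):
            symmetric_model.ability_from_raw(-1)
        with pytest.raises(RaschError):
            symmetric_model.ability_from_raw(99)


@pytest.fixture(scope="module")
def scored(small_cohort):
    fit = fit_rasch(small_cohort.responses)
    table = score_cohort(small_cohort.responses, fit=fit)
    return small_cohort, fit, table


class TestScoreCohort:
    def test_raw_score_sufficiency(self, scored):
        _, _, table = scored
        for t in ("dining", "letters", "walking"):
            grouped = table.groupby(f"raw_{t}")[f"radpai_{t}"].nunique()
            assert (grouped == 1).all()

    def test_monotone_in_raw(self, scored):
        _, _, table = scored
        sub = table.drop_duplicates("raw_total").sort_values("raw_total")
        assert sub["radpai_total"].is_monotonic_increasing

    def test_identical_patients_identical_rows(self, schema):
        rng = np.random.default_rng(8)
        base = rng.integers(0, 3, size=30)
        resp = pd.DataFrame([base, base, rng.integers(0, 3, size=30),
                             rng.integers(0, 3, size=30)] * 10,
                            columns=list(schema.items))
        table = score_cohort(resp, schema)
        assert table.iloc[0].equals(table.iloc[1])

    def test_extreme_patient_finite_and_top(self, schema):
        rng = np.random.default_rng(9)
        resp = pd.DataFrame(rng.integers(0, 3, size=(60, 30)),
                            columns=list(schema.items))
        resp.iloc[0] = 2  # perfect scorer
        table = score_cohort(resp, schema)
        assert np.isfinite(table["radpai_total"]).all()
        assert table["radpai_total"].iloc[0] == table["radpai_total"].max()

    def test_ability_recovery_rank_correlation(self, scored):
        from scipy.stats import spearmanr

        cohort, _, table = scored
        true_overall = cohort.theta.mean(axis=1)
        rho = spearmanr(true_overall, table["radpai_total"]).statistic
        assert rho >= 0.9

    def test_ability_from_raw_wrapper(self, scored):
        _, fit, table = scored
        row = table.iloc[0]
        assert ability_from_raw(fit, int(row["raw_dining"]), "dining") == \
            pytest.approx(row["radpai_dining"])


def test_translation_identifiability():
    """Shifting all person and item parameters together leaves category
    probabilities unchanged; the mean-difficulty constraint pins the scale,
    so refitting responses simulated from shifted parameters recovers the
    centred difficulties."""
    delta = np.linspace(-1, 1, 10)
    theta = np.random.default_rng(12).normal(0, 1.2, size=400)
    X1, _ = _simulate_rsm(400, delta, [-0.8, 0.8],
                          np.random.default_rng(13), theta=theta)
    X2, _ = _simulate_rsm(400, delta + 2.0, [-0.8, 0.8],
                          np.random.default_rng(13), theta=theta + 2.0)
    assert np.array_equal(X1, X2)  # identical probabilities -> identical draws
    m = RatingScaleRaschModel().fit(X1)
    assert np.nanmean(m.difficulties_) == pytest.approx(0.0, abs=1e-8)
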