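"""AIPW score tables, IPW/DM/DR policy values, and nuisance selection."""

import numpy as np
import pytest

from pnn import (
    CounterfactualTable,
    ObservationalDataset,
    OutcomeModel,
    PositivityError,
    PropensityModel,
    TreatmentSet,
    dm_value,
    dr_policy_advantage,
    dr_policy_value,
    dr_score_table,
    fit_nuisance,
    ipw_value,
    observed_policy,
    score_table,
)
from .conftest import make_table


class ConstantPropensity:
    """Aligned probabilities, identical for every row."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict_proba(self, X):
        return np.tile(self.probs, (len(X), 1))


class ConstantOutcome:
    def __init__(self, mus):
        self.mus = np.asarray(mus, dtype=float)

    def predict(self, X):
        return np.tile(self.mus, (len(X), 1))


def two_point_dataset(y=(1.0, 3.0), t=(0, 1)):
    return ObservationalDataset(
        covariates=np.array([[0.0], [1.0]]),
        treatments=np.array(t),
        outcomes=np.array(y),
        treatment_set=TreatmentSet((0, 1)),
    )


class TestDrScoreTable:
    def test_observed_arm_gets_the_aipw_correction(self):
        # y=2, mu=1.5, p=0.5, observed arm -> psi = 1.5 + (2-1.5)/0.5 = 2.5
        data = ObservationalDataset(
            covariates=np.zeros((1, 1)),
            treatments=np.array([1]),
            outcomes=np.array([2.0]),
            treatment_set=TreatmentSet((0, 1)),
        )
        table = dr_score_table(
            data, ConstantPropensity([0.5, 0.5]), ConstantOutcome([1.5, 1.5])
        )
        assert table.psi[0, 1] == pytest.approx(2.5)
        # unobserved arm keeps the plain regression estimate
        assert table.psi[0, 0] == pytest.approx(1.5)

    def test_zero_outcome_model_reduces_to_ipw_terms(self):
        data = two_point_dataset()
        table = dr_score_table(
            data, ConstantPropensity([0.5, 0.5]), ConstantOutcome([0.0, 0.0])
        )
        n = np.arange(2)
        expected = np.zeros((2, 2))
        expected[n, data.treatment_indices] = data.outcomes / 0.5
        assert np.allclose(table.psi, expected)

    def test_clipping_monotonicity(self):
        # raising the floor never increases |psi - mu|
        rng = np.random.default_rng(0)
        n = 30
        data = ObservationalDataset(
            covariates=rng.standard_normal((n, 2)),
            treatments=rng.integers(0, 2, n),
            outcomes=rng.standard_normal(n),
            treatment_set=TreatmentSet((0, 1)),
        )

        class Skewed:
            def predict_proba(self, X):
                p1 = 0.001 + 0.9 * (X[:, 0] > 0)
                return np.column_stack([1 - p1, p1])

        mu_model = ConstantOutcome([0.3, -0.2])
        low = dr_score_table(data, Skewed(), mu_model, clip_floor=0.01)
        high = dr_score_table(data, Skewed(), mu_model, clip_floor=0.2)
        assert np.all(
            np.abs(high.psi - high.mu) <= np.abs(low.psi - low.mu) + 1e-12
        )

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        n = 20
        X = rng.standard_normal((n, 2))
        t = rng.integers(0, 2, n)
        y = rng.standard_normal(n)
        perm = rng.permutation(n)
        ts = TreatmentSet((0, 1))
        prop, out = ConstantPropensity([0.4, 0.6]), ConstantOutcome([0.1, 0.9])
        base = dr_score_table(ObservationalDataset(X, t, y, treatment_set=ts), prop, out)
        permuted = dr_score_table(
            ObservationalDataset(X[perm], t[perm], y[perm], treatment_set=ts), prop, out
        )
        assert np.allclose(base.psi[perm], permuted.psi)


class TestPolicyValues:
    def test_ipw_hand_examples(self):
        data = two_point_dataset()
        prop = ConstantPropensity([0.5, 0.5])
        # agree with both observed arms: (1/2)(1/0.5 + 3/0.5) = 4
        assert ipw_value(data, [0, 1], prop) == pytest.approx(4.0)
        # disagree with every observed arm: 0
        assert ipw_value(data, [1, 0], prop) == pytest.approx(0.0)

    def test_ipw_single_row(self):
        data = ObservationalDataset(
            covariates=np.zeros((1, 1)),
            treatments=np.array([0]),
            outcomes=np.array([2.0]),
            treatment_set=TreatmentSet((0, 1)),
        )
        assert ipw_value(data, [0], ConstantPropensity([0.25, 0.75])) == pytest.approx(8.0)

    def test_dm_constant_model_ignores_the_policy(self):
        data = two_point_dataset()
        model = ConstantOutcome([7.0, 7.0])
        assert dm_value(data, [0, 0], model) == pytest.approx(7.0)
        assert dm_value(data, [1, 0], model) == pytest.approx(7.0)

    def test_dm_mean_of_selected_estimates(self):
        data = two_point_dataset()
        assert dm_value(data, [0, 1], ConstantOutcome([1.0, 3.0])) == pytest.approx(2.0)

    def test_dm_unknown_label_rejected(self):
        data = two_point_dataset()
        with pytest.raises(KeyError):
            dm_value(data, [0, 2], ConstantOutcome([1.0, 3.0]))

    def test_dr_value_selects_by_assignment(self):
        table = make_table([[1.0, 5.0], [2.0, 0.0]])
        assert dr_policy_value(table, [1, 0]) == pytest.approx(3.5)

    def test_dr_value_policy_invariant_when_scores_tie(self):
        table = make_table([[2.0, 2.0], [0.5, 0.5]])
        assert dr_policy_value(table, [0, 0]) == dr_policy_value(table, [1, 1])

    def test_dr_value_recovers_sample_mean_with_interpolating_mu(self):
        # mu that interpolates the observed outcomes kills the correction
        rng = np.random.default_rng(1)
        n = 25
        data = ObservationalDataset(
            covariates=rng.standard_normal((n, 1)),
            treatments=rng.integers(0, 2, n),
            outcomes=rng.standard_normal(n),
            treatment_set=TreatmentSet((0, 1)),
        )

        class Interpolating:
            def predict(self, X):
                # exact lookup by row identity
                mu = np.zeros((len(X), 2))
                mu[np.arange(n), data.treatment_indices] = data.outcomes
                return mu

        table = dr_score_table(data, ConstantPropensity([0.5, 0.5]), Interpolating())
        value = dr_policy_value(table, observed_policy(data))
        assert value == pytest.approx(float(data.outcomes.mean()))

    def test_advantage_zero_against_itself_and_antisymmetric(self):
        table = make_table([[1.0, 5.0], [2.0, 0.0]])
        X = np.zeros((2, 1))
        assert dr_policy_advantage(table, [1, 0], [1, 0], X) == 0.0
        fwd = dr_policy_advantage(table, [1, 0], [0, 0], X)
        rev = dr_policy_advantage(table, [0, 0], [1, 0], X)
        assert fwd == pytest.approx(2.0)
        assert rev == pytest.approx(-fwd)


class TestScoreTableVariants:
    def test_table_methods_agree_with_value_estimators(self):
        rng = np.random.default_rng(7)
        n = 40
        data = ObservationalDataset(
            covariates=rng.standard_normal((n, 2)),
            treatments=rng.integers(0, 2, n),
            outcomes=rng.standard_normal(n),
            treatment_set=TreatmentSet((0, 1)),
        )
        prop = ConstantPropensity([0.3, 0.7])
        out = ConstantOutcome([0.2, -0.4])
        policy = rng.integers(0, 2, n)
        ipw_tab = score_table(data, prop=prop, method="ipw")
        assert dr_policy_value(ipw_tab, policy) == pytest.approx(
            ipw_value(data, policy, prop)
        )
        dm_tab = score_table(data, out=out, method="dm")
        assert dr_policy_value(dm_tab, policy) == pytest.approx(
            dm_value(data, policy, out)
        )

    def test_csv_round_trip(self, tmp_path):
        import pnn.io as io

        table = make_table([[1.0, 5.0], [2.0, 0.0]])
        path = tmp_path / "table.csv"
        io.write_table(table, path)
        loaded = io.load_table(path)
        assert np.allclose(loaded.psi, table.psi)
        assert loaded.treatment_set.labels == table.treatment_set.labels


class TestNuisanceSelection:
    @staticmethod
    def linear_world(n=120, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 2))
        t = rng.integers(0, 2, n)
        y = 1.5 * X[:, 0] - X[:, 1] + 0.5 * t + rng.normal(0, 0.1, n)
        return ObservationalDataset(X, t, y, treatment_set=TreatmentSet((0, 1)))

    def test_single_candidates_are_selected_unopposed(self):
        from sklearn.dummy import DummyRegressor
        from sklearn.linear_model import LogisticRegression

        data = self.linear_world()
        prop, out, report = fit_nuisance(
            data, [LogisticRegression()], [DummyRegressor()], n_folds=3
        )
        assert len(report[report.role == "propensity"]) == 1
        assert len(report[report.role == "outcome"]) == 1
        probs = prop.predict_proba(data.covariates)
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_true_model_class_beats_constant_predictor(self):
        from sklearn.dummy import DummyRegressor
        from sklearn.linear_model import LinearRegression, LogisticRegression

        data = self.linear_world(seed=3)
        _, out, report = fit_nuisance(
            data,
            [LogisticRegression()],
            [LinearRegression(), DummyRegressor()],
            n_folds=5,
        )
        scores = report[report.role == "outcome"].score.to_numpy()
        assert scores[0] < scores[1]  # linear CV-RMSE beats constant
        assert isinstance(out.estimators[0], LinearRegression)

    def test_missing_arm_raises_positivity_error(self):
        from sklearn.linear_model import LinearRegression, LogisticRegression

        rng = np.random.default_rng(0)
        data = ObservationalDataset(
            covariates=rng.standard_normal((30, 2)),
            treatments=np.zeros(30, dtype=int),
            outcomes=rng.standard_normal(30),
            treatment_set=TreatmentSet((0, 1)),
        )
        with pytest.raises(PositivityError):
            fit_nuisance(data, [LogisticRegression()], [LinearRegression()], n_folds=3)

    def test_propensity_rows_are_probability_vectors(self):
        from sklearn.linear_model import LogisticRegression

        data = self.linear_world(seed=5)
        model = PropensityModel.fit(LogisticRegression(), data)
        probs = model.predict_proba(data.covariates)
        assert probs.shape == (data.n, 2)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert (probs > 0).all()
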