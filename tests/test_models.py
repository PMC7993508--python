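"""Learners, the composite selection loss, and evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ifpscore.features import split_dataset
from ifpscore.interactions import N_CELLS
from ifpscore.models import (
    DNNConfig,
    DeepAffinityNetwork,
    RFConfig,
    RandomForestAffinity,
    _DenseNet,
    baseline_null,
    composite_loss,
    count_dnn_parameters,
    evaluation_report,
    mae,
    pcc,
    rmse,
    train_dnn,
    train_rf,
)
from ifpscore.synthetic import SyntheticDatasetSpec, make_synthetic_dataset


def linear_recovery_dataset(n=500, sigma=0.1, seed=42):
    """Labels = 3 * (first informative fingerprint cell) + noise."""
    w = np.zeros(N_CELLS)
    w[0] = 3.0
    return make_synthetic_dataset(
        SyntheticDatasetSpec(n=n, weights=w, noise_sigma=sigma, seed=seed))


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.5])
        rep = evaluation_report(y, y)
        assert rep.rmse == 0 and rep.mae == 0 and rep.pcc == pytest.approx(1.0)

    def test_constant_shift(self):
        y = np.array([1.0, 2.0, 3.5, 0.2])
        rep = evaluation_report(y, y + 1)
        assert rep.rmse == pytest.approx(1.0)
        assert rep.mae == pytest.approx(1.0)
        assert rep.pcc == pytest.approx(1.0)

    def test_worked_two_point_example(self):
        assert rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(25 / 2))
        assert mae([0, 0], [3, 4]) == pytest.approx(3.5)

    def test_agreement_with_independent_formulas(self):
        from scipy import stats
        from sklearn.metrics import mean_absolute_error, mean_squared_error

        rng = np.random.default_rng(8)
        for _ in range(10):
            y = rng.normal(size=60)
            p = rng.normal(size=60)
            assert abs(rmse(y, p) - np.sqrt(mean_squared_error(y, p))) < 1e-10
            assert abs(mae(y, p) - mean_absolute_error(y, p)) < 1e-10
            r, pv = pcc(y, p)
            assert abs(r - np.corrcoef(y, p)[0, 1]) < 1e-10
            assert abs(pv - stats.pearsonr(y, p).pvalue) < 1e-12

    def test_pcc_shift_scale_invariance(self):
        rng = np.random.default_rng(3)
        y, p = rng.normal(size=50), rng.normal(size=50)
        r0, _ = pcc(y, p)
        r1, _ = pcc(y, 2.5 * p + 7.0)
        assert r0 == pytest.approx(r1, abs=1e-12)

    def test_correlations_absent_when_undefined(self):
        rep = evaluation_report([1.0, 2.0], [3.0, 3.0])
        assert rep.pcc is None and rep.spearman is None
        assert rep.rmse > 0


class TestCompositeLoss:
    def test_perfect_fit_is_zero(self):
        for alpha in (0.0, 0.3, 1.0):
            assert composite_loss(1.0, 0.0, alpha) == 0.0

    def test_alpha_one_ignores_rmse(self):
        assert composite_loss(0.5, 123.0, 1.0) == pytest.approx(0.5)

    def test_worked_example(self):
        assert composite_loss(0.8, 1.5, 0.7) == pytest.approx(0.59)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(-1, 1), st.floats(0, 10))
    def test_linear_in_alpha_with_correct_endpoints(self, alpha, r, e):
        lo = composite_loss(r, e, 0.0)
        hi = composite_loss(r, e, 1.0)
        assert lo == pytest.approx(e)
        assert hi == pytest.approx(1 - r)
        assert composite_loss(r, e, alpha) == pytest.approx(
            (1 - alpha) * lo + alpha * hi, abs=1e-9)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            composite_loss(0.5, 1.0, 1.5)


class TestParameterCount:
    @pytest.mark.parametrize("dim,expected", [
        (140, 159_601), (280, 215_601), (2422, 1_072_401), (2562, 1_128_401),
    ])
    def test_printed_dimension_table(self, dim, expected):
        assert count_dnn_parameters(dim) == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_constructed_network(self, seed):
        rng = np.random.default_rng(seed)
        for dim in rng.integers(1, 3000, size=4):
            net = _DenseNet(int(dim), dropout=0.1, rng=rng)
            assert net.n_parameters() == count_dnn_parameters(int(dim))

    def test_invalid_dimension(self):
        with pytest.raises(ValueError):
            count_dnn_parameters(0)


class TestRandomForest:
    def test_parameter_recovery_on_linear_data(self):
        ds = linear_recovery_dataset()
        train, test = split_dataset(ds, 0.8, seed=1)
        rep = train_rf(train, RFConfig(n_estimators=100, random_state=1)
                       ).evaluate(test)
        assert rep.pcc >= 0.9

    def test_constant_labels_predict_the_constant(self):
        ds = make_synthetic_dataset(SyntheticDatasetSpec(n=40, seed=2))
        ds.y[:] = 5.5
        with pytest.warns(UserWarning):
            res = RandomForestAffinity(ds, RFConfig(n_estimators=10)).fit()
        assert np.allclose(res.predict(ds.X), 5.5)

    def test_determinism_same_config_same_predictions(self):
        ds = make_synthetic_dataset(SyntheticDatasetSpec(n=80, seed=3))
        tr, te = split_dataset(ds, 0.8, seed=2)
        cfg = RFConfig(n_estimators=30, random_state=7)
        a = train_rf(tr, cfg).predict(te.X)
        b = train_rf(tr, cfg).predict(te.X)
        assert np.array_equal(a, b)

    def test_single_tree_ensemble_degeneracy(self):
        ds = make_synthetic_dataset(SyntheticDatasetSpec(n=60, seed=5))
        res = train_rf(ds, RFConfig(n_estimators=1, random_state=0))
        lone = res.forest.estimators_[0].predict(ds.X)
        assert np.allclose(res.predict(ds.X), lone)

    def test_too_few_rows(self):
        ds = make_synthetic_dataset(SyntheticDatasetSpec(n=5, seed=1))
        with pytest.raises(ValueError):
            RandomForestAffinity(ds)

    def test_summary_mentions_configuration(self):
        ds = make_synthetic_dataset(SyntheticDatasetSpec(n=40, seed=6))
        text = train_rf(ds, RFConfig(n_estimators=10)).summary()
        assert "n_estimators:  10" in text


class TestBaseline:
    def test_constant_labels(self):
        tr = make_synthetic_dataset(SyntheticDatasetSpec(n=20, seed=0))
        te = make_synthetic_dataset(SyntheticDatasetSpec(n=10, seed=1))
        tr.y[:] = 2.0
        te.y[:] = 2.0
        rep = baseline_null(tr, te)
        assert rep.rmse == 0.0
        assert rep.pcc is None  # constant predictions: correlation undefined

    def test_mean_predictor_error(self):
        tr = make_synthetic_dataset(SyntheticDatasetSpec(n=2, seed=0))
        te = make_synthetic_dataset(SyntheticDatasetSpec(n=2, seed=1))
        tr.y[:] = [0.0, 2.0]
        te.y[:] = [0.0, 2.0]
        assert baseline_null(tr, te).rmse == pytest.approx(1.0)


@pytest.fixture(scope="module")
def fitted():
    ds = linear_recovery_dataset(n=300, seed=10)
    tr, va = split_dataset(ds, 0.8, seed=1)
    return train_dnn(tr, va, DNNConfig(alpha=0.7, max_epochs=20, seed=0))


class TestDeepNetwork:
    def test_selected_epoch_minimizes_validation_loss(self, fitted):
        losses = fitted.history["valid_loss"].to_numpy()
        assert losses[fitted.best_epoch] == losses.min()

    def test_alpha_zero_reduces_to_min_validation_rmse(self):
        ds = linear_recovery_dataset(n=300, seed=11)
        tr, va = split_dataset(ds, 0.8, seed=2)
        res = train_dnn(tr, va, DNNConfig(alpha=0.0, max_epochs=15, seed=1))
        rmses = res.history["valid_rmse"].to_numpy()
        assert res.best_epoch == int(np.argmin(rmses))
        assert np.allclose(res.history["valid_loss"], rmses)

    def test_parameter_audit(self, fitted):
        assert fitted.n_parameters == count_dnn_parameters(N_CELLS)

    def test_learns_the_linear_signal(self, fitted):
        ds = linear_recovery_dataset(n=200, seed=12)
        rep = fitted.evaluate(ds)
        assert rep.pcc is not None and rep.pcc > 0.8

    def test_determinism(self):
        ds = linear_recovery_dataset(n=120, seed=13)
        tr, va = split_dataset(ds, 0.8, seed=3)
        cfg = DNNConfig(max_epochs=4, seed=5)
        a = train_dnn(tr, va, cfg).predict(va.X)
        b = train_dnn(tr, va, cfg).predict(va.X)
        assert np.array_equal(a, b)

    def test_empty_validation_set_rejected(self):
        ds = linear_recovery_dataset(n=50, seed=14)
        tr, va = split_dataset(ds, 0.8, seed=1)
        with pytest.raises(ValueError):
            DeepAffinityNetwork(tr, va.subset(np.array([0])), DNNConfig())

    def test_feature_set_mismatch_rejected(self):
        a = make_synthetic_dataset(SyntheticDatasetSpec(n=40, seed=1))
        b = make_synthetic_dataset(
            SyntheticDatasetSpec(n=40, seed=1, feature_set="ifp+dist"))
        with pytest.raises(ValueError, match="feature-set"):
            DeepAffinityNetwork(a, b, DNNConfig())
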