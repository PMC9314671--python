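"""MaxEnt core: feature expansion, regularised fit, prediction, tuning,
variable contributions."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from cryosdm import maxent
from cryosdm.covariates import CovariateMatrix
from cryosdm.errors import SchemaError
from cryosdm.maxent import FeatureSpec, MaxEntModel


def cov_matrix(values, names=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    names = names or [f"x{j}" for j in range(values.shape[1])]
    cells = np.column_stack(
        [np.arange(values.shape[0]), np.zeros(values.shape[0], int)]
    )
    return CovariateMatrix(cells=cells, names=names, values=values)


class TestExpandFeatures:
    def test_linear_scaling_endpoints(self):
        x = np.array([[2.0], [4.0], [10.0]])
        feats, names, ranges = maxent.expand_features(
            x, ["t"], FeatureSpec(classes=("linear",))
        )
        assert feats[0, 0] == 0.0 and feats[2, 0] == 1.0
        np.testing.assert_array_equal(ranges[0], [2.0])
        np.testing.assert_array_equal(ranges[1], [10.0])

    def test_class_combinatorics_two_covariates(self, rng):
        x = rng.normal(size=(20, 2))
        feats, names, _ = maxent.expand_features(
            x, ["a", "b"], FeatureSpec(classes=("linear", "quadratic", "product"))
        )
        assert feats.shape[1] == len(names) == 5  # 2 + 2 + 1

    def test_hinge_count_and_bounds(self, rng):
        x = rng.normal(size=(30, 1))
        spec = FeatureSpec(classes=("hinge",), hinge_knots=8)
        feats, names, _ = maxent.expand_features(x, ["a"], spec)
        assert feats.shape[1] == 16  # 8 forward + 8 reverse
        assert feats.min() >= 0.0 and feats.max() <= 1.0

    def test_clamp_truncates_beyond_training_range(self):
        spec = FeatureSpec(classes=("linear",), clamp=True)
        ranges = (np.array([0.0]), np.array([1.0]))
        feats, _, _ = maxent.expand_features(np.array([[2.5]]), ["t"], spec, ranges)
        assert feats[0, 0] == 1.0

    def test_zero_variance_covariate_dropped_with_warning(self, caplog):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        with caplog.at_level("WARNING"):
            feats, names, _ = maxent.expand_features(
                x, ["const", "var"], FeatureSpec(classes=("linear",))
            )
        assert names == ["lin(var)"]
        assert "const" in caplog.text


class TestFitMaxent:
    def test_raw_normalises_over_background(self, rng):
        pres = cov_matrix(rng.normal(0.5, 0.3, size=(40, 2)))
        bg = cov_matrix(rng.normal(0.0, 1.0, size=(300, 2)))
        model = maxent.train_maxent(pres, bg, FeatureSpec(), beta=1.0)
        raw = maxent.predict(model, bg, "raw")
        assert raw.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_signal_gives_near_uniform_predictions(self, rng):
        bg_vals = rng.normal(size=(600, 2))
        idx = rng.choice(600, size=120, replace=False)
        pres = cov_matrix(bg_vals[idx])
        bg = cov_matrix(bg_vals)
        model = maxent.train_maxent(
            pres, bg, FeatureSpec(classes=("linear", "quadratic")), beta=1.0
        )
        assert np.max(np.abs(model.weights)) <= 0.05
        raw = maxent.predict(model, bg, "raw")
        np.testing.assert_allclose(raw, 1.0 / 600, rtol=0.05)

    def test_single_binary_feature_matches_1d_oracle(self):
        # all presences have f=1; half the background does
        m, n = 25, 200
        fp = np.ones((m, 1))
        fb = np.concatenate([np.ones(n // 2), np.zeros(n // 2)])[:, None]
        beta = 1.0
        lam, log_z, _ = maxent.fit_maxent(fp, fb, beta=beta)
        mass = np.exp(fb @ lam - log_z)[: n // 2].sum()

        b1 = beta * max(fp.std(), 0.1) / np.sqrt(m)  # same penalty rule

        def objective(l):
            return -l + logsumexp(fb @ [l]) + b1 * abs(l)

        res = minimize_scalar(objective, bounds=(-20, 20), method="bounded",
                              options={"xatol": 1e-10})
        oracle_mass = (n // 2) * np.exp(res.x) / (
            (n // 2) * np.exp(res.x) + n // 2
        )
        assert mass == pytest.approx(oracle_mass, abs=1e-4)

    def test_l1_norm_nonincreasing_in_beta(self, rng):
        pres = cov_matrix(rng.normal(0.7, 0.2, size=(50, 2)))
        bg = cov_matrix(rng.normal(0.0, 1.0, size=(400, 2)))
        norms = []
        for beta in (0.5, 1.0, 2.0, 4.0):
            model = maxent.train_maxent(pres, bg, FeatureSpec(), beta=beta)
            norms.append(np.abs(model.weights).sum())
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_separable_data_keeps_weights_finite(self):
        fp = np.ones((20, 1))
        fb = np.concatenate([np.ones(5), np.zeros(195)])[:, None]
        lam, _, kkt = maxent.fit_maxent(fp, fb, beta=1.0)
        assert np.isfinite(lam).all()
        assert kkt < 1e-3


class TestPredict:
    def test_zero_weight_model_is_uniform(self, rng):
        bg = cov_matrix(rng.normal(size=(50, 1)))
        model = MaxEntModel(
            cov_names=["x0"], cov_mins=np.array([-3.0]), cov_maxs=np.array([3.0]),
            feature_names=["lin(x0)"], weights=np.zeros(1),
            log_normaliser=np.log(50), n_background=50, entropy=np.log(50),
            reg_multiplier=1.0, spec=FeatureSpec(classes=("linear",)),
        )
        raw = maxent.predict(model, bg, "raw")
        np.testing.assert_allclose(raw, 1.0 / 50)

    def test_logistic_strictly_increasing_in_raw(self, rng):
        pres = cov_matrix(rng.normal(0.8, 0.3, size=(30, 1)))
        bg = cov_matrix(rng.normal(0.0, 1.0, size=(200, 1)))
        model = maxent.train_maxent(pres, bg, FeatureSpec(classes=("linear", "quadratic")))
        raw = maxent.predict(model, bg, "raw")
        logi = maxent.predict(model, bg, "logistic")
        order = np.argsort(raw)
        assert (np.diff(logi[order]) >= 0).all()
        assert (logi > 0).all() and (logi < 1).all()

    def test_name_mismatch_is_schema_error(self, rng):
        pres = cov_matrix(rng.normal(size=(10, 1)), ["a"])
        bg = cov_matrix(rng.normal(size=(50, 1)), ["a"])
        model = maxent.train_maxent(pres, bg, FeatureSpec(classes=("linear",)))
        with pytest.raises(SchemaError):
            maxent.predict(model, cov_matrix(rng.normal(size=(5, 1)), ["b"]))

    def test_serialisation_replays_predictions_exactly(self, rng):
        pres = cov_matrix(rng.normal(0.5, 0.5, size=(30, 3)))
        bg = cov_matrix(rng.normal(size=(150, 3)))
        model = maxent.train_maxent(pres, bg, FeatureSpec())
        clone = MaxEntModel.from_json(model.to_json())
        np.testing.assert_array_equal(
            maxent.predict(model, bg, "logistic"), maxent.predict(clone, bg, "logistic")
        )


class TestTune:
    def _data(self, rng):
        pres = cov_matrix(rng.normal(0.8, 0.3, size=(25, 2)))
        bg = cov_matrix(rng.normal(0.0, 1.0, size=(150, 2)))
        return pres, bg

    def test_single_candidate_returned(self, rng):
        pres, bg = self._data(rng)
        spec = FeatureSpec(classes=("linear",))
        res = maxent.tune(pres, bg, spec_grid=(spec,), beta_grid=(2.0,), seed=0)
        assert res.best == (2.0, spec)

    def test_tie_goes_to_first_candidate(self, rng):
        pres, bg = self._data(rng)
        spec = FeatureSpec(classes=("linear",))
        res = maxent.tune(
            pres, bg, spec_grid=(spec, spec), beta_grid=(1.0,), seed=0
        )
        assert res.cv_scores[0] == res.cv_scores[1]
        assert res.best == (1.0, spec)

    def test_cv_winner_not_worse_than_most_complex_candidate(self, rng):
        # informative covariate plus 3 pure-noise covariates
        n_bg, m = 300, 40
        bg_vals = np.column_stack(
            [rng.normal(size=n_bg)] + [rng.normal(size=n_bg) for _ in range(3)]
        )
        pres_vals = np.column_stack(
            [rng.normal(1.5, 0.4, m)] + [rng.normal(size=m) for _ in range(3)]
        )
        pres, bg = cov_matrix(pres_vals), cov_matrix(bg_vals)
        grid = (FeatureSpec(classes=("linear", "quadratic")), FeatureSpec())
        res = maxent.tune(pres, bg, spec_grid=grid, beta_grid=(0.5, 1.0, 2.0), seed=7)
        # oracle: exhaustive score table is what tune itself reports; the
        # winner must attain the max, and beat the most complex low-beta fit
        assert max(res.cv_scores) == res.cv_scores[res.grid.index(res.best)]
        most_complex = res.grid.index((0.5, FeatureSpec()))
        assert res.cv_scores[res.grid.index(res.best)] >= res.cv_scores[most_complex]


class TestVariableContribution:
    def test_percentages_sum_to_100(self, rng):
        pres = cov_matrix(rng.normal(0.8, 0.3, size=(40, 3)))
        bg = cov_matrix(rng.normal(size=(200, 3)))
        model = maxent.train_maxent(pres, bg, FeatureSpec(classes=("linear", "quadratic")))
        contrib = maxent.variable_contribution(model, pres, bg, seed=0)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=1e-6)

    def test_unused_covariate_gets_zero(self, rng):
        bg = cov_matrix(rng.normal(size=(100, 2)), ["a", "b"])
        pres = cov_matrix(rng.normal(1.0, 0.5, size=(20, 2)), ["a", "b"])
        model = MaxEntModel(
            cov_names=["a", "b"],
            cov_mins=np.array([-3.0, -3.0]), cov_maxs=np.array([3.0, 3.0]),
            feature_names=["lin(a)", "lin(b)"], weights=np.array([2.0, 0.0]),
            log_normaliser=0.0, n_background=100, entropy=np.log(100),
            reg_multiplier=1.0, spec=FeatureSpec(classes=("linear",)),
        )
        contrib = maxent.variable_contribution(model, pres, bg, seed=0)
        assert contrib["b"] == 0.0
        assert contrib["a"] == pytest.approx(100.0)
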