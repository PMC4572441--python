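import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from wcoxboost.boosting import (
    BoostingConfig,
    LinearPredictorState,
    WeightedCoxBoost,
    boost_step,
    export_coef_path,
    fit_boosting,
    update_mandatory,
)
from wcoxboost.core import weighted_partial_loglik
from wcoxboost.datasets import SurvivalDataset
from wcoxboost.simulate import SimulationScenario, generate
from wcoxboost.weights import WeightScheme

from conftest import random_dataset


def test_zero_steps_keeps_all_penalized_at_zero():
    ds = random_dataset(0, n=30, p=5)
    fit = fit_boosting(ds, BoostingConfig(steps=0))
    assert np.all(fit.coef == 0) and fit.selected == []


def test_infinite_penalty_limit():
    ds = random_dataset(1, n=40, p=4)
    state, j, gamma = boost_step(
        LinearPredictorState.null(ds), ds, BoostingConfig(steps=1, penalty=1e12)
    )
    assert abs(gamma) < 1e-8
    assert np.max(np.abs(state.beta)) < 1e-8


def test_single_covariate_unpenalized_boosting_reaches_mle():
    # p=1, rho=0, many steps: converges to the stratified Cox MLE
    ds = random_dataset(7, n=120, p=1)
    fit = fit_boosting(
        ds, BoostingConfig(steps=200, penalty=0.0, standardize=False)
    )
    df = pd.DataFrame({"time": ds.times, "status": ds.status,
                       "stratum": ds.strata, "x": ds.covariates[:, 0]})
    cph = CoxPHFitter()
    cph.fit(df, "time", "status", strata=["stratum"])
    assert fit.coef[0] == pytest.approx(cph.params_["x"], abs=1e-4)


def test_first_update_is_shrinkage_fraction_of_one_step_mle():
    from wcoxboost.core import directional_score_info
    from wcoxboost.datasets import standardize

    ratios = []
    for seed in range(5):
        sc = SimulationScenario(n=250, p=1, subgroup_prob=0.0, effects=((1, 0.5, 0.5),))
        ds = generate(sc, seed=seed)
        ds_std, _ = standardize(ds)
        U, I = directional_score_info(ds_std, WeightScheme(1.0), np.zeros(ds.n), 0)
        fit1 = fit_boosting(ds_std, BoostingConfig(steps=1))
        ratios.append(abs(fit1.coef[0]) / abs(U / I))
    assert np.mean(ratios) == pytest.approx(0.02, rel=0.3)


class TestMandatory:
    def test_no_mandatory_is_identity(self):
        ds = random_dataset(2, n=30, p=2)
        state = LinearPredictorState.null(ds)
        out = update_mandatory(state, ds, WeightScheme(1.0))
        assert out.mandatory_coefs == {} and np.array_equal(out.eta, state.eta)

    def test_single_stratum_matches_lifelines(self):
        rng = np.random.default_rng(21)
        n = 150
        ds = SurvivalDataset(
            rng.exponential(1, n), (rng.uniform(size=n) > 0.35).astype(int),
            np.ones(n, int), rng.standard_normal((n, 1)), ["age"],
            mandatory_mask=[True],
        )
        fit = fit_boosting(ds, BoostingConfig(steps=0))
        df = pd.DataFrame({"time": ds.times, "status": ds.status, "age": ds.covariates[:, 0]})
        cph = CoxPHFitter()
        cph.fit(df, "time", "status")
        assert fit.state.mandatory_coefs[1][0] == pytest.approx(cph.params_["age"], abs=1e-6)

    def test_stratum_specific_coefs_equal_separate_fits(self):
        rng = np.random.default_rng(31)
        n = 160
        ds = SurvivalDataset(
            rng.exponential(1, n), (rng.uniform(size=n) > 0.3).astype(int),
            rng.integers(1, 3, n), rng.standard_normal((n, 1)), ["age"],
            mandatory_mask=[True],
        )
        fit = fit_boosting(ds, BoostingConfig(steps=0))
        for s in (1, 2):
            rows = ds.strata == s
            df = pd.DataFrame({"time": ds.times[rows], "status": ds.status[rows],
                               "age": ds.covariates[rows, 0]})
            cph = CoxPHFitter()
            cph.fit(df, "time", "status")
            assert fit.state.mandatory_coefs[s][0] == pytest.approx(
                cph.params_["age"], abs=1e-6
            )

    def test_mandatory_refit_before_each_step_keeps_eta_consistent(self):
        rng = np.random.default_rng(5)
        n = 100
        X = np.column_stack([rng.standard_normal(n), rng.standard_normal((n, 4))])
        ds = SurvivalDataset(rng.exponential(1, n), (rng.uniform(size=n) > 0.3).astype(int),
                             rng.integers(1, 3, n), X,
                             ["clin", "a", "b", "c", "d"], mandatory_mask=[True] + [False] * 4)
        fit = fit_boosting(ds, BoostingConfig(steps=10, scheme=WeightScheme(0.5)))
        recomputed = fit.state.recompute_eta(ds)
        np.testing.assert_allclose(recomputed, fit.state.eta, atol=1e-10)


def test_determinism_bit_identical():
    ds = random_dataset(11, n=80, p=20)
    cfg = BoostingConfig(steps=25, scheme=WeightScheme(0.3))
    f1 = fit_boosting(ds, cfg)
    f2 = fit_boosting(ds, cfg)
    assert np.array_equal(f1.coef_path, f2.coef_path)
    assert f1.selected == f2.selected


def test_selection_sparsity_bounded_by_steps():
    ds = random_dataset(13, n=60, p=40)
    fit = fit_boosting(ds, BoostingConfig(steps=15))
    assert len(set(fit.selected)) <= 15
    assert (fit.coef != 0).sum() <= 15
    # consecutive steps differ in at most one penalized coefficient
    diffs = np.diff(fit.coef_path, axis=0)
    assert np.all((diffs != 0).sum(axis=1) <= 1)


def test_limiting_weight_path_equivalences():
    ds = generate(SimulationScenario(n=120, p=30), seed=17)
    # w=0: identical to fitting on the focus subgroup alone
    f0 = fit_boosting(ds, BoostingConfig(steps=20, scheme=WeightScheme(0.0)))
    focus = ds.subset(np.flatnonzero(ds.strata == 1))
    f_sub = fit_boosting(focus, BoostingConfig(steps=20, scheme=WeightScheme(1.0)))
    assert np.array_equal(f0.coef_path, f_sub.coef_path)
    assert f0.selected == f_sub.selected
    # w=1: identical to the unweighted stratified run
    f1 = fit_boosting(ds, BoostingConfig(steps=20, scheme=WeightScheme(1.0)))
    f1b = fit_boosting(ds, BoostingConfig(steps=20))
    assert np.array_equal(f1.coef_path, f1b.coef_path)


@pytest.mark.parametrize("seed", range(20))
def test_monotone_likelihood_with_auto_penalty(seed):
    ds = random_dataset(seed, n=60, p=10)
    scheme = WeightScheme(w=float(np.random.default_rng(seed).uniform(0.1, 1.0)))
    fit = fit_boosting(ds, BoostingConfig(steps=20, scheme=scheme))
    lls = []
    Z = ds.covariates[:, ds.mandatory_mask]
    for m in range(fit.coef_path.shape[0]):
        eta = ds.covariates @ fit.coef_path[m]
        for s, th in fit.mandatory_path[m].items():
            rows = ds.strata == s
            eta[rows] += Z[rows] @ th
        lls.append(weighted_partial_loglik(ds, scheme, eta))
    assert np.all(np.diff(lls) >= -1e-9)


def test_noise_path_boundedness():
    for seed in range(20):
        ds = random_dataset(1000 + seed, n=60, p=20)
        fit = fit_boosting(ds, BoostingConfig(steps=50))
        first_gamma = np.abs(fit.coef_path[1]).max()
        assert np.abs(fit.coef).max() <= first_gamma * 50 + 1e-12


def test_subgroup2_effects_rarely_selected_at_tiny_weight():
    # covariates with effects only in the down-weighted stratum should be
    # picked later/less often than focus-stratum effects
    first_count = np.zeros(2)  # [groups 1-3, groups 8-10]
    for seed in range(10):
        ds = generate(SimulationScenario(n=200, p=50), seed=seed)
        fit = fit_boosting(ds, BoostingConfig(steps=30, scheme=WeightScheme(0.001)))
        distinct = list(dict.fromkeys(fit.selected))[:10]
        first_count[0] += sum(j in (0, 1, 2) for j in distinct)
        first_count[1] += sum(j in (7, 8, 9) for j in distinct)
    assert first_count[0] > first_count[1]


def test_export_coef_path_shapes(tmp_path):
    ds = random_dataset(3, n=40, p=6)
    fit = fit_boosting(ds, BoostingConfig(steps=8))
    wide = tmp_path / "path.csv"
    export_coef_path(fit, wide)
    df = pd.read_csv(wide)
    assert len(df) == 9 and df["step"].tolist() == list(range(9))
    tri = tmp_path / "path_sparse.csv"
    export_coef_path(fit, tri, sparse=True)
    tdf = pd.read_csv(tri)
    assert set(tdf.columns) == {"step", "name", "value"}
    assert (tdf["value"] != 0).all()


class TestEstimatorInterface:
    def test_sklearn_params_roundtrip(self):
        est = WeightedCoxBoost(n_steps=5, weight=0.25)
        params = est.get_params()
        est2 = WeightedCoxBoost(**params)
        assert est2.get_params() == params
        est2.set_params(weight=0.5)
        assert est2.weight == 0.5

    def test_fit_predict_matrix_api(self):
        ds = generate(SimulationScenario(n=100, p=12), seed=2)
        y = np.column_stack([ds.times, ds.status])
        est = WeightedCoxBoost(n_steps=10, weight=0.5).fit(
            ds.covariates, y, strata=ds.strata, feature_names=ds.covariate_names
        )
        eta = est.predict(ds.covariates, strata=ds.strata)
        np.testing.assert_allclose(eta, ds.covariates @ est.coef_)
        S = est.predict_survival_function(ds.covariates[:3], [0.01, 0.05, 0.1],
                                          strata=ds.strata[:3])
        assert S.shape == (3, 3) and np.all((S >= 0) & (S <= 1))
        assert np.all(np.diff(S, axis=1) <= 1e-12)

    def test_fit_accepts_dataset_directly(self):
        ds = generate(SimulationScenario(n=80, p=12), seed=4)
        est = WeightedCoxBoost(n_steps=5).fit(ds)
        assert est.coef_path_.shape == (6, 12)
        assert len(est.selected_) == 5
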