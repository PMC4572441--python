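import numpy as np
import pandas as pd
import pytest

from wcoxboost.datasets import (
    SurvivalDataset,
    filter_all_missing,
    read_dataset,
    standardize,
    write_dataset,
)
from wcoxboost.simulate import SimulationScenario, generate


def _write(tmp_path, cov_df, end_df, sep=",", ext="csv"):
    cov = tmp_path / f"cov.{ext}"
    end = tmp_path / f"end.{ext}"
    cov_df.to_csv(cov, sep=sep, index=False)
    end_df.to_csv(end, sep=sep, index=False)
    return cov, end


def test_read_minimal_single_stratum(tmp_path):
    cov, end = _write(
        tmp_path,
        pd.DataFrame({"g1": [0.1, 0.2, 0.3]}),
        pd.DataFrame({"time": [1, 2, 3], "status": [1, 1, 1], "stratum": ["A", "A", "A"]}),
    )
    ds = read_dataset(cov, end)
    assert (ds.n, ds.p, ds.n_strata) == (3, 1, 1)
    assert ds.strata.tolist() == [1, 1, 1]


@pytest.mark.parametrize(
    "endpoint, match",
    [
        ({"time": [1, 2], "status": [1, 2], "stratum": [1, 1]}, "binary"),
        ({"time": [1, -2], "status": [1, 1], "stratum": [1, 1]}, "nonnegative"),
        ({"time": [1, 2, 3], "status": [1, 1, 1], "stratum": [1, 1, 1]}, "mismatch"),
    ],
)
def test_read_contract_violations(tmp_path, endpoint, match):
    cov, end = _write(tmp_path, pd.DataFrame({"g1": [0.1, 0.2]}), pd.DataFrame(endpoint))
    with pytest.raises(ValueError, match=match):
        read_dataset(cov, end)


def test_unknown_mandatory_name(tmp_path):
    cov, end = _write(
        tmp_path,
        pd.DataFrame({"g1": [0.1, 0.2]}),
        pd.DataFrame({"time": [1, 2], "status": [1, 1], "stratum": [1, 1]}),
    )
    with pytest.raises(ValueError, match="mandatory"):
        read_dataset(cov, end, mandatory=["age"])


def test_focus_stratum_mapped_to_one(tmp_path):
    cov, end = _write(
        tmp_path,
        pd.DataFrame({"g1": [0.1, 0.2, 0.3]}),
        pd.DataFrame({"time": [1, 2, 3], "status": [1, 1, 1], "stratum": ["hi", "lo", "hi"]}),
    )
    ds = read_dataset(cov, end, focus="lo")
    assert ds.strata.tolist() == [2, 1, 2]
    assert ds.stratum_labels[1] == "lo"


def test_roundtrip_simulation_scale_bit_identical(tmp_path):
    ds = generate(SimulationScenario(n=250, p=1000), seed=11)
    write_dataset(ds, tmp_path / "c.csv", tmp_path / "e.csv")
    back = read_dataset(tmp_path / "c.csv", tmp_path / "e.csv")
    assert back == ds
    # second round trip is also byte-identical on disk
    write_dataset(back, tmp_path / "c2.csv", tmp_path / "e2.csv")
    assert (tmp_path / "c.csv").read_bytes() == (tmp_path / "c2.csv").read_bytes()
    assert (tmp_path / "e.csv").read_bytes() == (tmp_path / "e2.csv").read_bytes()


def test_roundtrip_tsv_with_missing(tmp_path):
    X = np.array([[1.0, np.nan], [2.0, np.nan], [3.0, 4.0]])
    ds = SurvivalDataset([1, 2, 3], [1, 0, 1], [1, 1, 1], X, ["a", "b"])
    write_dataset(ds, tmp_path / "c.tsv", tmp_path / "e.tsv")
    assert read_dataset(tmp_path / "c.tsv", tmp_path / "e.tsv") == ds


def test_log_transform_spares_mandatory(tmp_path):
    cov, end = _write(
        tmp_path,
        pd.DataFrame({"age": [50.0, 60.0], "g1": [0.0, 9.0]}),
        pd.DataFrame({"time": [1, 2], "status": [1, 1], "stratum": [1, 1]}),
    )
    ds = read_dataset(cov, end, mandatory=["age"], log_transform=True)
    np.testing.assert_allclose(ds.covariates[:, 0], [50.0, 60.0])
    np.testing.assert_allclose(ds.covariates[:, 1], np.log([1.0, 10.0]))


class TestFilterAllMissing:
    def test_definition(self):
        X = np.ones((4, 5))
        X[:, 2] = np.nan
        ds = SurvivalDataset([1, 2, 3, 4], [1, 1, 0, 1], [1, 1, 1, 1], X,
                             [f"cov{j + 1}" for j in range(5)])
        out, removed = filter_all_missing(ds)
        assert removed == ["cov3"]
        assert out.p == 4 and "cov3" not in out.covariate_names

    def test_identity_when_complete(self, tiny_dataset):
        out, removed = filter_all_missing(tiny_dataset)
        assert removed == [] and out == tiny_dataset

    def test_random_matrix_brute_force(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((100, 50))
        gone = rng.choice(50, size=7, replace=False)
        X[:, gone] = np.nan
        X[rng.integers(0, 100, 30), rng.integers(0, 50, 30)] = np.nan  # partial missing stays
        names = [f"c{j}" for j in range(50)]
        ds = SurvivalDataset(rng.exponential(1, 100), rng.integers(0, 2, 100),
                             np.ones(100, int), X, names)
        expected = sorted(names[j] for j in range(50) if all(np.isnan(X[i, j]) for i in range(100)))
        out, removed = filter_all_missing(ds)
        assert sorted(removed) == expected and set(names[g] for g in gone) <= set(removed)
        # idempotent
        again, removed2 = filter_all_missing(out)
        assert removed2 == [] and again == out


class TestStandardize:
    def test_zero_variance_flagged(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        ds = SurvivalDataset([1, 2, 3, 4, 5], [1] * 5, [1] * 5, X, ["const", "v"])
        with pytest.warns(UserWarning, match="zero variance"):
            out, rec = standardize(ds)
        assert not rec.applied[0] and rec.applied[1]
        np.testing.assert_array_equal(out.covariates[:, 0], np.ones(5))

    def test_idempotent_on_standardized_column(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        x = (x - x.mean()) / x.std(ddof=1)
        ds = SurvivalDataset(rng.exponential(1, 50), np.ones(50, int), np.ones(50, int),
                             x[:, None], ["z"])
        _, rec = standardize(ds)
        assert abs(rec.center[0]) < 1e-12 and abs(rec.scale[0] - 1) < 1e-12

    def test_backtransform_preserves_linear_predictor(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 4)) * [1, 10, 0.1, 5] + [0, 3, -2, 1]
        ds = SurvivalDataset(rng.exponential(1, 30), np.ones(30, int), np.ones(30, int),
                             X, list("abcd"))
        std, rec = standardize(ds)
        beta_std = rng.standard_normal(4)
        eta_std = std.covariates @ beta_std
        beta = rec.invert_coefficients(beta_std)
        eta = ds.covariates @ beta
        # equal up to the global centering constant, which cancels in the
        # partial likelihood
        shift = eta - eta_std
        assert np.ptp(shift) < 1e-12

    def test_mandatory_untouched(self):
        X = np.column_stack([np.arange(5.0) * 100, np.arange(5.0)])
        ds = SurvivalDataset([1, 2, 3, 4, 5], [1] * 5, [1] * 5, X, ["age", "g"],
                             mandatory_mask=[True, False])
        out, rec = standardize(ds)
        np.testing.assert_array_equal(out.covariates[:, 0], X[:, 0])
        assert not rec.applied[0]


def test_partial_missing_is_fit_time_error():
    X = np.ones((4, 2))
    X[0, 1] = np.nan
    ds = SurvivalDataset([1, 2, 3, 4], [1, 1, 1, 1], [1, 1, 1, 1], X, ["a", "b"])
    with pytest.raises(ValueError, match="missing"):
        ds.validate_for_fitting()
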