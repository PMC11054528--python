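"""GA descriptor selection and MLR fitting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lipichrom import (
    GAConfig,
    SyntheticSpec,
    fit_mlr,
    ga_select,
    gen_descriptor_matrix,
    predict,
    split_train_validation,
)
from lipichrom.qsrr import SingularDesignError, format_equation
from lipichrom.validation import q2_loo


class TestSplit:
    def test_sizes_disjoint_exhaustive(self):
        ids = list(range(1, 27))
        y = np.linspace(0, 1, 26)
        train, val = split_train_validation(ids, y)
        assert len(train) == 19 and len(val) == 7
        assert sorted(train + val) == ids

    def test_systematic_rule_small_case(self):
        # 4 compounds, 2/2 split: validation takes response ranks 2 and 4
        ids = ["w", "x", "y", "z"]
        y = [0.3, 0.1, 0.4, 0.2]
        train, val = split_train_validation(ids, y, n_train=2, n_validation=2)
        assert set(val) == {"z", "y"}  # ranks: x(1) z(2) w(3) y(4)

    def test_random_split_deterministic_given_seed(self):
        ids = list(range(26))
        a = split_train_validation(ids, strategy="random", seed=11)
        b = split_train_validation(ids, strategy="random", seed=11)
        assert a == b

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            split_train_validation([1, 2, 3], [1, 2, 3], n_train=1, n_validation=1)


class TestFitMLR:
    def test_exact_linear_data(self):
        X = pd.DataFrame({"x1": [0.0, 1, 2, 3, 4]})
        y = 2 * X["x1"] + 1
        m = fit_mlr(X, y)
        assert m.coefficients[0] == pytest.approx(2.0)
        assert m.intercept == pytest.approx(1.0)
        assert predict(m, X) == pytest.approx(y.to_numpy())

    def test_noisy_fit_matches_statsmodels_and_truth(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((30, 2)), columns=["x1", "x2"])
        y = 3 * X["x1"] - 1 * X["x2"] + 0.5 + rng.normal(0, 0.1, 30)
        m = fit_mlr(X, y)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert m.intercept == pytest.approx(ref.params["const"], abs=1e-10)
        assert m.coefficients == pytest.approx(ref.params[["x1", "x2"]].to_numpy(), abs=1e-10)
        assert m.coefficient_uncertainties == pytest.approx(
            ref.bse[["x1", "x2"]].to_numpy(), abs=1e-10
        )
        for truth, est, se in zip(
            [3.0, -1.0], m.coefficients, m.coefficient_uncertainties
        ):
            assert abs(est - truth) < 3 * se

    def test_duplicate_column_raises_singular(self):
        X = pd.DataFrame({"x1": [1.0, 2, 3, 4, 5], "x2": [1.0, 2, 3, 4, 5]})
        with pytest.raises(SingularDesignError, match="x"):
            fit_mlr(X, [1.0, 2, 3, 4, 5])

    def test_predict_structure(self):
        m = fit_mlr(pd.DataFrame({"x": [0.0, 1, 2]}), [1.0, 3.0, 5.0])
        assert predict(m, pd.DataFrame({"x": [3.0]}))[0] == pytest.approx(7.0)
        assert predict(m, pd.DataFrame({"x": [0.0]}))[0] == pytest.approx(m.intercept)
        with pytest.raises(KeyError):
            predict(m, pd.DataFrame({"other": [1.0]}))

    def test_published_equation_shape_evaluates_by_hand(self):
        # a 3-descriptor affinity model evaluated at illustrative inputs:
        # 0.114*40 - 0.857*1 - 0.050*10 - 2.751 = 0.452
        from lipichrom.qsrr import MLRModel

        m = MLRModel(
            descriptor_names=["CHI_IAM", "GATS2e", "RDF155u"],
            coefficients=[0.114, -0.857, -0.050],
            intercept=-2.751,
            coefficient_uncertainties=[0.952, 0.141, 0.274],
            intercept_uncertainty=0.994,
        )
        X = pd.DataFrame({"CHI_IAM": [40.0], "GATS2e": [1.0], "RDF155u": [10.0]})
        assert predict(m, X)[0] == pytest.approx(0.452)
        eq = format_equation(m, "LogK_HSA")
        assert eq.startswith("LogK_HSA = 0.114(±0.952)CHI_IAM")
        assert "- 2.751(±0.994)" in eq


def _exhaustive_best(X, y, k, criterion="q2_loo"):
    from lipichrom.qsrr import _subset_fitness

    A = X.to_numpy(float)
    yv = np.asarray(y, float)
    best, best_fit = None, -np.inf
    for cols in itertools.combinations(range(X.shape[1]), k):
        f = _subset_fitness(A, yv, cols, criterion)
        if f > best_fit:
            best, best_fit = cols, f
    return set(X.columns[list(best)]), best_fit


class TestGASelect:
    def test_matches_exhaustive_search_on_small_pool(self):
        spec = SyntheticSpec(n_descriptors=8, informative={2: 3.0, 5: -1.5}, noise_sd=0.4, seed=4)
        X, y, _ = gen_descriptor_matrix(spec)
        cfg = GAConfig(model_size=2, seed=4, generations=150)
        models = ga_select(X, y, cfg)
        _, oracle_fit = _exhaustive_best(X, y, 2)
        assert models[0].ga_fitness == pytest.approx(oracle_fit, abs=1e-12)

    def test_recovers_planted_pair_among_decoys(self):
        spec = SyntheticSpec(
            n_compounds=26, n_descriptors=42, informative={3: 4.0, 7: -2.0}, noise_sd=0.5, seed=9
        )
        X, y, truth = gen_descriptor_matrix(spec)
        models = ga_select(X, y, GAConfig(model_size=2, seed=9))
        assert set(models[0].descriptor_names) == set(truth["informative"])

    def test_degenerate_single_descriptor_optimum(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((20, 5)), columns=[f"d{i}" for i in range(5)])
        y = 2.0 * X["d3"]  # perfectly collinear with one descriptor
        models = ga_select(X, y, GAConfig(model_size=1, seed=0, generations=50))
        assert models[0].descriptor_names == ["d3"]
        assert models[0].ga_fitness == pytest.approx(1.0, abs=1e-10)

    def test_reproducible_and_right_cardinality(self):
        spec = SyntheticSpec(n_descriptors=15, informative={1: 2.0}, noise_sd=0.3, seed=2)
        X, y, _ = gen_descriptor_matrix(spec)
        cfg = GAConfig(model_size=3, seed=21, generations=60)
        a = ga_select(X, y, cfg)
        b = ga_select(X, y, cfg)
        assert [m.descriptor_names for m in a] == [m.descriptor_names for m in b]
        assert all(len(m.descriptor_names) == 3 for m in a)
        names = [tuple(m.descriptor_names) for m in a]
        assert len(set(names)) == len(names)  # deduplicated

    def test_elitist_best_fitness_non_decreasing(self):
        # the reported best must never be worse than any earlier population's best
        spec = SyntheticSpec(n_descriptors=10, informative={0: 1.0}, noise_sd=1.0, seed=6)
        X, y, _ = gen_descriptor_matrix(spec)
        fits = []
        for gens in [5, 20, 80]:
            m = ga_select(X, y, GAConfig(model_size=2, seed=6, generations=gens))[0]
            fits.append(m.ga_fitness)
        assert fits == sorted(fits)

    def test_infeasible_size_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((6, 10)))
        X.columns = [f"d{i}" for i in range(10)]
        with pytest.raises(ValueError):
            ga_select(X, np.arange(6.0), GAConfig(model_size=6, seed=0))

    def test_ga_fitness_agrees_with_q2loo_on_winner(self):
        spec = SyntheticSpec(n_descriptors=12, informative={4: 3.0}, noise_sd=0.4, seed=8)
        X, y, _ = gen_descriptor_matrix(spec)
        m = ga_select(X, y, GAConfig(model_size=1, seed=8, generations=60))[0]
        assert m.ga_fitness == pytest.approx(q2_loo(X[m.descriptor_names], y), abs=1e-10)
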