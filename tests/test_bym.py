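import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import spatialprev as sp
from spatialprev.bym import (
    ModelData,
    PosteriorSample,
    PosteriorSamples,
    FitResult,
    prepare_model_data,
    tau_s_conditional,
    tau_u_conditional,
)
from spatialprev.synthetic import TruthSet

from .conftest import line_map, zero_truth


def small_records(n=6, seed=0, areas=("1", "2", "3")):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "outcome": rng.integers(0, 2, n),
        "weight": np.ones(n),
        "stratum_id": ["s"] * n,
        "psu_id": [f"p{i}" for i in range(n)],
        "area_id": [areas[i % len(areas)] for i in range(n)],
        "g": [["x", "y"][i % 2] for i in range(n)],
    })


class TestDesignMatrix:
    def test_three_levels_two_columns(self):
        rec = pd.DataFrame({"f": ["a", "b", "c", "a"]})
        X, names = sp.build_design_matrix(rec, {"f": ["a", "b", "c"]})
        assert names == ["f=b", "f=c"]
        np.testing.assert_array_equal(X, [[0, 0], [1, 0], [0, 1], [0, 0]])

    def test_reference_pattern_is_zero_row(self):
        rec = pd.DataFrame({"f": ["a"], "g": ["u"]})
        X, _ = sp.build_design_matrix(rec, {"f": ["a", "b"], "g": ["u", "v"]})
        np.testing.assert_array_equal(X, [[0, 0]])

    def test_column_count_sums_levels_minus_one(self):
        rng = np.random.default_rng(3)
        spec = {"f1": [f"l{i}" for i in range(7)],
                "f2": [f"m{i}" for i in range(8)],
                "f3": ["p", "q"]}
        rec = pd.DataFrame({f: rng.choice(lv, 50) for f, lv in spec.items()})
        X, names = sp.build_design_matrix(rec, spec)
        assert X.shape[1] == len(names) == 6 + 7 + 1

    def test_unseen_level_rejected(self):
        rec = pd.DataFrame({"f": ["a", "zzz"]})
        with pytest.raises(ValueError, match="zzz"):
            sp.build_design_matrix(rec, {"f": ["a", "b"]})

    def test_custom_reference_level(self):
        rec = pd.DataFrame({"f": ["a", "b"]})
        _, names = sp.build_design_matrix(rec, {"f": ["a", "b"]}, {"f": "b"})
        assert names == ["f=a"]


class TestLogPosterior:
    def test_balanced_outcomes_at_null_point(self):
        rec = small_records(n=8)
        rec["outcome"] = [0, 1] * 4
        amap = line_map(3)
        data, names, _ = prepare_model_data(rec, amap, {"g": ["x", "y"]})
        eta = np.zeros(len(data.cell_n))
        assert data.loglik(eta) == pytest.approx(8 * math.log(0.5))

    def test_icar_kernel_invariant_to_constant_shift(self):
        amap = line_map(4)
        sm = sp.structure_matrix(amap)
        f = np.array([0.3, -0.1, 0.4, -0.6])
        q1 = f @ sm.Q @ f
        q2 = (f + 5.0) @ sm.Q @ (f + 5.0)
        assert q1 == pytest.approx(q2, abs=1e-9)

    def test_matches_term_by_term_oracle(self):
        # n = 6 records, Model 4: independent re-derivation record by record
        rec = small_records(n=6, seed=4)
        amap = line_map(3)
        spec = sp.ModelSpec(True, True, prior_a=0.7, prior_b=0.2,
                            beta_prior_precision=0.01)
        data, names, _ = prepare_model_data(rec, amap, {"g": ["x", "y"]})
        sm = sp.structure_matrix(amap)
        sample = PosteriorSample(
            beta0=0.3, beta=np.array([-0.4]),
            f_s=np.array([0.2, -0.5, 0.3]), f_u=np.array([0.1, 0.0, -0.1]),
            tau_s=1.5, tau_u=2.5,
        )
        got = sp.log_posterior(sample, data, spec, sm)

        # oracle: loop over records and parameters with plain math
        expected = 0.0
        aidx = {"1": 0, "2": 1, "3": 2}
        for _, row in rec.iterrows():
            x = 1.0 if row["g"] == "y" else 0.0
            a = aidx[row["area_id"]]
            eta = 0.3 + (-0.4) * x + sample.f_s[a] + sample.f_u[a]
            p = 1.0 / (1.0 + math.exp(-eta))
            expected += math.log(p if row["outcome"] == 1 else 1 - p)
        expected += -0.5 * 0.01 * (0.3**2 + 0.4**2)
        expected += 0.5 * 3 * math.log(2.5) - 0.5 * 2.5 * sum(v**2 for v in sample.f_u)
        edges = [(0, 1), (1, 2)]
        quad = sum((sample.f_s[i] - sample.f_s[j]) ** 2 for i, j in edges)
        expected += 0.5 * (3 - 1) * math.log(1.5) - 0.5 * 1.5 * quad
        for tau in (1.5, 2.5):
            expected += (0.7 - 1) * math.log(tau) - 0.2 * tau
        assert got == pytest.approx(expected, rel=1e-12)

    def test_missing_random_effect_rejected(self):
        rec = small_records()
        amap = line_map(3)
        data, _, _ = prepare_model_data(rec, amap, {"g": ["x", "y"]})
        sm = sp.structure_matrix(amap)
        sample = PosteriorSample(beta0=0.0, beta=np.zeros(1))
        with pytest.raises(ValueError, match="f_s"):
            sp.log_posterior(sample, data, sp.ModelSpec(True, False), sm)


class TestPrecisionConditionals:
    def test_icar_worked_example(self):
        # path graph, f_s = (-1, 0, 1), Gamma(1, 1) prior -> Gamma(2, 2)
        sm = sp.structure_matrix(line_map(3))
        shape, rate = tau_s_conditional(np.array([-1.0, 0.0, 1.0]), sm, 1.0, 1.0)
        assert shape == pytest.approx(2.0)
        assert rate == pytest.approx(2.0)

    def test_iid_conditional_shape_rate(self):
        f_u = np.array([0.5, -0.5, 1.0, 0.0])
        shape, rate = tau_u_conditional(f_u, 0.5, 0.0005)
        assert shape == pytest.approx(0.5 + 2.0)
        assert rate == pytest.approx(0.0005 + 0.5 * 1.5)


@pytest.fixture(scope="module")
def glm_fit():
    """Model 1 on moderately large data, with the ML fit as oracle."""
    import statsmodels.api as sm_api

    amap = line_map(4)
    truth = zero_truth(amap, beta0=-0.5,
                       beta={"g": {"b": 0.8, "c": -0.6}})
    rec = sp.simulate_survey(
        amap, truth,
        design={"psus_per_area": 10, "respondents_per_psu": 125,
                "weight_dispersion": 0.0, "n_regions": 1},
        factor_spec={"g": {"a": 0.4, "b": 0.3, "c": 0.3}},
        seed=21,
    )
    fit = sp.fit_model(rec, amap, sp.ModelSpec(False, False),
                       factor_spec={"g": ["a", "b", "c"]},
                       mcmc={"iterations": 6000, "burn_in": 2000, "thin": 2,
                             "seed": 22})
    X, _ = sp.build_design_matrix(rec, {"g": ["a", "b", "c"]})
    ml = sm_api.GLM(rec["outcome"], sm_api.add_constant(X),
                    family=sm_api.families.Binomial()).fit()
    return fit, ml


class TestFitModel:
    def test_posterior_means_match_ml(self, glm_fit):
        fit, ml = glm_fit
        post = np.concatenate([[fit.samples.beta0.mean()],
                               fit.samples.beta.mean(axis=0)])
        se = ml.bse.to_numpy()
        np.testing.assert_array_less(np.abs(post - ml.params.to_numpy()), 2.5 * se)

    def test_pd_near_parameter_count(self, glm_fit):
        fit, _ = glm_fit
        assert fit.pd == pytest.approx(3.0, rel=0.3)  # beta0 + 2 coefficients

    def test_deterministic_given_seed(self, survey20, lattice20):
        kw = dict(factor_spec=sp.default_factor_spec(),
                  mcmc={"iterations": 400, "burn_in": 200, "thin": 2, "seed": 5})
        a = sp.fit_model(survey20, lattice20, sp.ModelSpec.from_number(4), **kw)
        b = sp.fit_model(survey20, lattice20, sp.ModelSpec.from_number(4), **kw)
        np.testing.assert_array_equal(a.samples.beta, b.samples.beta)
        np.testing.assert_array_equal(a.samples.tau_s, b.samples.tau_s)

    def test_stored_fs_sums_to_zero_every_iteration(self, survey20, lattice20):
        fit = sp.fit_model(survey20, lattice20, sp.ModelSpec.from_number(3),
                           factor_spec=sp.default_factor_spec(),
                           mcmc={"iterations": 600, "burn_in": 200, "thin": 2,
                                 "seed": 6})
        np.testing.assert_allclose(fit.samples.f_s.sum(axis=1), 0.0, atol=1e-8)

    def test_structured_effect_needs_edges(self):
        amap = sp.AreaMap(("a", "b"), np.array([(0.0, 0.0), (1.0, 0.0)]),
                          {"a": frozenset(), "b": frozenset()})
        rec = small_records(areas=("a", "b"))
        with pytest.raises(ValueError, match="edgeless"):
            sp.fit_model(rec, amap, sp.ModelSpec(True, False),
                         factor_spec={"g": ["x", "y"]},
                         mcmc={"iterations": 20, "burn_in": 10, "seed": 1})

    def test_seed_required(self, survey20, lattice20):
        with pytest.raises(ValueError, match="seed"):
            sp.fit_model(survey20, lattice20, sp.ModelSpec(False, False),
                         mcmc={"iterations": 100, "burn_in": 10})

    def test_save_load_roundtrip(self, survey20, lattice20, tmp_path):
        fit = sp.fit_model(survey20, lattice20, sp.ModelSpec.from_number(2),
                           factor_spec=sp.default_factor_spec(),
                           mcmc={"iterations": 300, "burn_in": 100, "thin": 2,
                                 "seed": 8})
        fit.save(tmp_path / "m2")
        back = FitResult.load(tmp_path / "m2")
        assert back.dic == pytest.approx(fit.dic)
        np.testing.assert_allclose(back.samples.f_u, fit.samples.f_u)
        assert back.column_names == fit.column_names


class TestDic:
    def test_arithmetic(self):
        dic, p_d = sp.compute_dic(np.array([10.0, 14.0]), 11.0)
        assert p_d == pytest.approx(1.0)
        assert dic == pytest.approx(13.0)

    def test_degenerate_posterior_pd_zero(self):
        dic, p_d = sp.compute_dic(np.array([7.0, 7.0, 7.0]), 7.0)
        assert p_d == 0.0
        assert dic == 7.0


class TestSelectBestModel:
    def test_argmin_of_dic(self):
        assert sp.select_best_model({1: 10.0, 2: 8.5, 3: 9.0}) == 2

    def test_accepts_fit_results(self, glm_fit):
        fit, _ = glm_fit
        assert sp.select_best_model({1: fit, 2: fit.dic + 1}) == 1

    def test_exact_tie_prefers_earlier_model(self):
        assert sp.select_best_model({2: 100.0, 3: 100.0}) == 2

    def test_tie_prefers_fewer_random_components(self):
        assert sp.select_best_model({4: 50.0, 2: 50.0}) == 2

    def test_needs_two_models(self):
        with pytest.raises(ValueError):
            sp.select_best_model({3: 1.0})


def make_synthetic_fit(beta_draws, f_s=None, n_areas=0, area_ids=(), spec=None):
    """Hand-assembled FitResult for summary-level checks (synthetic posterior)."""
    S = len(beta_draws)
    spec = spec or sp.ModelSpec(f_s is not None, False)
    samples = PosteriorSamples(
        beta0=np.zeros(S), beta=np.asarray(beta_draws).reshape(S, -1),
        f_s=f_s, f_u=None,
        tau_s=np.ones(S) if f_s is not None else None, tau_u=None,
        deviance=np.zeros(S),
    )
    return FitResult(
        spec=spec, samples=samples, summaries=pd.DataFrame(), dic=0.0, pd=0.0,
        acceptance_rates={}, seed=0, column_names=["g=y"],
        area_ids=tuple(area_ids), factor_spec={"g": ["x", "y"]},
        reference_levels={"g": "x"},
    )


class TestOddsRatios:
    def test_zero_coefficients_give_unit_or(self):
        fit = make_synthetic_fit(np.zeros((50, 1)))
        tab = sp.odds_ratio_table(fit).set_index("level")
        assert tab.loc["y", "or"] == pytest.approx(1.0)
        assert tab.loc["x", "reference"]

    def test_location_ln2_gives_or_two(self):
        rng = np.random.default_rng(0)
        fit = make_synthetic_fit(rng.normal(np.log(2), 1e-4, (400, 1)))
        tab = sp.odds_ratio_table(fit).set_index("level")
        assert tab.loc["y", "or"] == pytest.approx(2.0, rel=1e-3)

    def test_interval_is_exp_of_beta_percentiles(self):
        rng = np.random.default_rng(1)
        b = rng.normal(0.5, 0.3, (500, 1))
        fit = make_synthetic_fit(b)
        tab = sp.odds_ratio_table(fit).set_index("level")
        assert tab.loc["y", "or_low"] == pytest.approx(np.exp(np.percentile(b, 2.5)))
        assert tab.loc["y", "or_high"] == pytest.approx(np.exp(np.percentile(b, 97.5)))


class TestPrevalenceMap:
    def _records(self, amap):
        n = amap.n_areas * 4
        return pd.DataFrame({
            "outcome": [0, 1] * (n // 2),
            "weight": np.ones(n),
            "stratum_id": ["s"] * n,
            "psu_id": [f"p{i}" for i in range(n)],
            "area_id": list(amap.area_ids) * 4,
            "g": ["x"] * n,
        })

    def test_degenerate_null_posterior_maps_to_half(self):
        amap = line_map(3)
        fit = make_synthetic_fit(np.zeros((20, 1)), f_s=np.zeros((20, 3)),
                                 area_ids=amap.area_ids)
        prev = sp.posterior_prevalence_map(fit, self._records(amap), amap)
        np.testing.assert_allclose(prev["mean"], 0.5)

    def test_quantile_ordering(self, survey20, lattice20):
        fit = sp.fit_model(survey20, lattice20, sp.ModelSpec.from_number(3),
                           factor_spec=sp.default_factor_spec(),
                           mcmc={"iterations": 500, "burn_in": 200, "thin": 2,
                                 "seed": 9})
        prev = sp.posterior_prevalence_map(fit, survey20, lattice20)
        assert (prev["q025"] <= prev["median"] + 1e-12).all()
        assert (prev["median"] <= prev["q975"] + 1e-12).all()
        assert prev["mean"].between(0, 1).all()

    def test_area_effect_lifts_prevalence_to_logistic_value(self):
        amap = line_map(3)
        S = 30
        f_s = np.tile([1.0, 0.0, 0.0], (S, 1))
        fit = make_synthetic_fit(np.zeros((S, 1)), f_s=f_s, area_ids=amap.area_ids)
        prev = sp.posterior_prevalence_map(fit, self._records(amap), amap)
        assert prev.loc["1", "mean"] == pytest.approx(expit(1.0), abs=1e-9)

    def test_area_without_records_flagged(self):
        amap = line_map(3)
        rec = self._records(amap)
        rec = rec[rec["area_id"] != "3"]
        fit = make_synthetic_fit(np.zeros((10, 1)), f_s=np.zeros((10, 3)),
                                 area_ids=amap.area_ids)
        prev = sp.posterior_prevalence_map(fit, rec, amap)
        assert bool(prev.loc["3", "no_records"])
        assert prev.loc["3", "mean"] == pytest.approx(0.5)
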