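import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, multivariate_normal

from famvc import (
    CovariateSpec,
    FitOptions,
    RandomEffectDesign,
    SimulationConfig,
    SubjectRecord,
    aic,
    block_covariance,
    build_family_data,
    build_kinship_grm,
    compare_models,
    derive_pregnancy_id,
    fit_ml,
    fit_model,
    log_likelihood,
    profile_ci,
    residualize,
    simulate_dataset,
    total_variance,
)
from famvc.relatedness import subjects_from_frame

from conftest import residuals_and_obs


def dense_reference_loglik(obs, resid, grm, fractions, sigma2):
    """Independent oracle: assemble the full dense covariance over all
    observations directly from the model's rules and evaluate one
    multivariate-normal log-density."""
    n = len(obs)
    subs = obs["subject_id"].astype(str).to_numpy()
    fams = obs["family_id"].astype(str).to_numpy()
    pregs = obs["pregnancy_id"].astype(str).to_numpy()
    pos = {s: i for i, s in enumerate(grm.ids)}
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if fams[i] != fams[j]:
                continue
            a = 1.0 if subs[i] == subs[j] else grm.values[pos[subs[i]], pos[subs[j]]]
            V[i, j] = (
                fractions.get("A", 0) * a
                + fractions.get("C", 0)
                + fractions.get("T", 0) * (pregs[i] == pregs[j])
                + fractions.get("S", 0) * (subs[i] == subs[j])
                + fractions.get("E", 0) * (i == j)
            )
    return multivariate_normal.logpdf(resid, mean=np.zeros(n), cov=sigma2 * V)


class TestTotalVariance:
    def test_two_point_example(self):
        assert total_variance(np.array([1.0, -1.0]), df_used=1) == 2.0

    def test_zero_residuals_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert total_variance(np.zeros(5), df_used=1) == 0.0

    def test_unbiased_under_monte_carlo(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100_000)
        r = x - x.mean()
        assert total_variance(r, df_used=1) == pytest.approx(1.0, abs=0.02)

    def test_rejects_when_df_consumes_sample(self):
        with pytest.raises(ValueError, match="exceed"):
            total_variance(np.array([1.0, 2.0]), df_used=2)

    def test_n_minus_one_denominator_option(self):
        r = np.array([1.0, -1.0, 2.0, -2.0])
        assert total_variance(r, df_used=2, denominator="n-1") == pytest.approx(
            (r @ r) / 3
        )


class TestBlockCovariance:
    def test_singleton_collapses_to_total_variance(self):
        comps = {e: np.ones((1, 1)) for e in "ACE"}
        V = block_covariance({"A": 0.3, "C": 0.3, "E": 0.4}, 2.5, comps)
        np.testing.assert_allclose(V, [[2.5]])

    @pytest.mark.parametrize("kin,expected_off", [(1.0, 0.8), (0.5, 0.5)])
    def test_twin_pair_off_diagonal(self, kin, expected_off):
        comps = {
            "A": np.array([[1.0, kin], [kin, 1.0]]),
            "C": np.ones((2, 2)),
            "E": np.eye(2),
        }
        V = block_covariance({"A": 0.6, "C": 0.2, "E": 0.2}, 3.0, comps)
        assert V[0, 1] == pytest.approx(3.0 * expected_off)
        np.testing.assert_allclose(np.diag(V), 3.0)

    def test_off_simplex_fractions_rejected(self):
        comps = {"A": np.eye(2), "E": np.eye(2)}
        with pytest.raises(ValueError, match="simplex"):
            block_covariance({"A": 0.7, "E": 0.7}, 1.0, comps)


class TestLogLikelihood:
    def test_singleton_closed_form(self):
        obs = pd.DataFrame({"subject_id": ["a"], "family_id": ["f"],
                            "visit": ["baseline"]})
        grm = build_kinship_grm([SubjectRecord("a", "f", "2008-01-01")])
        y, s2 = 0.7, 1.3
        data = build_family_data(obs, np.array([y]), grm, "ACE")
        ll = log_likelihood({"A": 0.5, "C": 0.2, "E": 0.3}, s2, data)
        expected = -0.5 * np.log(2 * np.pi * s2) - y**2 / (2 * s2)
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_block_sum_equals_dense_density_on_mixed_toy(self):
        # families of size 1, 2 and 4 (sibling pair x 2 visits)
        subs = [
            SubjectRecord("a", "f1", "2008-01-01"),
            SubjectRecord("b", "f2", "2008-02-02", "MZ"),
            SubjectRecord("c", "f2", "2008-02-02", "MZ"),
            SubjectRecord("d", "f3", "2008-03-03"),
            SubjectRecord("e", "f3", "2009-04-04"),
        ]
        grm = build_kinship_grm(subs)
        preg = derive_pregnancy_id(subs)
        rows = [("a", "f1", 1), ("b", "f2", 1), ("c", "f2", 1),
                ("d", "f3", 1), ("d", "f3", 2), ("e", "f3", 1), ("e", "f3", 2)]
        obs = pd.DataFrame(rows, columns=["subject_id", "family_id", "visit"])
        obs["pregnancy_id"] = obs["subject_id"].map(preg)
        rng = np.random.default_rng(1)
        resid = rng.standard_normal(len(obs))
        frac = {"A": 0.35, "C": 0.15, "T": 0.1, "S": 0.15, "E": 0.25}
        data = build_family_data(obs, resid, grm, "ACTSE")
        ll = log_likelihood(frac, 1.7, data)
        ref = dense_reference_loglik(obs, resid, grm, frac, 1.7)
        assert ll == pytest.approx(ref, abs=1e-10)

    def test_a_c_swap_invariance_on_mz_pairs(self):
        # on MZ pairs the relatedness block equals the all-ones block, so
        # likelihood depends on A and C only through their sum
        cfg = SimulationConfig(n_mz=40, seed=2)
        table, grm, _ = simulate_dataset(cfg)
        rp, obs = residuals_and_obs(table)
        data = build_family_data(obs, rp.values.to_numpy(), grm, "ACE")
        s2 = total_variance(rp)
        ll1 = log_likelihood({"A": 0.6, "C": 0.2, "E": 0.2}, s2, data)
        ll2 = log_likelihood({"A": 0.2, "C": 0.6, "E": 0.2}, s2, data)
        assert ll1 == pytest.approx(ll2, abs=1e-12)

    def test_degenerate_block_is_effectively_infeasible(self):
        obs = pd.DataFrame({"subject_id": ["a", "b"], "family_id": ["f", "f"],
                            "visit": [1, 1]})
        subs = [SubjectRecord("a", "f", "2008-01-01", "MZ"),
                SubjectRecord("b", "f", "2008-01-01", "MZ")]
        grm = build_kinship_grm(subs)
        # residuals orthogonal to the all-ones direction: with f_E = 0 the
        # MZ-pair covariance is singular, so after the diagonal jitter
        # rescue the density collapses (optimizer treats it as infeasible)
        data = build_family_data(obs, np.array([1.0, -1.0]), grm, "AE")
        ll = log_likelihood({"A": 1.0, "E": 0.0}, 1.0, data)
        assert ll < -1e6
        # a well-conditioned point on the same data stays ordinary
        assert log_likelihood({"A": 0.5, "E": 0.5}, 1.0, data) > -10


class TestRandomEffectDesign:
    @pytest.mark.parametrize("model", ["ACE", "ACTE", "ACSE", "ACTSE", "AE", "E"])
    def test_valid_models_parse(self, model):
        d = RandomEffectDesign.from_string(model)
        assert d.model == model
        assert d.n_free == len(model) - 1

    @pytest.mark.parametrize("model", ["ACA", "AC", "EA", "CAE", "ACXE"])
    def test_invalid_models_rejected(self, model):
        with pytest.raises(ValueError):
            RandomEffectDesign.from_string(model)

    def test_s_requires_repeat_visits(self, ace_toy):
        with pytest.raises(ValueError, match="visits"):
            fit_model(ace_toy["table"], "pheno", "ACSE")


class TestFitML:
    def test_pure_noise_attributes_variance_to_e(self):
        cfg = SimulationConfig(n_mz=100, n_dz=100, n_sib=100,
                               fractions={"E": 1.0}, seed=3)
        table, _, _ = simulate_dataset(cfg)
        fit = fit_model(table, "pheno", "ACE", options=FitOptions(compute_ci=False))
        assert fit.fractions["E"] >= 0.9
        assert fit.fractions["A"] <= 0.1

    def test_deterministic_across_repeat_calls(self, ace_toy):
        fit2 = fit_model(ace_toy["table"], "pheno", "ACE",
                         options=FitOptions(compute_ci=False))
        for e in "ACE":
            assert fit2.fractions[e] == ace_toy["fit"].fractions[e]
        assert fit2.log_likelihood == ace_toy["fit"].log_likelihood

    def test_fractions_on_simplex(self, ace_toy):
        f = ace_toy["fit"].fractions
        assert all(0.0 <= v <= 1.0 for v in f.values())
        assert sum(f.values()) == pytest.approx(1.0, abs=1e-8)

    def test_only_singleton_families_rejected(self):
        obs = pd.DataFrame({"subject_id": ["a", "b"], "family_id": ["f1", "f2"],
                            "visit": [1, 1]})
        subs = [SubjectRecord("a", "f1", "2008-01-01"),
                SubjectRecord("b", "f2", "2008-01-01")]
        with pytest.raises(ValueError, match="family with >= 2"):
            fit_ml(np.array([1.0, -1.0]), obs, build_kinship_grm(subs), "ACE")

    def test_e_only_model(self):
        cfg = SimulationConfig(n_sib=20, fractions={"E": 1.0}, seed=7)
        table, _, _ = simulate_dataset(cfg)
        fit = fit_model(table, "pheno", "E")
        assert fit.fractions == {"E": 1.0}
        assert fit.k == 0
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood)

    def test_joint_total_variance_mode_agrees_closely(self, ace_toy):
        fit_joint = fit_model(
            ace_toy["table"], "pheno", "ACE",
            options=FitOptions(compute_ci=False, jointly_estimate_total=True),
        )
        fixed = ace_toy["fit"]
        assert fit_joint.k == fixed.k + 1
        # ML sigma^2 differs from the unbiased estimate by O(p/n)
        assert fit_joint.total_variance == pytest.approx(
            fixed.total_variance, rel=0.05
        )
        for e in "ACE":
            assert fit_joint.fractions[e] == pytest.approx(
                fixed.fractions[e], abs=0.02
            )


class TestAicAndComparison:
    def test_direct_formula(self):
        assert aic(-100.0, 3) == 206.0

    def test_equal_k_delta_is_minus_two_delta_ll(self, ace_toy):
        base = ace_toy["fit"]
        other = fit_model(ace_toy["table"], "pheno", "ACE",
                          options=FitOptions(compute_ci=False,
                                             variance_denominator="n-1"))
        cmp = compare_models(base, other)
        assert cmp.delta_k == 0
        assert cmp.delta_aic == pytest.approx(-2 * cmp.delta_loglik)

    def test_identical_fits_compare_to_zero(self, ace_toy):
        cmp = compare_models(ace_toy["fit"], ace_toy["fit"])
        assert cmp.comparable
        assert cmp.delta_aic == 0.0
        assert all(d == 0.0 for d in cmp.fraction_differences.values())

    def test_different_samples_refuse_aic_but_report_differences(self, ace_toy):
        other_table, _, _ = simulate_dataset(
            SimulationConfig(n_mz=25, n_dz=25, n_sib=25, seed=99)
        )
        other = fit_model(other_table, "pheno", "ACE",
                          options=FitOptions(compute_ci=False))
        cmp = compare_models(ace_toy["fit"], other)
        assert not cmp.comparable
        assert cmp.delta_aic is None
        assert "A" in cmp.fraction_differences
        with pytest.raises(ValueError, match="different"):
            compare_models(ace_toy["fit"], other, require_aic=True)


class TestProfileCI:
    def test_threshold_is_half_chi2_quantile(self):
        assert chi2.ppf(0.95, df=1) / 2 == pytest.approx(1.9207, abs=1e-4)

    def test_interior_endpoints_sit_at_threshold(self):
        cfg = SimulationConfig(n_mz=70, n_dz=90, n_sib=70,
                               fractions={"A": 0.5, "C": 0.25, "E": 0.25},
                               seed=21)
        table, _, _ = simulate_dataset(cfg)
        fit = fit_model(table, "pheno", "ACE")
        state = fit._lik
        delta = chi2.ppf(0.95, df=1) / 2
        for e in "ACE":
            lo, hi = fit.ci[e]
            assert lo <= fit.fractions[e] <= hi
            for end in (lo, hi):
                if 0.0 < end < 1.0:  # interior endpoint: re-optimize there
                    ll_end = state.profile_loglik(e, end)
                    assert ll_end == pytest.approx(
                        fit.log_likelihood - delta, abs=0.05
                    )

    def test_boundary_estimate_truncates_lower_endpoint_to_zero(self):
        cfg = SimulationConfig(n_mz=80, n_dz=80, n_sib=80,
                               fractions={"E": 1.0}, seed=13)
        table, _, _ = simulate_dataset(cfg)
        fit = fit_model(table, "pheno", "ACE")
        boundary = [e for e in "AC" if fit.fractions[e] == 0.0]
        assert boundary, "expected a boundary estimate on pure-noise data"
        for e in boundary:
            assert fit.ci[e][0] == 0.0

    def test_mz_only_flat_direction_detected(self):
        cfg = SimulationConfig(n_mz=80, fractions={"A": 0.5, "C": 0.3, "E": 0.2},
                               seed=31)
        table, _, _ = simulate_dataset(cfg)
        fit = fit_model(table, "pheno", "ACE")
        assert fit.ci["A"] == (0.0, 1.0)
        assert any("flat profile" in w for w in fit.warnings)

    def test_level_must_be_probability(self, ace_toy):
        with pytest.raises(ValueError, match="level"):
            profile_ci(ace_toy["fit"], "A", level=1.5)

    def test_unknown_effect_rejected(self, ace_toy):
        with pytest.raises(KeyError):
            profile_ci(ace_toy["fit"], "S")
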