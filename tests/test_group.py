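"""Group averaging, posterior differences, contribution analysis and
cohort statistics."""

import math

import numpy as np
import pytest

from bgdcm.circuit import ParameterVector
from bgdcm.cohort import make_fixture, sample_subject
from bgdcm.group import (
    ContributionTable,
    GroupPosterior,
    band_power,
    bayesian_parameter_average,
    cohort_stats,
    contribution,
    contribution_table,
    gamma_contribution,
    perturbed_spectrum,
    prob_difference,
)
from bgdcm.inversion import Posterior


def _post(names, mean, var):
    p = len(names)
    return Posterior(names=names, mean=np.asarray(mean, dtype=float),
                     cov=np.diag(var), lam=0.0, lam_var=0.1, free_energy=0.0)


class TestBayesianParameterAverage:
    def test_identical_posteriors_divide_covariance(self):
        names = ["a", "b"]
        posts = [_post(names, [1.0, -2.0], [0.5, 2.0]) for _ in range(4)]
        g = bayesian_parameter_average(posts)
        assert np.allclose(g.mean, [1.0, -2.0])
        assert np.allclose(g.cov, np.diag([0.5 / 4, 2.0 / 4]))
        assert g.n_subjects == 4

    def test_two_univariate_gaussians_closed_form(self):
        p1 = _post(["x"], [1.0], [0.25])
        p2 = _post(["x"], [3.0], [1.0])
        g = bayesian_parameter_average([p1, p2])
        w1, w2 = 1 / 0.25, 1 / 1.0
        mu = (w1 * 1.0 + w2 * 3.0) / (w1 + w2)
        var = 1.0 / (w1 + w2)
        assert g.mean[0] == pytest.approx(mu, abs=1e-12)
        assert g.cov[0, 0] == pytest.approx(var, abs=1e-12)

    def test_order_invariance(self):
        posts = [_post(["x", "y"], [i, -i], [0.5 + i, 1.0]) for i in range(3)]
        g1 = bayesian_parameter_average(posts)
        g2 = bayesian_parameter_average(posts[::-1])
        assert np.allclose(g1.mean, g2.mean, atol=1e-12)
        assert np.allclose(g1.cov, g2.cov, atol=1e-12)

    def test_group_precision_at_least_best_subject(self):
        posts = [_post(["x"], [0.0], [0.3]), _post(["x"], [1.0], [0.9])]
        g = bayesian_parameter_average(posts)
        assert g.cov[0, 0] <= 0.3

    def test_mismatched_names_rejected(self):
        with pytest.raises(ValueError):
            bayesian_parameter_average([_post(["a"], [0], [1]),
                                        _post(["b"], [0], [1])])


class TestProbDifference:
    def _group(self, mean, var):
        return GroupPosterior(names=["x"], mean=np.array([mean]),
                              cov=np.array([[var]]), n_subjects=1)

    def test_identical_marginals_give_half(self):
        g = self._group(0.3, 0.2)
        assert prob_difference(g, g, "x") == pytest.approx(0.5)

    def test_ten_pooled_sd_apart_crosses_threshold(self):
        a = self._group(10.0 * math.sqrt(2.0), 1.0)
        b = self._group(0.0, 1.0)
        assert prob_difference(a, b, "x") > 0.9999

    def test_symmetry(self):
        a, b = self._group(0.4, 0.5), self._group(-0.1, 0.3)
        assert prob_difference(a, b, "x") + prob_difference(b, a, "x") == \
            pytest.approx(1.0, abs=1e-12)

    def test_unknown_parameter_rejected(self):
        g = self._group(0.0, 1.0)
        with pytest.raises(ValueError):
            prob_difference(g, g, "nope")


class TestBandPower:
    def test_beta_band_sums_three_bins(self, circuit, parkinsonian_params):
        from bgdcm.spectra import default_grid, predict_csd

        grid = default_grid()
        cs = predict_csd(parkinsonian_params, circuit,
                         include_channel_noise=False)
        bins = (grid >= 16) & (grid <= 18)
        assert bins.sum() == 3
        manual = cs.auto_spectra()[:, bins].sum(axis=1).mean()
        assert band_power(parkinsonian_params) == pytest.approx(manual, rel=1e-12)

    def test_doubling_gains_quadruples_band_power(self, circuit,
                                                  parkinsonian_params):
        pv = parkinsonian_params.copy()
        for src in circuit.observed_sources:
            pv[f"gain_{src}"] = pv[f"gain_{src}"] + math.log(2.0)
        assert band_power(pv) == pytest.approx(
            4.0 * band_power(parkinsonian_params), rel=1e-10)

    def test_band_outside_grid_rejected(self, parkinsonian_params):
        with pytest.raises(ValueError, match="outside grid"):
            band_power(parkinsonian_params, band=(59.0, 61.0))


class TestContribution:
    def test_matches_quadratic_fit_oracle(self, circuit, parkinsonian_params):
        """Derivative agrees with the slope of a quadratic fit through
        +-1% and +-2% log-scale perturbations."""
        name = "c_str_gpe"
        d = contribution(parkinsonian_params, name)
        deltas = np.array([-0.02, -0.01, 0.01, 0.02])
        powers = []
        for dd in deltas:
            pv = parkinsonian_params.copy()
            pv[name] = pv[name] + dd
            powers.append(band_power(pv))
        coef = np.polyfit(deltas, powers, 2)
        assert d == pytest.approx(coef[1], rel=0.05)

    def test_parkinsonian_indirect_pathway_contributions_positive(
            self, parkinsonian_params):
        assert contribution(parkinsonian_params, "c_str_gpe") > 0
        assert contribution(parkinsonian_params, "c_gpe_stn") > 0

    def test_non_extrinsic_name_rejected(self, parkinsonian_params):
        with pytest.raises(ValueError, match="not an extrinsic"):
            contribution(parkinsonian_params, "g_ctx_py_ctx_ii")

    def test_connection_feeding_dead_end_has_zero_contribution(self, circuit,
                                                               prior_params):
        """With EPN's only efferent silenced, the striatum->EPN connection
        cannot reach any observed channel, so its contribution vanishes."""
        pv = prior_params.copy()
        pv["c_epn_tha"] = -40.0
        d = contribution(pv, "c_str_epn")
        scale = abs(band_power(pv)) + 1.0
        assert abs(d) < 1e-6 * scale


class TestGammaContribution:
    def test_gamma_band_requires_extended_grid(self, parkinsonian_params):
        with pytest.raises(ValueError, match="outside grid"):
            contribution(parkinsonian_params, "c_str_gpe", band=(59.0, 61.0))
        # the dedicated entry point supplies the extended grid
        gamma_contribution(parkinsonian_params, "c_str_gpe")

    def test_reduces_to_beta_contribution_on_beta_band(self, parkinsonian_params):
        from bgdcm.spectra import extended_grid

        d1 = contribution(parkinsonian_params, "c_str_gpe", band=(16.0, 18.0),
                          grid=extended_grid(100.0))
        d2 = contribution(parkinsonian_params, "c_str_gpe")
        assert d1 == pytest.approx(d2, rel=1e-9)

    def test_no_systematic_parkinsonian_gamma_elevation(self, circuit):
        """Across a 10-subject cohort pair, the indirect-pathway gamma
        contributions show no consistent parkinsonian elevation
        (sign test p > 0.05)."""
        from scipy.stats import binomtest

        wins = 0
        n = 10
        for i in range(n):
            vals = {}
            for regime in ("parkinsonian", "control"):
                subj = sample_subject(make_fixture(regime), between_sd=0.1,
                                      seed=300 + i, circuit=circuit)
                vals[regime] = (gamma_contribution(subj.params, "c_str_gpe")
                                + gamma_contribution(subj.params, "c_gpe_stn"))
            wins += vals["parkinsonian"] > vals["control"]
        assert binomtest(wins, n, 0.5, alternative="greater").pvalue > 0.05


class TestPerturbedSpectrum:
    def test_zero_scale_is_baseline(self, circuit, parkinsonian_params):
        base = perturbed_spectrum(parkinsonian_params, "c_str_gpe", 0.0)
        from bgdcm.spectra import predict_csd

        direct = predict_csd(parkinsonian_params, circuit,
                             include_channel_noise=False).auto_spectra().mean(axis=0)
        assert np.allclose(base, direct, rtol=1e-12)

    def test_striatum_gpe_boost_increases_beta(self, parkinsonian_params):
        from bgdcm.spectra import default_grid

        grid = default_grid()
        m = (grid >= 16) & (grid <= 18)
        base = perturbed_spectrum(parkinsonian_params, "c_str_gpe", 0.0)
        up = perturbed_spectrum(parkinsonian_params, "c_str_gpe", 0.5)
        assert up[m].sum() > base[m].sum()

    def test_small_perturbation_matches_linear_response(self, parkinsonian_params):
        from bgdcm.spectra import default_grid

        grid = default_grid()
        m = (grid >= 16) & (grid <= 18)
        name = "c_gpe_stn"
        scale = 0.01
        base = perturbed_spectrum(parkinsonian_params, name, 0.0)
        up = perturbed_spectrum(parkinsonian_params, name, scale)
        observed = up[m].sum() - base[m].sum()
        predicted = math.log1p(scale) * contribution(parkinsonian_params, name)
        assert observed == pytest.approx(predicted, rel=0.10)


class TestCohortStats:
    def test_degrees_of_freedom_9x9(self):
        rng = np.random.default_rng(0)
        table = ContributionTable(rng.standard_normal((9, 9)),
                                  [f"c{i}" for i in range(9)])
        out = cohort_stats(table)
        assert out["anova_df"] == (8, 72)

    def test_type_i_error_rate_under_null(self):
        """Equal-mean Gaussian columns: the ANOVA rejects at ~alpha."""
        rng = np.random.default_rng(1)
        alpha, n_sim = 0.05, 1000
        rejections = 0
        for _ in range(n_sim):
            table = ContributionTable(rng.standard_normal((9, 9)),
                                      [f"c{i}" for i in range(9)])
            rejections += cohort_stats(table)["anova_p"] < alpha
        # binomial 99% CI around alpha for n_sim trials
        se = math.sqrt(alpha * (1 - alpha) / n_sim)
        assert abs(rejections / n_sim - alpha) < 2.58 * se + 1e-9

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(2)
        table = ContributionTable(rng.standard_normal((6, 9)),
                                  [f"c{i}" for i in range(9)])
        out = cohort_stats(table)
        assert (out["ttests"]["p_bonferroni"] <= 1.0).all()

    def test_fewer_than_two_subjects_rejected(self):
        table = ContributionTable(np.zeros((1, 9)), [f"c{i}" for i in range(9)])
        with pytest.raises(ValueError):
            cohort_stats(table)

    def test_contribution_table_shape_and_export(self, circuit,
                                                 parkinsonian_params,
                                                 control_params):
        tab = contribution_table([parkinsonian_params, control_params])
        assert tab.values.shape == (2, 9)
        frame = tab.to_frame()
        assert list(frame.columns) == tab.connections


def test_regime_contrast_of_indirect_pathway_contributions(circuit):
    """Striatum->GPe and GPe->STN move beta power more when embedded in the
    parkinsonian network than in the control network (sign test over
    seeded cohort pairs)."""
    n_pairs, n_subj, wins = 10, 6, 0
    for i in range(n_pairs):
        means = {}
        for regime in ("parkinsonian", "control"):
            vals = []
            for j in range(n_subj):
                subj = sample_subject(make_fixture(regime), between_sd=0.1,
                                      seed=500 + i * n_subj + j,
                                      circuit=circuit)
                vals.append(contribution(subj.params, "c_str_gpe")
                            + contribution(subj.params, "c_gpe_stn"))
            means[regime] = np.mean(vals)
        wins += means["parkinsonian"] > means["control"]
    assert wins >= 8
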