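"""Variational-Laplace inversion: vectorisation, error model, free energy,
oracle equivalence and model comparison."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from bgdcm.circuit import ParameterVector, build_standard_circuit, build_variant_circuit
from bgdcm.cohort import make_fixture, sample_csd, sample_subject
from bgdcm.inversion import (
    ErrorCovariance,
    PriorSpec,
    compare_models,
    csd_feature_scales,
    error_covariance,
    free_energy,
    invert,
    invert_csd,
    load_priors,
    n_feature_components,
    unvectorize_csd,
    vectorize_csd,
)
from bgdcm.spectra import default_grid, predict_csd


class TestPriors:
    def test_shipped_table_matches_circuit(self, circuit):
        priors = load_priors(circuit)
        assert priors.names == list(ParameterVector(circuit).names)
        assert np.all(priors.variance > 0)

    def test_connectivity_looser_than_synaptic(self, circuit):
        priors = load_priors(circuit)
        v = dict(zip(priors.names, priors.variance))
        assert v["c_ctx_stn"] > v["H_stn"]

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(names=["a"], mean=[0.0], variance=[-1.0], classes=["noise"])

    def test_zero_variance_fixes_parameter(self, circuit, parkinsonian_params):
        priors = PriorSpec.from_circuit(circuit)
        i = priors.index("rho")
        priors.variance[i] = 0.0
        cs = predict_csd(parkinsonian_params, circuit)
        post = invert_csd(cs, circuit, priors=priors, max_iter=3,
                          update_lambda=False)
        assert post.mean[i] == 0.0
        assert post.cov[i, i] == 0.0


class TestVectorise:
    def test_roundtrip_identity(self, circuit, parkinsonian_params):
        cs = predict_csd(parkinsonian_params, circuit)
        vec = vectorize_csd(cs)
        back = unvectorize_csd(vec, cs.grid, cs.channels)
        assert np.allclose(back.values, cs.values, atol=0.0)

    def test_length_for_4_channels_26_freqs(self, circuit, prior_params):
        cs = predict_csd(prior_params, circuit)
        assert len(vectorize_csd(cs)) == 26 * (4 + 12) == 416

    def test_ordering_deterministic(self, circuit, prior_params):
        cs = predict_csd(prior_params, circuit)
        assert np.array_equal(vectorize_csd(cs), vectorize_csd(cs.copy()))

    def test_non_hermitian_rejected(self, circuit, prior_params):
        cs = predict_csd(prior_params, circuit)
        cs.values[0, 1, 0] += 1.0
        with pytest.raises(ValueError, match="Hermitian"):
            vectorize_csd(cs)


class TestErrorCovariance:
    def test_zero_correlation_length_is_diagonal(self):
        V = error_covariance(0.0, default_grid(), 2, corr_length=0.0)
        assert np.allclose(V, np.diag(np.diag(V)))

    def test_lambda_shift_doubles_covariance(self):
        g = default_grid()
        V1 = error_covariance(0.3, g, 2)
        V2 = error_covariance(0.3 + np.log(2.0), g, 2)
        assert np.allclose(V2, 2.0 * V1, rtol=1e-12)

    def test_positive_definite_default(self):
        ec = ErrorCovariance(default_grid(), n_feature_components(4))
        assert ec.min_eigenvalue() > 0
        V = error_covariance(0.0, default_grid(), 3)
        assert np.min(np.linalg.eigvalsh(V)) > 0

    def test_solve_and_logdet_match_dense(self):
        g = default_grid()
        rng = np.random.default_rng(0)
        scales = rng.uniform(0.5, 2.0, size=len(g) * 2)
        ec = ErrorCovariance(g, 2, scales=scales)
        V = error_covariance(0.4, g, 2, scales=scales)
        x = rng.standard_normal(len(g) * 2)
        assert np.allclose(ec.solve(0.4, x), np.linalg.solve(V, x), rtol=1e-8)
        assert ec.logdet(0.4) == pytest.approx(np.linalg.slogdet(V)[1], rel=1e-10)


def _toy_linear_setup(seed=0, n_p=3, F=10, ncomp=2):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(F * ncomp, n_p))
    priors = PriorSpec(names=[f"p{i}" for i in range(n_p)],
                       mean=np.zeros(n_p),
                       variance=np.array([0.5, 0.5, 0.25]),
                       classes=["connectivity"] * n_p)
    ec = ErrorCovariance(np.arange(F, dtype=float), ncomp)
    return rng, X, priors, ec


class TestFreeEnergy:
    def test_zero_residual_at_prior_mean_leaves_normalising_term(self):
        _, X, priors, ec = _toy_linear_setup()
        y = X @ priors.mean
        lam = -0.7
        F = free_energy(y, y, priors.mean, priors, lam, ec)
        expected = -0.5 * ec.n * np.log(2 * np.pi) - 0.5 * ec.logdet(lam)
        assert F == pytest.approx(expected, abs=1e-10)

    def test_matches_closed_form_log_evidence(self):
        """On a linear-Gaussian model the Laplace free energy at the exact
        posterior equals the log marginal likelihood."""
        rng, X, priors, ec = _toy_linear_setup(seed=1)
        lam = -0.5
        Se = error_covariance(lam, np.arange(10, dtype=float), 2)
        y = X @ np.array([0.3, -0.2, 0.1]) + rng.multivariate_normal(
            np.zeros(ec.n), Se)
        Sei = np.linalg.inv(Se)
        Sq = np.linalg.inv(X.T @ Sei @ X + np.diag(1 / priors.variance))
        mu = Sq @ (X.T @ Sei @ y)
        F = free_energy(y, X @ mu, mu, priors, lam, ec, jacobian=X,
                        posterior_cov=Sq)
        lml = multivariate_normal.logpdf(
            y, mean=X @ priors.mean,
            cov=Se + X @ np.diag(priors.variance) @ X.T)
        assert F == pytest.approx(lml, abs=1e-6)

    def test_unused_parameter_never_increases_free_energy(self):
        """Adding a parameter with prior uncertainty costs complexity even
        when the fit is unchanged."""
        rng, X, priors, ec = _toy_linear_setup(seed=2)
        lam = 0.0
        y = X @ np.array([0.2, 0.1, -0.1])
        Sei = np.linalg.inv(error_covariance(lam, np.arange(10, dtype=float), 2))
        Sq = np.linalg.inv(X.T @ Sei @ X + np.diag(1 / priors.variance))
        mu = Sq @ (X.T @ Sei @ y)
        F_small = free_energy(y, X @ mu, mu, priors, lam, ec, jacobian=X,
                              posterior_cov=Sq)
        # augment with a parameter the data do not inform (zero column)
        X2 = np.hstack([X, np.zeros((ec.n, 1))])
        priors2 = PriorSpec(names=priors.names + ["extra"],
                            mean=np.zeros(4),
                            variance=np.append(priors.variance, 0.5),
                            classes=priors.classes + ["connectivity"])
        Sq2 = np.linalg.inv(X2.T @ Sei @ X2 + np.diag(1 / priors2.variance))
        mu2 = Sq2 @ (X2.T @ Sei @ y)
        F_big = free_energy(y, X2 @ mu2, mu2, priors2, lam, ec, jacobian=X2,
                            posterior_cov=Sq2)
        assert F_big <= F_small + 1e-9


class TestInvert:
    def test_linear_gaussian_matches_conjugate_posterior(self):
        rng, X, priors, ec = _toy_linear_setup(seed=3)
        lam = -1.0
        Se = error_covariance(lam, np.arange(10, dtype=float), 2)
        y = X @ np.array([0.4, -0.3, 0.2]) + rng.multivariate_normal(
            np.zeros(ec.n), Se)
        post = invert(y, lambda th: X @ th, priors,
                      grid=np.arange(10, dtype=float), n_components=2,
                      update_lambda=False, lam_init=lam)
        Sei = np.linalg.inv(Se)
        Sq = np.linalg.inv(X.T @ Sei @ X + np.diag(1 / priors.variance))
        mu = Sq @ (X.T @ Sei @ y)
        assert np.max(np.abs(post.mean - mu)) < 1e-4
        assert np.max(np.abs(post.cov - Sq)) < 1e-4
        lml = multivariate_normal.logpdf(
            y, mean=X @ priors.mean,
            cov=Se + X @ np.diag(priors.variance) @ X.T)
        assert post.free_energy == pytest.approx(lml, abs=1e-4)

    def test_self_consistency_at_prior_means(self, circuit, prior_params):
        """Noise-free data generated at the prior means keep the posterior
        at the prior."""
        cs = predict_csd(prior_params, circuit)
        priors = PriorSpec.from_circuit(circuit)
        post = invert_csd(cs, circuit, max_iter=16)
        sd = np.sqrt(priors.variance)
        assert np.max(np.abs(post.mean - priors.mean) / sd) < 0.3

    def test_free_energy_trace_nondecreasing(self, circuit,
                                             parkinsonian_subject_csd):
        _, csd = parkinsonian_subject_csd
        post = invert_csd(csd, circuit, max_iter=24)
        assert np.all(np.diff(post.trace) >= -1e-9)

    def test_posterior_covariance_psd(self, circuit, parkinsonian_subject_csd):
        _, csd = parkinsonian_subject_csd
        post = invert_csd(csd, circuit, max_iter=12)
        w = np.linalg.eigvalsh(0.5 * (post.cov + post.cov.T))
        assert w.min() >= -1e-12

    def test_hyperdirect_recovery_exceeds_control_fit(self, circuit):
        """Fitting parkinsonian-regime data recovers a larger hyperdirect
        deviation than fitting control-regime data, in most seeded runs."""
        wins = 0
        runs = 3
        for seed in range(runs):
            vals = {}
            for regime in ("parkinsonian", "control"):
                subj = sample_subject(make_fixture(regime), between_sd=0.1,
                                      seed=100 + seed, circuit=circuit)
                csd = sample_csd(subj, n_segments=60, seed=200 + seed)
                post = invert_csd(csd, circuit, max_iter=48)
                vals[regime] = post.marginal("c_ctx_stn")[0]
            if vals["parkinsonian"] > vals["control"]:
                wins += 1
        assert wins >= 2


class TestCompareModels:
    def _posterior(self, circuit, F, data_hash="h"):
        from bgdcm.inversion import Posterior

        p = len(ParameterVector(circuit).names)
        return Posterior(names=list(ParameterVector(circuit).names),
                         mean=np.zeros(p), cov=np.eye(p), lam=0.0,
                         lam_var=0.1, free_energy=F, data_hash=data_hash)

    def test_identical_models_have_unit_bayes_factor(self, circuit):
        table = compare_models([self._posterior(circuit, -100.0),
                                self._posterior(circuit, -100.0)])
        assert np.allclose(table["bayes_factor_vs_best"], 1.0)
        assert np.allclose(table["posterior_prob"], 0.5)

    def test_delta_f_is_log_bayes_factor(self, circuit):
        table = compare_models([self._posterior(circuit, -100.0),
                                self._posterior(circuit, -103.0)])
        assert np.allclose(np.exp(table["delta_f"]),
                           table["bayes_factor_vs_best"])

    def test_mismatched_data_rejected(self, circuit):
        with pytest.raises(ValueError, match="different data"):
            compare_models([self._posterior(circuit, -1.0, "a"),
                            self._posterior(circuit, -2.0, "b")])

    def test_standard_model_beats_pallidofugal_variant(self, circuit):
        """Evidence for the standard circuit is at least that of the
        GPe->EPN variant on data generated from the standard circuit."""
        subj = sample_subject(make_fixture("parkinsonian"), between_sd=0.1,
                              seed=42, circuit=circuit)
        csd = sample_csd(subj, n_segments=60, seed=43)
        post_std = invert_csd(csd, circuit, max_iter=32)
        variant = build_variant_circuit("gpe_to_epn")
        post_var = invert_csd(csd, variant, max_iter=32)
        assert post_std.free_energy >= post_var.free_energy - 3.0


def test_identifiability_posterior_correlations(circuit, parkinsonian_subject_csd):
    """Mean magnitude of posterior correlations between extrinsic
    connectivity parameters stays modest (no strong identifiability
    failure)."""
    _, csd = parkinsonian_subject_csd
    post = invert_csd(csd, circuit, max_iter=32)
    names = [circuit.connection_param(c) for c in circuit.extrinsic_connections()]
    idx = [post.names.index(n) for n in names]
    cov = post.cov[np.ix_(idx, idx)]
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    off = corr[~np.eye(len(idx), dtype=bool)]
    assert np.mean(np.abs(off)) < 0.5
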