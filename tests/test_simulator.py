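import numpy as np
import pytest

from bsde import (
    DESpec,
    ParamPrior,
    ZINBParams,
    default_prior,
    generate_dataset,
    mean_de_params,
    multimodal_de_counts,
    multimodal_single_params,
    proportion_de_counts,
    rzinb,
    sample_params,
    simulate_gene_subject,
    variance_de_params,
    zinb_mean_var,
)


class TestSampleParams:
    def test_zero_covariance_hits_transformed_mean(self):
        prior = ParamPrior(default_prior().mean, np.zeros((4, 4)))
        p = sample_params(prior, np.random.default_rng(0))
        assert p.mu == pytest.approx(2.0)
        assert p.phi == pytest.approx(1.0)
        assert p.z == pytest.approx(0.3)
        assert p.sigma == pytest.approx(0.3)

    def test_seed_determinism(self):
        prior = default_prior()
        a = sample_params(prior, np.random.default_rng(42))
        b = sample_params(prior, np.random.default_rng(42))
        assert (a.mu, a.phi, a.z, a.sigma) == (b.mu, b.phi, b.z, b.sigma)

    def test_log_mean_matches_prior_mean_in_large_samples(self):
        prior = default_prior()
        rng = np.random.default_rng(1)
        draws = np.log([sample_params(prior, rng).mu for _ in range(10_000)])
        se = np.sqrt(prior.covariance[0, 0] / 10_000)
        assert abs(draws.mean() - prior.mean[0]) < 3 * se

    def test_non_psd_covariance_rejected(self):
        cov = np.eye(4)
        cov[0, 0] = -1.0
        with pytest.raises(ValueError):
            ParamPrior(default_prior().mean, cov)


class TestRzinb:
    def test_full_dropout_all_zero(self):
        counts = rzinb(1000, mu=5.0, phi=2.0, z=1.0, rng=np.random.default_rng(0))
        assert np.all(counts == 0)

    def test_closed_form_moments(self):
        rng = np.random.default_rng(2)
        mu, phi, z, n = 5.0, 2.0, 0.3, 100_000
        counts = rzinb(n, mu, phi, z, rng)
        mean, var = zinb_mean_var(mu, phi, z)
        assert mean == pytest.approx(3.5) and var == pytest.approx(17.5)
        assert abs(counts.mean() - mean) < 3 * np.sqrt(var / n)
        assert counts.var() == pytest.approx(var, rel=0.05)

    def test_poisson_limit_at_large_phi(self):
        rng = np.random.default_rng(3)
        counts = rzinb(100_000, mu=4.0, phi=1e6, z=0.0, rng=rng)
        assert counts.var() == pytest.approx(4.0, rel=0.05)

    def test_invalid_params_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            rzinb(10, mu=-1.0, phi=1.0, z=0.0, rng=rng)
        with pytest.raises(ValueError):
            rzinb(10, mu=1.0, phi=1.0, z=1.5, rng=rng)


class TestSimulateGeneSubject:
    def test_sigma_zero_matches_zinb_moments(self):
        params = ZINBParams(mu=5.0, phi=2.0, z=0.3, sigma=0.0)
        counts = simulate_gene_subject(params, 100_000, np.random.default_rng(4))
        mean, var = zinb_mean_var(5.0, 2.0, 0.3)
        assert abs(counts.mean() - mean) < 3 * np.sqrt(var / 100_000)
        assert counts.var() == pytest.approx(var, rel=0.05)

    def test_cell_level_variability_inflates_variance(self):
        base = ZINBParams(mu=5.0, phi=2.0, z=0.3, sigma=0.0)
        noisy = ZINBParams(mu=5.0, phi=2.0, z=0.3, sigma=0.8)
        rng = np.random.default_rng(5)
        v0 = simulate_gene_subject(base, 100_000, rng).var()
        v1 = simulate_gene_subject(noisy, 100_000, rng).var()
        assert v1 > v0

    def test_single_cell(self):
        params = ZINBParams(mu=2.0, phi=1.0, z=0.2, sigma=0.3)
        counts = simulate_gene_subject(params, 1, np.random.default_rng(6))
        assert counts.shape == (1,)


class TestMeanDE:
    def test_identity_factor(self):
        p = ZINBParams(mu=3.0, phi=2.0, z=0.1, sigma=0.2)
        q = mean_de_params(p, 1.0)
        assert (q.mu, q.phi, q.z) == (p.mu, p.phi, p.z)

    def test_closed_form_example(self):
        q = mean_de_params(ZINBParams(mu=10.0, phi=5.0, z=0.1), 2.0)
        assert q.mu == pytest.approx(20.0)
        assert q.phi == pytest.approx(40.0)
        assert 20 + 400 / 40 == pytest.approx(10 + 100 / 5)

    def test_nb_variance_invariant_on_random_draws(self):
        rng = np.random.default_rng(7)
        prior = default_prior()
        checked = 0
        while checked < 50:
            p = sample_params(prior, rng)
            r = rng.uniform(0.5, 1.2)
            try:
                q = mean_de_params(p, r)
            except ValueError:
                continue
            assert q.mu + q.mu**2 / q.phi == pytest.approx(p.mu + p.mu**2 / p.phi, abs=1e-9)
            checked += 1

    def test_inadmissible_draw_rejected(self):
        # r_mu > 1 + mu/phi makes the equal-variance dispersion nonpositive
        with pytest.raises(ValueError):
            mean_de_params(ZINBParams(mu=1.0, phi=10.0, z=0.1), 4.0)
        with pytest.raises(ValueError):
            mean_de_params(ZINBParams(mu=1.0, phi=1.0, z=0.1), -1.0)


class TestVarianceDE:
    def test_identity_factor(self):
        p = ZINBParams(mu=5.0, phi=2.0, z=0.3)
        assert variance_de_params(p, 1.0).phi == pytest.approx(2.0)

    def test_closed_form_example(self):
        q = variance_de_params(ZINBParams(mu=5.0, phi=2.0, z=0.3), 2.0)
        assert q.phi == pytest.approx(10 / (10 + 2 + 3))

    def test_full_zinb_variance_scales_and_mean_preserved(self):
        rng = np.random.default_rng(8)
        prior = default_prior()
        for _ in range(50):
            p = sample_params(prior, rng)
            r = rng.uniform(1.0, 4.0)
            q = variance_de_params(p, r)
            m0, v0 = zinb_mean_var(p.mu, p.phi, p.z)
            m1, v1 = zinb_mean_var(q.mu, q.phi, q.z)
            assert m1 == pytest.approx(m0, abs=1e-12)
            assert v1 == pytest.approx(r * v0, rel=1e-9)


class TestProportionDE:
    def test_symmetric_mixture_is_null(self):
        p1 = ZINBParams(mu=2.0, phi=1.0, z=0.2)
        p2 = ZINBParams(mu=4.0, phi=1.0, z=0.2)
        rng = np.random.default_rng(9)
        case = proportion_de_counts(p1, p2, 0.5, "case", 200_000, rng)
        ctrl = proportion_de_counts(p1, p2, 0.5, "control", 200_000, rng)
        assert case.mean() == pytest.approx(ctrl.mean(), rel=0.03)

    def test_mixture_mean_closed_form(self):
        mu1, z = 3.0, 0.2
        p1 = ZINBParams(mu=mu1, phi=2.0, z=z)
        p2 = ZINBParams(mu=2 * mu1, phi=2.0, z=z)
        rng = np.random.default_rng(10)
        case = proportion_de_counts(p1, p2, 0.8, "case", 100_000, rng)
        ctrl = proportion_de_counts(p1, p2, 0.8, "control", 100_000, rng)
        m_case = (1 - z) * (0.8 * mu1 + 0.2 * 2 * mu1)
        m_ctrl = (1 - z) * (0.2 * mu1 + 0.8 * 2 * mu1)
        assert case.mean() == pytest.approx(m_case, rel=0.03)
        assert ctrl.mean() == pytest.approx(m_ctrl, rel=0.03)

    def test_degenerate_weight_gives_pure_components(self):
        p1 = ZINBParams(mu=2.0, phi=1e6, z=0.0)
        p2 = ZINBParams(mu=50.0, phi=1e6, z=0.0)
        rng = np.random.default_rng(11)
        case = proportion_de_counts(p1, p2, 1.0, "case", 50_000, rng)
        assert case.mean() == pytest.approx(2.0, rel=0.05)

    def test_mismatched_components_rejected(self):
        p1 = ZINBParams(mu=2.0, phi=1.0, z=0.2)
        p2 = ZINBParams(mu=4.0, phi=2.0, z=0.2)
        with pytest.raises(ValueError, match="share"):
            proportion_de_counts(p1, p2, 0.8, "case", 10, np.random.default_rng(0))


class TestMultimodalDE:
    def test_stated_mean_relations(self):
        star = multimodal_single_params(ZINBParams(mu=3.0, phi=2.0, z=0.3), 0.5)
        assert star.mu == pytest.approx(6.0)  # mu* = mu2/(1-rm); mu1 = 9

    def test_vanishing_separation_recovers_null(self):
        p2 = ZINBParams(mu=3.0, phi=2.0, z=0.3)
        star = multimodal_single_params(p2, 1e-9)
        assert star.mu == pytest.approx(3.0, rel=1e-6)
        assert star.phi == pytest.approx(2.0, rel=1e-4)

    def test_arm_moments_match_analytically(self):
        p2 = ZINBParams(mu=3.0, phi=2.0, z=0.3)
        r_m = 0.4
        star = multimodal_single_params(p2, r_m)
        mu1 = 3.0 * 1.4 / 0.6
        m1, v1 = zinb_mean_var(mu1, 2.0, 0.3)
        m2, v2 = zinb_mean_var(3.0, 2.0, 0.3)
        mix_mean = 0.5 * (m1 + m2)
        mix_var = 0.5 * (v1 + v2) + 0.25 * (m1 - m2) ** 2
        ms, vs = zinb_mean_var(star.mu, star.phi, star.z)
        assert ms == pytest.approx(mix_mean, abs=1e-12)
        assert vs == pytest.approx(mix_var, rel=1e-12)

    def test_invalid_size_factor_rejected(self):
        with pytest.raises(ValueError):
            multimodal_de_counts(
                ZINBParams(mu=3.0, phi=2.0, z=0.3), 1.5, "case", 10, np.random.default_rng(0)
            )


class TestGenerateDataset:
    def test_shapes_and_labels(self):
        ds = generate_dataset(n_genes=6, n_per_arm=3, m=4, seed=0)
        assert ds.counts.shape == (6, 24)
        assert len(set(ds.cell_subject)) == 6
        arms = [ds.subject_arm[s] for s in sorted(set(ds.cell_subject))]
        assert arms.count("case") == 3 and arms.count("control") == 3

    def test_seed_determinism(self):
        a = generate_dataset(n_genes=5, n_per_arm=2, m=6, seed=3)
        b = generate_dataset(n_genes=5, n_per_arm=2, m=6, seed=3)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_zero_de_fraction_all_null(self):
        ds = generate_dataset(n_genes=5, n_per_arm=2, m=4, de_fraction=0.0, seed=1)
        assert all(d.de_type == "null" for d in ds.de_truth)

    def test_per_gene_specs_respected(self):
        specs = [DESpec("mean", 2.0), DESpec("null"), DESpec("variance", 2.0)]
        ds = generate_dataset(n_genes=3, n_per_arm=2, m=4, de_specs=specs, seed=2)
        assert [d.de_type for d in ds.de_truth] == ["mean", "null", "variance"]

    def test_spec_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(n_genes=2, n_per_arm=2, m=4, de_specs=[DESpec("null")], seed=0)

    def test_counts_are_nonnegative_integers(self):
        ds = generate_dataset(n_genes=4, n_per_arm=2, m=5, de_fraction=0.5, de_type="multimodal", size_factor=0.3, seed=4)
        assert ds.counts.dtype == np.int64
        assert np.all(ds.counts >= 0)
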