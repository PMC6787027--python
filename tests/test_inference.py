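"""Likelihood/prior building blocks and the Metropolis-within-Gibbs sampler."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

import fsthermo as ft
from fsthermo.inference import (
    SIGMA_FLOOR,
    log_likelihood,
    log_prior,
    metropolis_run,
    metropolis_run_kinetic,
    prepare_sigma,
    summarize,
)
from fsthermo.thermo import DEFAULT_CONSTANTS

from conftest import make_design

KT = DEFAULT_CONSTANTS.kT


class TestLogLikelihood:
    def test_zero_residual_is_pure_normalisation(self):
        d = make_design([[1]], ["x"])
        fs_model = float(expit(-1.0 / KT))
        val = log_likelihood([fs_model], [0.1], [1.0], d)
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi * 0.01))

    def test_one_sigma_residual_costs_half(self):
        d = make_design([[1]], ["x"])
        fs_model = float(expit(-1.0 / KT))
        base = log_likelihood([fs_model], [0.1], [1.0], d)
        off = log_likelihood([fs_model + 0.1], [0.1], [1.0], d)
        assert off == pytest.approx(base - 0.5)

    def test_wild_type_like_row_zero_residual(self):
        # single favourable wobble change: ΔG = −2.9 kJ/mol puts FS at ~0.7550
        d = make_design([[1]], ["A3 G·S→A·S"])
        fs = float(ft.fs_from_dg(-2.9))
        val = log_likelihood([fs], [0.02], [-2.9], d)
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi * 0.02**2))

    def test_kinetic_factor_enters_model(self):
        d = make_design([[0]], ["x"])
        # zero row: equilibrium FS=0.5, kappa=0.2 -> model 0.4
        val = log_likelihood([0.4], [0.1], [0.0], d, kappa=[0.2])
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi * 0.01))

    def test_nonpositive_sigma_rejected(self):
        d = make_design([[1]], ["x"])
        with pytest.raises(ValueError):
            log_likelihood([0.5], [0.0], [0.0], d)


def test_log_prior_box():
    cfg = ft.FitConfig(n_steps=1)
    assert log_prior(np.zeros(3), cfg) == 0.0
    assert log_prior([26.0], cfg) == -np.inf
    assert log_prior([25.0, -25.0], cfg) == 0.0  # closed interval


def test_prepare_sigma_floors_zeros():
    with pytest.warns(UserWarning, match="floored"):
        out = prepare_sigma([0.0, 0.02])
    assert out[0] == SIGMA_FLOOR and out[1] == 0.02
    with pytest.raises(ValueError):
        prepare_sigma([-0.1])


class TestSampler:
    def test_flat_likelihood_reproduces_prior(self):
        # wide proposals: the uniform box is invariant under any symmetric
        # proposal once the likelihood carries no information
        d = make_design([[1]], ["x"])
        cfg = ft.FitConfig(
            n_steps=60_000, n_chains=1, rng_seed=3, proposal_sigma=25.0
        )
        chain = metropolis_run([0.5], [1e6], d, cfg)
        x = chain.post_burn_in(0.2)[:, 0]
        ks = stats.kstest(x, stats.uniform(loc=-25, scale=50).cdf).statistic
        assert ks < 0.02

    def test_symmetric_data_centres_posterior_at_zero(self):
        d = make_design([[1]], ["x"])
        cfg = ft.FitConfig(n_steps=20_000, n_chains=1, rng_seed=1)
        chain = metropolis_run([0.5], [0.02], d, cfg)
        x = chain.post_burn_in(0.2)[:, 0]
        # |mean| within ~3 standard errors at this chain length
        assert abs(x.mean()) < 0.05

    def test_samples_respect_prior_box(self, study_chains):
        for chain in study_chains:
            assert chain.dg_samples.min() >= -25.0
            assert chain.dg_samples.max() <= 25.0

    def test_bit_reproducible_given_seed(self, study):
        d, fs, sigma = study["design"], study["fs"], study["sigma"]
        cfg = ft.FitConfig(n_steps=300, n_chains=1, rng_seed=42)
        a = metropolis_run(fs, sigma, d, cfg)
        b = metropolis_run(fs, sigma, d, cfg)
        np.testing.assert_array_equal(a.dg_samples, b.dg_samples)
        np.testing.assert_array_equal(a.accept_counts, b.accept_counts)

    def test_sum_identified_pair(self):
        # two variables only ever appear summed: the sum matches a 1-D grid
        # posterior, the difference stays prior-wide
        fs_target = 0.3
        sigma = 0.02
        d = make_design([[1, 1]], ["x", "y"])
        cfg = ft.FitConfig(n_steps=60_000, n_chains=1, rng_seed=9)
        chain = metropolis_run([fs_target], [sigma], d, cfg)
        samples = chain.post_burn_in(0.2)
        s = samples.sum(axis=1)
        diff = samples[:, 0] - samples[:, 1]

        # independent 1-D oracle for the sum: likelihood × segment-length
        # factor from marginalising the box uniform along the flat direction
        grid = np.linspace(-50.0, 50.0, 200_001)
        seg = np.clip(50.0 - np.abs(grid), 0.0, None)  # |{x ∈ box : s−x ∈ box}|
        fs_model = 1.0 / (1.0 + np.exp(grid / KT))
        logp = -((fs_target - fs_model) ** 2) / (2 * sigma**2)
        w = np.exp(logp - logp.max()) * seg
        w /= w.sum()
        mean_oracle = float((grid * w).sum())
        sd_oracle = float(np.sqrt(((grid - mean_oracle) ** 2 * w).sum()))

        assert s.mean() == pytest.approx(mean_oracle, abs=4 * sd_oracle / np.sqrt(200))
        assert s.std() == pytest.approx(sd_oracle, rel=0.2)
        assert diff.std() > 5.0  # prior-scale spread along the flat direction

    def test_no_free_variables_is_an_error(self, study):
        cfg = ft.FitConfig(
            n_steps=10,
            pinned_variables=frozenset(study["design"].col_labels),
        )
        with pytest.raises(ValueError, match="pinned"):
            metropolis_run(study["fs"], study["sigma"], study["design"], cfg)


class TestKineticSampler:
    def _tiny(self):
        # an informative variant, a zero row (FS = 0.5·(1−κ)) and its mirror
        d = make_design([[1], [0], [-1]], ["x"])
        fs = np.array([float(ft.fs_from_dg(-2.9)), 0.5, float(ft.fs_from_dg(2.9))])
        sigma = np.full(3, 0.02)
        return d, fs, sigma

    def test_equilibrium_data_puts_kappa_mode_in_lowest_bin(
        self, study_kinetic_chain
    ):
        chain, cfg = study_kinetic_chain
        summary = summarize([chain], cfg, bins=20)
        edges, density = summary.kappa_histogram
        assert np.argmax(density) == 0
        assert summary.kappa_mean < 0.05

    def test_nests_equilibrium_model(self):
        # κ̄ held at ~0 (negligible proposal width): the ΔG marginal must
        # reproduce the plain sampler's posterior
        d, fs, sigma = self._tiny()
        cfg_eq = ft.FitConfig(n_steps=40_000, n_chains=1, rng_seed=6)
        cfg_kin = ft.FitConfig(
            n_steps=40_000, n_chains=1, rng_seed=7,
            kinetic_enabled=True, kappa_init=1e-9, kappa_proposal_sigma=1e-12,
        )
        eq = metropolis_run(fs, sigma, d, cfg_eq).post_burn_in(0.2)[:, 0]
        kin = metropolis_run_kinetic(fs, sigma, d, cfg_kin).post_burn_in(0.2)[:, 0]
        ks = stats.ks_2samp(eq, kin).statistic
        assert ks < 0.05

    def test_kappa_samples_stay_in_unit_interval(self):
        d, fs, sigma = self._tiny()
        cfg = ft.FitConfig(
            n_steps=2_000, n_chains=1, rng_seed=8,
            kinetic_enabled=True, kappa_proposal_sigma=0.05,
        )
        chain = metropolis_run_kinetic(fs, sigma, d, cfg)
        assert np.all((chain.kappa_samples > 0) & (chain.kappa_samples < 1))

    def test_requires_kinetic_flag(self):
        d, fs, sigma = self._tiny()
        with pytest.raises(ValueError):
            metropolis_run_kinetic(fs, sigma, d, ft.FitConfig(n_steps=10))


class TestSummarize:
    def _chain(self, values, labels=("x",)):
        arr = np.asarray(values, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        return ft.ChainSamples(
            dg_samples=arr,
            variable_labels=list(labels),
            seed=0,
            accept_counts=np.zeros(arr.shape[1], dtype=int),
        )

    def test_constant_chain(self):
        cfg = ft.FitConfig(n_steps=4, burn_in_fraction=0.0)
        s = summarize([self._chain([3.0, 3.0, 3.0, 3.0])], cfg)
        assert s["x"] == (3.0, 0.0)
        edges, density = s.histograms[0]
        widths = np.diff(edges)
        assert float((density * widths).sum()) == pytest.approx(1.0)

    def test_pooling_after_burn_in(self):
        cfg = ft.FitConfig(n_steps=4, burn_in_fraction=0.5)
        s = summarize(
            [self._chain([0.0, 0.0, 2.0, 2.0]), self._chain([1.0, 1.0, 3.0, 3.0])],
            cfg,
        )
        assert s["x"][0] == pytest.approx(2.5)
        assert s.pooled_chains and s.n_samples == 4

    def test_pooled_equals_concatenation(self, study_chains, study_config):
        pooled = ft.pooled_samples(study_chains, study_config.burn_in_fraction)
        manual = np.concatenate(
            [c.post_burn_in(study_config.burn_in_fraction) for c in study_chains]
        )
        np.testing.assert_array_equal(pooled, manual)

    def test_histogram_densities_integrate_to_one(self, study_summary):
        for edges, density in study_summary.histograms:
            assert float((density * np.diff(edges)).sum()) == pytest.approx(1.0)

    def test_full_burn_in_rejected(self):
        cfg = ft.FitConfig(n_steps=2, burn_in_fraction=0.99)
        with pytest.raises(ValueError, match="burn-in"):
            summarize([self._chain([1.0, 2.0])], cfg)
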