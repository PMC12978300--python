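"""Likelihood, sampler and posterior summaries of the global fit."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from naquad.inference import (MCMCSettings, Model1Params, Model2Params,
                              ParameterBounds, PosteriorSummary,
                              RelaxationDataset, _kernel_loglik,
                              forward_model, log_likelihood, mcmc_fit,
                              site_fraction_table, split_rhat)
from naquad.synthetic import (default_model1_truth, default_model2_truth,
                              generate_dataset)

BOUNDS = ParameterBounds()


def dataset(model=1, noise=0.02, seed=0):
    make = default_model1_truth if model == 1 else default_model2_truth
    return generate_dataset(make(noise_level=noise, seed=seed))


class TestDatasetValidation:
    def test_missing_r2_rejected(self):
        df = dataset().observations
        df = df[~((df.observable == "R2") & (df.concentration_mM == 300.0)
                  & (df.temperature_K == 283.0))]
        with pytest.raises(ValueError, match="R1/R2 pair"):
            RelaxationDataset(observations=df.reset_index(drop=True))

    def test_nonpositive_sigma_rejected(self):
        df = dataset().observations.copy()
        df.loc[0, "sigma"] = 0.0
        with pytest.raises(ValueError, match="sigma"):
            RelaxationDataset(observations=df)

    def test_single_concentration_rejected(self):
        df = dataset().observations
        df = df[df.concentration_mM == 50.0].reset_index(drop=True)
        with pytest.raises(ValueError, match="concentrations"):
            RelaxationDataset(observations=df)

    def test_csv_round_trip(self, tmp_path):
        ds = dataset()
        ds.to_csv(tmp_path / "ds.csv", header_comment="prov")
        back = RelaxationDataset.from_csv(tmp_path / "ds.csv")
        pd.testing.assert_frame_equal(back.observations, ds.observations)


class TestLikelihood:
    def test_python_and_compiled_paths_agree(self):
        for model, ds, params in [
            (1, dataset(1), Model1Params(A_m=2.1e13, E_m=21.5e3,
                                         P_a={50.0: 0.05, 300.0: 0.4,
                                              700.0: 0.55}, chi=112e3)),
            (2, dataset(2), Model2Params(R_m=13e-10,
                                         P_a={50.0: 0.02, 300.0: 0.35,
                                              700.0: 0.6}, chi=109e3)),
        ]:
            slow = log_likelihood(params, ds)
            fast = _kernel_loglik(f"model{model}",
                                  params.to_theta(ds.concentrations), ds)
            assert fast == pytest.approx(slow, rel=1e-9)

    def test_truth_is_local_maximum_on_noiseless_data(self):
        ds = dataset(1, noise=0.0)
        truth = ds.meta["truth"]
        base = log_likelihood(truth, ds)
        concs = ds.concentrations
        theta = truth.to_theta(concs)
        for i in range(theta.size):
            for sign in (-1, 1):
                bumped = theta.copy()
                bumped[i] *= 1 + sign * 1e-3
                assert log_likelihood(
                    Model1Params.from_theta(bumped, concs), ds) < base

    def test_doubling_sigma_closed_form(self):
        ds = dataset(1, seed=5)
        params = ds.meta["truth"]
        y = ds.observations["value"].to_numpy()
        sig = ds.observations["sigma"].to_numpy()
        m = forward_model(params, ds)
        q = np.sum(((y - m) / sig) ** 2)
        n = y.size
        ll1 = log_likelihood(params, ds)
        ds2 = RelaxationDataset(
            observations=ds.observations.assign(sigma=2 * sig))
        ll2 = log_likelihood(params, ds2)
        # quadratic term shrinks to a quarter; normalization adds -n ln 2
        assert ll2 == pytest.approx(ll1 + 0.5 * q - q / 8 - n * math.log(2),
                                    rel=1e-12)

    def test_out_of_bounds_is_minus_infinity(self):
        ds = dataset(1)
        bad = Model1Params(A_m=1.6e13, E_m=20.9e3,
                           P_a={50.0: 0.03, 300.0: 0.38, 700.0: 0.59},
                           chi=150e3)  # above the 119 kHz bound
        assert log_likelihood(bad, ds) == -math.inf

    def test_invariant_under_row_reordering(self):
        ds = dataset(1)
        params = ds.meta["truth"]
        shuffled = RelaxationDataset(observations=ds.observations.sample(
            frac=1.0, random_state=3).reset_index(drop=True))
        assert log_likelihood(params, shuffled) == pytest.approx(
            log_likelihood(params, ds), rel=1e-12)

    def test_model2_tau_triple_from_fixed_surface_diffusion(self):
        params = Model2Params(R_m=14.5e-10, P_a={}, chi=117e3)
        d_s = {275.0: 7.4e-10, 283.0: 9.1e-10, 295.0: 10.6e-10}
        taus = [params.tau_m(t, d_s) * 1e9 for t in (275.0, 283.0, 295.0)]
        # printed values are rounded to two decimals
        assert taus == pytest.approx([0.47, 0.38, 0.33], abs=0.006)
        assert taus[0] > taus[1] > taus[2]


class TestSampler:
    def test_same_seed_gives_identical_chains(self):
        ds = dataset(1, seed=9)
        settings = MCMCSettings(seed=21, n_steps=4000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = mcmc_fit(ds, 1, settings)
            b = mcmc_fit(ds, 1, settings)
        np.testing.assert_array_equal(a.chain, b.chain)

    def test_different_seeds_differ(self):
        ds = dataset(1, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = mcmc_fit(ds, 1, MCMCSettings(seed=21, n_steps=4000))
            b = mcmc_fit(ds, 1, MCMCSettings(seed=22, n_steps=4000))
        assert not np.array_equal(a.chain, b.chain)

    def test_full_fit_recovers_generating_parameters(self, model1_fit):
        ds, post = model1_fit
        truth = ds.meta["truth"]
        assert post.means["P_a_50mM"] == pytest.approx(truth.P_a[50.0],
                                                       abs=0.015)
        assert post.means["P_a_700mM"] == pytest.approx(truth.P_a[700.0],
                                                        abs=0.04)
        assert post.means["chi"] == pytest.approx(truth.chi, rel=0.03)
        # well-identified components should mix cleanly
        for p in ("P_a_50mM", "P_a_300mM", "P_a_700mM", "chi"):
            assert post.rhat[p] < 1.1
        for p, a in post.acceptance_rate.items():
            assert 0.05 <= a <= 0.7

    def test_credible_intervals_ordered_and_cover_mean(self, model1_fit):
        _, post = model1_fit
        for p in post.param_names:
            lo, hi = post.ci99[p]
            assert lo < hi
            assert lo <= post.means[p] <= hi

    def test_boundary_proximity_diagnostic(self, model1_fit):
        _, post = model1_fit
        prox = post.boundary_proximity(BOUNDS)
        assert set(prox) == set(post.param_names)
        assert all(v >= 0 for v in prox.values())
        # chi at 117 kHz sits close to its 119 kHz prior edge in units of
        # posterior spread; fractions are far from their bounds
        assert prox["chi"] < prox["P_a_300mM"]


class TestSummaries:
    def _toy_posterior(self, pa_values):
        rng = np.random.default_rng(0)
        names = ["A_m", "E_m", "P_a_50mM", "P_a_300mM", "P_a_700mM", "chi"]
        n = 4000
        chain = np.empty((n, 6))
        chain[:, 0] = 1.6e13
        chain[:, 1] = 20.9e3
        for i, pa in enumerate(pa_values):
            chain[:, 2 + i] = pa + rng.normal(0, 1e-4, n)
        chain[:, 5] = 117e3
        return PosteriorSummary(
            model="model1", param_names=names, chain=chain, n_burn=0,
            acceptance_rate={p: 0.3 for p in names}, seed=0,
            concentrations=(50.0, 300.0, 700.0),
            temperatures=(275.0, 283.0, 295.0),
            surface_diffusion={275.0: 7.4e-10, 283.0: 9.1e-10,
                               295.0: 10.6e-10})

    def test_fraction_table_matches_printed_bookkeeping(self):
        # bulk fractions 0.97/0.62/0.41 -> micelle fractions 0/0.25/0.50
        post = self._toy_posterior([0.03, 0.38, 0.59])
        ds = dataset(1)
        table = site_fraction_table(post, ds).set_index("concentration_mM")
        assert table.loc[50.0, "micelle"] == 0.0
        assert table.loc[300.0, "micelle"] == pytest.approx(0.25, abs=0.01)
        assert table.loc[700.0, "micelle"] == pytest.approx(0.50, abs=0.01)

    def test_fraction_rows_sum_to_one(self, model1_fit):
        ds, post = model1_fit
        table = site_fraction_table(post, ds)
        sums = table["micelle"] + table["cluster"] + table["bulk"]
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_tau_m_summary_decreases_with_temperature(self, model1_fit):
        _, post = model1_fit
        taus = post.tau_m_summary()["tau_m_ns"].to_numpy()
        assert taus[0] > taus[1] > taus[2]


class TestSplitRhat:
    def test_near_one_for_stationary_chain(self):
        x = np.random.default_rng(4).standard_normal(20000)
        assert split_rhat(x) == pytest.approx(1.0, abs=0.01)

    def test_large_for_drifting_chain(self):
        x = np.concatenate([np.zeros(5000), np.ones(5000)])
        x += np.random.default_rng(5).normal(0, 0.1, x.size)
        assert split_rhat(x) > 1.5
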