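"""Likelihood, ML fit, bootstrap and germination estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from scipy.stats import poisson

from annualcoex import (
    CompetitionParams,
    bootstrap_fit,
    estimate_germination,
    fit_competition_model,
    make_design,
    nb_loglik,
    simulate_seed_production,
)


def _row(seeds, neighbour="none", density=0, focal="i", treatment="dry"):
    return {
        "pot": 1,
        "treatment": treatment,
        "focal": focal,
        "neighbour": neighbour,
        "neighbour_density": density,
        "seeds": seeds,
    }


class TestLoglik:
    def test_zero_count_closed_form(self):
        # P(Y=0) under NB2 is (theta/(theta+mu))^theta
        table = pd.DataFrame([_row(0)])
        lam, theta = 50.0, 3.0
        ll = nb_loglik((lam, 0.1, 0.1, theta), table)
        assert ll == pytest.approx(theta * np.log(theta / (theta + lam)), abs=1e-12)

    def test_poisson_limit_at_large_theta(self):
        # ten pots with modest counts: NB2 at theta=1e6 is numerically Poisson
        rows = [_row(s) for s in (18, 22, 20, 25, 17, 21, 19, 23, 20, 16)]
        table = pd.DataFrame(rows)
        ll_nb = nb_loglik((20.0, 0.1, 0.1, 1e6), table)
        ll_pois = poisson.logpmf(table.seeds.to_numpy(), 20.0).sum()
        assert abs(ll_nb - ll_pois) < 1e-3

    def test_additivity_under_row_duplication(self, small_table):
        params = (350.0, 0.25, 0.29, 5.0)
        one = nb_loglik(params, small_table, focal="i", treatment="dry")
        doubled = pd.concat([small_table, small_table], ignore_index=True)
        two = nb_loglik(params, doubled, focal="i", treatment="dry")
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_empty_subset_rejected(self, small_table):
        with pytest.raises(ValueError):
            nb_loglik((1, 0, 0, 1), small_table, focal="i", treatment="wet")


def grid_search_max(table, focal, treatment, lam_grid, alpha_grid, theta_grid):
    """Brute-force profile of the NB2 Beverton-Holt likelihood on a grid."""
    sub = table[(table.focal == focal) & (table.treatment == treatment)]
    y = sub.seeds.to_numpy(dtype=float)
    n = sub.neighbour_density.to_numpy(dtype=float)
    n_con = np.where(sub.neighbour == "conspecific", n, 0.0)
    n_het = np.where(sub.neighbour == "heterospecific", n, 0.0)

    best = -np.inf
    combos = np.array(np.meshgrid(lam_grid, alpha_grid, alpha_grid, theta_grid)).T.reshape(-1, 4)
    for chunk in np.array_split(combos, max(1, len(combos) // 20000)):
        lam, ai, aj, th = (chunk[:, k][:, None] for k in range(4))
        mu = lam / (1 + ai * n_con + aj * n_het)
        ll = (
            gammaln(y + th)
            - gammaln(th)
            - gammaln(y + 1)
            + th * np.log(th / (th + mu))
            + y * np.log(mu / (th + mu))
        ).sum(axis=1)
        best = max(best, float(ll.max()))
    return best


class TestFit:
    def test_fitted_loglik_beats_grid_search_oracle(self, small_table):
        fit = fit_competition_model(small_table, "i", "dry")
        lam0 = small_table[(small_table.focal == "i") & (small_table.neighbour_density == 0)].seeds.mean()
        oracle = grid_search_max(
            small_table,
            "i",
            "dry",
            np.linspace(0.5 * lam0, 2.0 * lam0, 25),
            np.geomspace(1e-3, 5.0, 21),
            np.geomspace(0.5, 50.0, 13),
        )
        assert fit.loglik >= oracle - 1e-4

    def test_noise_free_data_recovers_lambda(self, dry_params):
        # seed counts set exactly to the rounded Beverton-Holt mean
        design = make_design(treatments=("dry",))
        table = simulate_seed_production(design, dry_params, rng_seed=0)
        sub = table[table.focal == "i"].copy()
        n = sub.neighbour_density.to_numpy(dtype=float)
        n_con = np.where(sub.neighbour == "conspecific", n, 0)
        n_het = np.where(sub.neighbour == "heterospecific", n, 0)
        sub["seeds"] = np.round(
            dry_params.lambda_i / (1 + dry_params.alpha_ii * n_con + dry_params.alpha_ij * n_het)
        ).astype(int)
        fit = fit_competition_model(sub, "i", "dry")
        assert fit.estimates["lam"] == pytest.approx(dry_params.lambda_i, rel=0.02)

    def test_degenerate_design_errors_name_missing_cell(self, small_table):
        only_zero = small_table[small_table.neighbour_density == 0]
        with pytest.raises(ValueError, match="conspecific"):
            fit_competition_model(only_zero, "i", "dry")

    def test_row_permutation_invariance(self, small_table):
        fit_a = fit_competition_model(small_table, "i", "dry")
        shuffled = small_table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit_b = fit_competition_model(shuffled, "i", "dry")
        # identical optimum up to optimizer termination noise
        for k in fit_a.estimates:
            assert fit_a.estimates[k] == pytest.approx(fit_b.estimates[k], rel=1e-4)

    def test_covariance_symmetric_psd_and_converged(self, dry_table):
        fit = fit_competition_model(dry_table, "j", "dry")
        assert fit.converged
        assert np.allclose(fit.cov, fit.cov.T)
        assert np.linalg.eigvalsh(fit.cov).min() >= -1e-8
        assert fit.estimates["lam"] > 0 and fit.estimates["theta"] > 0


@pytest.fixture(scope="module")
def boots(dry_table):
    return bootstrap_fit(dry_table, "j", "dry", n_boot=50, rng_seed=100)


class TestBootstrap:
    def test_replicate_count_and_convergence_accounting(self, boots):
        assert len(boots.replicates) == 50
        assert boots.n_excluded == int((~boots.replicates.converged).sum())

    def test_bootstrap_se_order_of_magnitude(self, boots):
        # reference bootstrap SE for lambda_j (dry) is 57.4; simulated data
        # at the same design should land within a factor of two
        se = boots.sd()["lam"]
        assert 57.4 / 2 < se < 57.4 * 2

    def test_determinism_under_seed(self, dry_table, boots):
        again = bootstrap_fit(dry_table, "j", "dry", n_boot=50, rng_seed=100)
        pd.testing.assert_frame_equal(boots.replicates, again.replicates)

    def test_bootstrap_mean_tracks_full_data_estimate(self, dry_table, boots):
        full = fit_competition_model(dry_table, "j", "dry")
        assert abs(boots.mean()["lam"] - full.estimates["lam"]) < boots.sd()["lam"]

    def test_single_replicate_rejected(self, dry_table):
        with pytest.raises(ValueError):
            bootstrap_fit(dry_table, "i", "dry", n_boot=1)


class TestGerminationEstimate:
    def test_pooled_fraction_and_se(self):
        trials = pd.DataFrame(
            {"species": "i", "pot": range(144), "sown": 3, "germinated": [2] * 144}
        )
        trials.loc[:0, "germinated"] = 3  # 289 of 432
        est = estimate_germination(trials)["i"]
        assert est.g == pytest.approx(289 / 432)
        assert round(est.g, 3) == 0.669
        assert est.se == pytest.approx(np.sqrt(est.g * (1 - est.g) / 432))

    @pytest.mark.parametrize("germ,expected", [(3, 1.0), (0, 0.0)])
    def test_degenerate_fractions_have_zero_se(self, germ, expected):
        trials = pd.DataFrame({"species": "j", "pot": range(144), "sown": 3, "germinated": germ})
        est = estimate_germination(trials)["j"]
        assert est.g == expected and est.se == 0.0

    def test_zero_sown_rejected(self):
        trials = pd.DataFrame({"species": "i", "pot": [1], "sown": [0], "germinated": [0]})
        with pytest.raises(ValueError):
            estimate_germination(trials)
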