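"""Coexistence algebra: published-value checks, identities, symmetries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from annualcoex import (
    classify_outcome,
    competitive_response_ratio,
    demographic_ratio,
    fitness_ratio,
    invasion_growth_rate,
    niche_overlap,
    summarize_pair,
)
from annualcoex.fitting import CompetitionFit
from annualcoex.metrics import BOUNDARY_TOL

alphas = st.floats(min_value=1e-3, max_value=5.0)
lambdas = st.floats(min_value=1.5, max_value=2000.0)


def _fit(focal, treatment, lam, a_intra, a_inter):
    return CompetitionFit(
        focal=focal,
        treatment=treatment,
        estimates={"lam": lam, "alpha_intra": a_intra, "alpha_inter": a_inter, "theta": 5.0},
        se={k: 0.0 for k in ("lam", "alpha_intra", "alpha_inter", "theta")},
        cov=np.zeros((4, 4)),
        loglik=0.0,
        converged=True,
        n_obs=72,
        n_starts=3,
    )


class TestPointValues:
    """The derived quantities reproduce the published two-decimal table."""

    def test_niche_overlap(self, dry_estimates, wet_estimates):
        assert round(niche_overlap(0.25, 0.29, 0.73, 0.45), 2) == 0.85
        assert round(niche_overlap(0.37, 0.27, 0.47, 0.42), 2) == 0.81

    def test_demographic_ratio(self):
        assert round(demographic_ratio(650.0, 365.9), 2) == 1.78
        assert round(demographic_ratio(327.4, 391.23), 2) == 0.84
        assert demographic_ratio(5.0, 5.0) == 1.0

    def test_competitive_response_ratio(self):
        assert round(competitive_response_ratio(0.25, 0.29, 0.73, 0.45), 2) == 0.47
        assert round(competitive_response_ratio(0.37, 0.27, 0.47, 0.42), 2) == 0.71
        assert competitive_response_ratio(0.3, 0.3, 0.3, 0.3) == 1.0

    def test_fitness_ratio_unrounded_components(self, dry_estimates, wet_estimates):
        k_dry = fitness_ratio(**dry_estimates)
        k_wet = fitness_ratio(**wet_estimates)
        assert k_dry == pytest.approx(0.836, abs=0.01)
        assert k_wet == pytest.approx(0.595, abs=0.01)

    def test_invasion_growth_rates(self):
        assert round(invasion_growth_rate(391.23, 327.4, 0.27, 0.47), 2) == 2.08
        assert round(invasion_growth_rate(327.4, 391.23, 0.42, 0.37), 2) == 0.74
        assert round(invasion_growth_rate(650.0, 365.9, 0.45, 0.25), 2) == 0.99
        assert invasion_growth_rate(365.9, 650.0, 0.29, 0.73) == pytest.approx(1.414, abs=0.02)

    def test_no_interspecific_suppression_returns_lambda(self):
        assert invasion_growth_rate(123.4, 50.0, 0.0, 0.5) == 123.4


class TestDomainErrors:
    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            niche_overlap(0.0, 0.3, 0.3, 0.3)
        with pytest.raises(ValueError):
            competitive_response_ratio(0.3, 0.3, -0.1, 0.3)

    def test_nonreplacing_population_rejected(self):
        with pytest.raises(ValueError):
            demographic_ratio(0.9, 365.9)

    def test_resident_without_equilibrium_rejected(self):
        with pytest.raises(ValueError):
            invasion_growth_rate(100.0, 50.0, 0.3, 0.0)

    def test_array_input_yields_nan_not_error(self):
        r = niche_overlap(np.array([0.25, -1.0]), 0.29, 0.73, 0.45)
        assert np.isfinite(r[0]) and np.isnan(r[1])


class TestClassification:
    @pytest.mark.parametrize(
        "rho,kappa,label",
        [
            (0.8456, 0.8355, "i_excludes_j"),  # dry reference column
            (0.8075, 0.5950, "i_excludes_j"),  # wet reference column
            (0.5, 1.0, "coexistence"),
            (0.5, 0.3, "i_excludes_j"),
            (0.5, 2.5, "j_excludes_i"),
            (1.25, 1.0, "priority_effect"),
        ],
    )
    def test_inequality_logic(self, rho, kappa, label):
        assert classify_outcome(rho, kappa) == label

    def test_boundary_is_indeterminate(self):
        assert classify_outcome(0.7, 0.7 + BOUNDARY_TOL / 10) == "indeterminate"
        assert classify_outcome(1.0, 1.0) == "indeterminate"

    @given(
        li=lambdas, lj=lambdas, aii=alphas, aij=alphas, ajj=alphas, aji=alphas
    )
    def test_classification_agrees_with_mutual_invasibility(self, li, lj, aii, aij, ajj, aji):
        rho = niche_overlap(aii, aij, ajj, aji)
        kappa = fitness_ratio(li, lj, aii, aij, ajj, aji)
        igr_i = invasion_growth_rate(li, lj, aij, ajj)
        igr_j = invasion_growth_rate(lj, li, aji, aii)
        if min(abs(igr_i - 1), abs(igr_j - 1)) < 1e-9:
            return  # boundary case, classification deliberately indeterminate
        label = classify_outcome(rho, kappa)
        expected = {
            (True, True): "coexistence",
            (True, False): "i_excludes_j",
            (False, True): "j_excludes_i",
            (False, False): "priority_effect",
        }[(igr_i > 1, igr_j > 1)]
        if label != "indeterminate":
            assert label == expected


class TestSymmetries:
    @given(li=lambdas, lj=lambdas, aii=alphas, aij=alphas, ajj=alphas, aji=alphas)
    def test_species_swap_maps_kappa_to_its_inverse(self, li, lj, aii, aij, ajj, aji):
        rho = niche_overlap(aii, aij, ajj, aji)
        rho_sw = niche_overlap(ajj, aji, aii, aij)
        assert rho_sw == pytest.approx(rho, rel=1e-12)
        k = fitness_ratio(li, lj, aii, aij, ajj, aji)
        k_sw = fitness_ratio(lj, li, ajj, aji, aii, aij)
        assert k_sw == pytest.approx(1.0 / k, rel=1e-9)

    @given(li=lambdas, lj=lambdas, aii=alphas, aij=alphas, ajj=alphas, aji=alphas)
    def test_fitness_ratio_is_exact_product_of_components(self, li, lj, aii, aij, ajj, aji):
        k = fitness_ratio(li, lj, aii, aij, ajj, aji)
        prod = demographic_ratio(lj, li) * competitive_response_ratio(aii, aij, ajj, aji)
        assert k == prod  # identical float expression by construction

    def test_equal_alphas_mean_no_stabilization(self):
        assert niche_overlap(0.4, 0.4, 0.9, 0.9) == pytest.approx(1.0)


class TestSummarizePair:
    def test_reference_dry_column_summary(self, dry_estimates):
        e = dry_estimates
        fit_i = _fit("i", "dry", e["lambda_i"], e["alpha_ii"], e["alpha_ij"])
        fit_j = _fit("j", "dry", e["lambda_j"], e["alpha_jj"], e["alpha_ji"])
        s = summarize_pair(fit_i, fit_j, se_method="taylor1")
        r = s.rounded(2)
        assert r["rho"] == 0.85
        assert r["demographic_ratio"] == 1.78
        assert r["competitive_response_ratio"] == 0.47
        assert abs(s.values["fitness_ratio"] - 0.83) <= 0.01
        assert s.outcome == "i_excludes_j"

    def test_symmetric_species_flagged_indeterminate(self):
        fit_i = _fit("i", "wet", 100.0, 0.5, 0.5)
        fit_j = _fit("j", "wet", 100.0, 0.5, 0.5)
        s = summarize_pair(fit_i, fit_j, se_method="taylor1")
        assert s.values["rho"] == pytest.approx(1.0)
        assert s.values["fitness_ratio"] == pytest.approx(1.0)
        assert s.outcome == "indeterminate"

    def test_treatment_mismatch_rejected(self):
        with pytest.raises(ValueError, match="treatment"):
            summarize_pair(_fit("i", "dry", 100, 0.5, 0.5), _fit("j", "wet", 100, 0.5, 0.5))
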