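"""Discrete-grid Bayesian MAP ratio estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from oscimap.bayes import (
    CandidateGrid,
    LikelihoodSpec,
    Prior,
    default_dbp_grid,
    default_sbp_grid,
    estimate_bp_bayes,
    likelihood,
    make_grid,
    map_ratio,
    posterior,
    reference_ratio,
    uniform_prior,
)
from oscimap.errors import GridError
from oscimap.maa import FixedRatios, maa_estimate

# the five systolic reference ratios printed for one example subject
EXAMPLE_SBP_RATIOS = (0.91, 0.81, 0.97, 0.74, 0.75)


def nearest_candidate(y, grid):
    """Brute-force oracle: smallest candidate at minimal |y - c|."""
    d = np.abs(grid.values - y)
    return float(grid.values[int(np.argmin(d))])  # argmin takes first = smaller


class TestGrid:
    def test_default_sbp_grid_has_31_candidates(self):
        g = make_grid(0.65, 0.95, 0.01)
        assert g.K == 31
        assert g.values[0] == pytest.approx(0.65)
        assert g.values[-1] == 0.95

    def test_default_dbp_grid_endpoints_exact(self):
        g = make_grid(0.30, 0.60, 0.01)
        assert g.K == 31
        assert g.values[0] == pytest.approx(0.30)
        assert g.values[-1] == 0.60

    def test_non_commensurate_bounds_rejected(self):
        with pytest.raises(GridError, match="not commensurate"):
            make_grid(0.5, 0.5001, 0.01)

    def test_uniform_prior_elements(self):
        g = default_sbp_grid()
        p = uniform_prior(g)
        assert np.allclose(p.probabilities, 1 / 31)
        assert round(p.probabilities[0], 3) == 0.032
        assert p.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k", [1, 4])
    def test_uniform_prior_small_grids(self, k):
        g = make_grid(0.5, 0.5 + 0.01 * (k - 1), 0.01) if k > 1 else CandidateGrid(
            values=np.array([0.5]), step=0.01
        )
        p = uniform_prior(g)
        assert np.allclose(p.probabilities, 1.0 / k)
        assert p.probabilities.sum() == pytest.approx(1.0)


class TestLikelihood:
    def test_gaussian_density_at_mean(self):
        spec = LikelihoodSpec("gaussian", 0.1)
        assert likelihood(0.8, 0.8, spec) == pytest.approx(1 / (np.sqrt(2 * np.pi) * 0.1))

    def test_laplacian_density_at_mode(self):
        spec = LikelihoodSpec("laplacian", 0.1)
        assert likelihood(0.8, 0.8, spec) == pytest.approx(1 / (np.sqrt(2) * 0.1))

    def test_gaussian_one_sigma_away_matches_scipy(self):
        spec = LikelihoodSpec("gaussian", 0.1)
        val = likelihood(0.9, 0.8, spec)
        assert val == pytest.approx(3.989422804 * np.exp(-0.5), rel=1e-6)
        assert val == pytest.approx(sps.norm.pdf(0.9, loc=0.8, scale=0.1), rel=1e-12)

    def test_laplacian_matches_scipy_parameterization(self):
        # variance sigma^2 corresponds to scipy's laplace scale sigma/sqrt(2)
        spec = LikelihoodSpec("laplacian", 0.1)
        val = likelihood(0.73, 0.8, spec)
        assert val == pytest.approx(
            sps.laplace.pdf(0.73, loc=0.8, scale=0.1 / np.sqrt(2)), rel=1e-12
        )

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            LikelihoodSpec("gaussian", -0.1)
        with pytest.raises(ValueError):
            LikelihoodSpec("gaussian", 0.5)  # outside validated range
        LikelihoodSpec("gaussian", 0.5, validate_sigma=False)  # explicit override


class TestPosterior:
    def test_symmetric_candidates_split_evenly(self):
        g = make_grid(0.70, 0.80, 0.10)
        post = posterior(0.75, g, uniform_prior(g), LikelihoodSpec("gaussian", 0.1))
        assert np.allclose(post.probabilities, [0.5, 0.5])

    def test_two_candidate_closed_form(self):
        # P(c1 | y=c1) = 1 / (1 + exp(-1/2)) for candidates one sigma apart
        g = make_grid(0.70, 0.80, 0.10)
        post = posterior(0.70, g, uniform_prior(g), LikelihoodSpec("gaussian", 0.1))
        expected = 1.0 / (1.0 + np.exp(-0.5))
        assert post.probabilities[0] == pytest.approx(expected, abs=1e-9)
        # brute-force normalization agrees
        lik = np.array([likelihood(0.70, c, LikelihoodSpec("gaussian", 0.1)) for c in g.values])
        brute = lik / lik.sum()
        assert np.allclose(post.probabilities, brute)

    def test_degenerate_prior_dominates(self):
        g = make_grid(0.70, 0.80, 0.10)
        prior = Prior(probabilities=np.array([1.0, 0.0]))
        for y in (0.70, 0.80, 1.2):
            post = posterior(y, g, prior, LikelihoodSpec("gaussian", 0.1))
            assert np.allclose(post.probabilities, [1.0, 0.0])

    def test_normalization_never_underflows(self):
        # far-out y with tiny sigma: densities underflow, posterior must not
        g = default_sbp_grid()
        post = posterior(30.0, g, uniform_prior(g), LikelihoodSpec("gaussian", 0.02))
        assert np.isfinite(post.probabilities).all()
        assert post.probabilities.sum() == pytest.approx(1.0, abs=1e-10)
        assert post.probabilities.max() > 0

    @given(
        y=st.floats(0.3, 1.3),
        sigma=st.sampled_from([0.02, 0.05, 0.10, 0.20]),
        family=st.sampled_from(["gaussian", "laplacian"]),
    )
    @settings(max_examples=100, deadline=None)
    def test_normalization_property(self, y, sigma, family):
        g = default_sbp_grid()
        post = posterior(y, g, uniform_prior(g), LikelihoodSpec(family, sigma))
        assert post.probabilities.sum() == pytest.approx(1.0, abs=1e-10)
        assert (post.probabilities >= 0).all()


class TestMapRatio:
    def test_grid_point_reference_returns_itself(self):
        est = map_ratio(0.78, default_sbp_grid())
        assert est.map_ratio == pytest.approx(0.78)

    def test_reference_beyond_grid_hits_boundary(self):
        for family in ("gaussian", "laplacian"):
            est = map_ratio(0.97, default_sbp_grid(), spec=LikelihoodSpec(family))
            assert est.map_ratio == 0.95

    def test_example_subject_ratios_map_to_nearest_candidates(self):
        g = default_sbp_grid()
        for y in EXAMPLE_SBP_RATIOS:
            est = map_ratio(y, g)
            assert est.map_ratio == pytest.approx(nearest_candidate(y, g))

    def test_midway_tie_breaks_to_smaller_candidate(self):
        g = make_grid(0.65, 0.95, 0.01)
        est = map_ratio(0.655, g)
        assert est.map_ratio == pytest.approx(0.65)

    def test_posterior_peak_is_at_map(self):
        est = map_ratio(0.83, default_sbp_grid())
        probs = est.posterior.probabilities
        idx = int(np.argmax(probs))
        assert est.posterior.grid.values[idx] == pytest.approx(est.map_ratio)

    @given(y=st.floats(0.5, 1.1), sigma=st.sampled_from([0.02, 0.10, 0.20]),
           family=st.sampled_from(["gaussian", "laplacian"]))
    @settings(max_examples=150, deadline=None)
    def test_map_equals_nearest_candidate(self, y, sigma, family):
        """With a uniform prior both families are monotone in |y - c|,
        so the MAP is the nearest grid candidate for any sigma."""
        g = default_sbp_grid()
        est = map_ratio(y, g, spec=LikelihoodSpec(family, sigma))
        assert est.map_ratio == pytest.approx(nearest_candidate(y, g))

    def test_sigma_leaves_argmax_unchanged(self):
        g = default_sbp_grid()
        for y in (0.661, 0.733, 0.912, 1.02):
            maps = {map_ratio(y, g, spec=LikelihoodSpec("gaussian", s)).map_ratio
                    for s in (0.02, 0.05, 0.10, 0.20)}
            assert len(maps) == 1

    def test_concentrated_prior_overrides_data(self):
        g = default_sbp_grid()
        probs = np.zeros(g.K)
        probs[7] = 1.0
        prior = Prior(probabilities=probs)
        for y in (0.65, 0.80, 0.95):
            est = map_ratio(y, g, prior=prior)
            assert est.map_ratio == pytest.approx(g.values[7])


class TestReferenceRatio:
    def test_on_point_lookup(self, three_point_envelope):
        ref = reference_ratio(three_point_envelope, 120.0, 65.0)
        assert ref.y_s == pytest.approx(0.70, abs=0.01)
        assert ref.y_d == pytest.approx(0.45, abs=0.01)
        assert not ref.ordering_violated

    def test_apex_reference_gives_unit_ratio(self, three_point_envelope):
        env = three_point_envelope
        ref = reference_ratio(env, env.pressure_at_max, 65.0)
        assert ref.y_s == pytest.approx(1.0, rel=1e-6)

    def test_synthetic_truth_recovered(self, clean_envelope, clean_truth):
        ref = reference_ratio(clean_envelope, clean_truth.true_sbp, clean_truth.true_dbp)
        assert ref.y_s == pytest.approx(clean_truth.true_ratio_s, abs=0.02)
        assert ref.y_d == pytest.approx(clean_truth.true_ratio_d, abs=0.02)


class TestEstimateBpBayes:
    def test_map_ratios_equal_fixed_reduces_to_maa(self, clean_envelope):
        g_s = make_grid(0.65, 0.95, 0.01)
        g_d = make_grid(0.30, 0.60, 0.01)
        r_s = map_ratio(0.70, g_s)
        r_d = map_ratio(0.45, g_d)
        bayes_est = estimate_bp_bayes(clean_envelope, r_s, r_d)
        maa_est = maa_estimate(clean_envelope, FixedRatios(0.70, 0.45))
        assert bayes_est.sbp == pytest.approx(maa_est.sbp)
        assert bayes_est.dbp == pytest.approx(maa_est.dbp)
        assert bayes_est.method == "MAABG"

    def test_noiseless_measurement_recovers_truth(self, clean_envelope, clean_truth):
        ref = reference_ratio(clean_envelope, clean_truth.true_sbp, clean_truth.true_dbp)
        r_s = map_ratio(ref.y_s, default_sbp_grid())
        r_d = map_ratio(ref.y_d, default_dbp_grid())
        est = estimate_bp_bayes(clean_envelope, r_s, r_d)
        assert est.sbp == pytest.approx(clean_truth.true_sbp, abs=3.0)
        assert est.dbp == pytest.approx(clean_truth.true_dbp, abs=3.0)

    def test_gaussian_and_laplacian_estimates_identical(self, clean_envelope, clean_truth):
        ref = reference_ratio(clean_envelope, clean_truth.true_sbp, clean_truth.true_dbp)
        ests = {}
        for fam in ("gaussian", "laplacian"):
            spec = LikelihoodSpec(fam)
            r_s = map_ratio(ref.y_s, default_sbp_grid(), spec=spec)
            r_d = map_ratio(ref.y_d, default_dbp_grid(), spec=spec)
            ests[fam] = estimate_bp_bayes(clean_envelope, r_s, r_d)
        g, l = ests["gaussian"], ests["laplacian"]
        assert (g.sbp, g.dbp) == (l.sbp, l.dbp)
        assert g.method == "MAABG" and l.method == "MAABL"
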