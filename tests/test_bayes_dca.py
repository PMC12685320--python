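"""Conjugate posterior sampling, decision curves and P(useful)."""

import numpy as np
import pytest
from scipy import stats

from triagedca import (
    ConfusionCounts,
    PosteriorDraws,
    PriorSpec,
    ValidationError,
    credible_interval,
    dca_curve,
    dca_curve_from_counts,
    nb_unreferred_rate,
    pathway_seed,
    prob_useful,
    sample_posterior,
)
from triagedca.synthetic_data import generate_counts


def make_counts(tp, fp, tn, fn):
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn,
                           n_total=tp + fp + tn + fn, n_cancer=tp + fn)


class TestSamplePosterior:
    def test_draw_means_match_closed_form_beta_means(self, overall_counts):
        """Empirical means agree with conjugate Beta means within 4 MC SE."""
        n_draws = 10_000
        draws = sample_posterior(overall_counts, n_draws=n_draws, seed=7)
        shapes = PriorSpec.uniform().posterior_shapes(overall_counts)
        for name, arr in (("se", draws.se), ("sp", draws.sp), ("prev", draws.prev)):
            a, b = shapes[name]
            mean = a / (a + b)
            sd = stats.beta(a, b).std()
            assert abs(arr.mean() - mean) < 4 * sd / np.sqrt(n_draws), name

    def test_zero_counts_give_prior_only_uniform_draws(self):
        counts = ConfusionCounts(tp=0, fp=0, tn=0, fn=0, n_total=0, n_cancer=0)
        draws = sample_posterior(counts, n_draws=20_000, seed=3)
        for arr in (draws.se, draws.sp, draws.prev):
            assert abs(arr.mean() - 0.5) < 0.01
            assert abs(arr.var() - 1 / 12) < 0.01

    def test_identical_seed_reproduces_bitwise(self, overall_counts):
        a = sample_posterior(overall_counts, n_draws=500, seed=11)
        b = sample_posterior(overall_counts, n_draws=500, seed=11)
        assert np.array_equal(a.se, b.se)
        assert np.array_equal(a.sp, b.sp)
        assert np.array_equal(a.prev, b.prev)

    def test_nonpositive_n_draws_rejected(self, overall_counts):
        with pytest.raises(ValidationError):
            sample_posterior(overall_counts, n_draws=0)

    def test_mismatched_draw_lengths_rejected(self):
        with pytest.raises(ValidationError):
            PosteriorDraws(se=np.ones(3) / 2, sp=np.ones(2) / 2, prev=np.ones(3) / 2)

    def test_pathway_seed_stable_and_label_dependent(self):
        assert pathway_seed(42, "lung") == pathway_seed(42, "lung")
        assert pathway_seed(42, "lung") != pathway_seed(42, "gynecologic")
        assert 0 <= pathway_seed(42, "lung") < 2**31


class TestCredibleInterval:
    def test_constant_sequence_collapses(self):
        assert credible_interval([4.2] * 10) == (4.2, 4.2)

    def test_uniform_draws_recover_analytic_quantiles(self):
        rng = np.random.default_rng(0)
        lo, hi = credible_interval(rng.uniform(size=10_000), 0.95)
        assert lo == pytest.approx(0.025, abs=0.01)
        assert hi == pytest.approx(0.975, abs=0.01)

    def test_linear_interpolation_rule_on_1_to_100(self):
        lo, hi = credible_interval(np.arange(1, 101), 0.5)
        assert (lo, hi) == pytest.approx((25.75, 75.25))

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            credible_interval([])


class TestDcaCurve:
    def test_perfect_test_curve_flat_at_1_minus_prev(self):
        counts = make_counts(tp=10_000, fp=0, tn=90_000, fn=0)
        curve = dca_curve_from_counts(counts, thresholds=[0.01, 0.03, 0.07],
                                      n_draws=4000, seed=5)
        expected = (1 - counts.prevalence) * 100_000
        assert np.allclose(curve["nb_unreferred_mean"], expected, rtol=0.02)

    def test_overall_fixture_net_tns_near_18000(self, overall_counts):
        curve = dca_curve_from_counts(overall_counts, thresholds=[0.03],
                                      n_draws=10_000, seed=1)
        assert curve["nb_unreferred_mean"].iloc[0] == pytest.approx(18_000, rel=0.05)

    def test_percentile_ordering(self, overall_counts):
        curve = dca_curve_from_counts(overall_counts, n_draws=2000, seed=2)
        assert (curve["nb_unreferred_lo"] <= curve["nb_unreferred_mean"]).all()
        assert (curve["nb_unreferred_mean"] <= curve["nb_unreferred_hi"]).all()
        assert (curve["nb_referred_lo"] <= curve["nb_referred_mean"]).all()
        assert (curve["nb_referred_mean"] <= curve["nb_referred_hi"]).all()

    def test_same_inputs_reproduce_identical_curve(self, overall_counts):
        a = dca_curve_from_counts(overall_counts, n_draws=1000, seed=9)
        b = dca_curve_from_counts(overall_counts, n_draws=1000, seed=9)
        assert a.equals(b)

    def test_out_of_range_threshold_propagates(self, overall_counts):
        draws = sample_posterior(overall_counts, n_draws=10, seed=0)
        with pytest.raises(ValidationError):
            dca_curve(draws, thresholds=[0.0])

    def test_per_threshold_resampling_flag_runs(self, overall_counts):
        curve = dca_curve_from_counts(overall_counts, thresholds=[0.02, 0.03],
                                      n_draws=2000, seed=4, shared_draws=False)
        assert len(curve) == 2

    def test_posterior_mean_matches_plugin_at_large_n(self):
        """With a million patients the posterior concentrates on the plug-in."""
        counts = generate_counts(10**6, 0.067, 0.663, 0.984, seed=12)
        curve = dca_curve_from_counts(counts, thresholds=[0.03],
                                      n_draws=4000, seed=13)
        plugin = nb_unreferred_rate(counts.sensitivity, counts.specificity,
                                    counts.prevalence, 0.03) * 100_000
        assert curve["nb_unreferred_mean"].iloc[0] == pytest.approx(plugin, rel=0.02)


class TestProbUseful:
    def test_perfect_test_is_almost_surely_useful(self):
        counts = make_counts(tp=500, fp=0, tn=4500, fn=0)
        draws = sample_posterior(counts, n_draws=4000, seed=21)
        assert prob_useful(draws, 0.03) > 0.99

    def test_overall_fixture_exceeds_99_4_percent(self, overall_counts):
        draws = sample_posterior(overall_counts, n_draws=10_000, seed=1)
        assert prob_useful(draws, 0.03) >= 0.994

    def test_equal_on_both_scales_draw_by_draw(self, overall_counts):
        draws = sample_posterior(overall_counts, n_draws=10_000, seed=8)
        for t in (0.01, 0.03, 0.07):
            assert prob_useful(draws, t, scale="referred") == prob_useful(
                draws, t, scale="unreferred"
            )

    def test_matches_dense_grid_quadrature_on_tiny_counts(self):
        """Independent oracle: 200^3 midpoint quadrature of the Beta joint."""
        counts = make_counts(tp=1, fp=1, tn=1, fn=1)  # N = 4
        t = 0.03
        shapes = PriorSpec.uniform().posterior_shapes(counts)
        m = 200
        edges = np.linspace(0.0, 1.0, m + 1)
        mid = (edges[:-1] + edges[1:]) / 2
        w_se = stats.beta(*shapes["se"]).pdf(mid) / m
        w_sp = stats.beta(*shapes["sp"]).pdf(mid) / m
        w_p = stats.beta(*shapes["prev"]).pdf(mid) / m
        se = mid[:, None, None]
        sp = mid[None, :, None]
        p = mid[None, None, :]
        nb_test = se * p - t / (1 - t) * (1 - p) * (1 - sp)
        nb_all = p - t / (1 - t) * (1 - p)
        useful = nb_test > np.maximum(nb_all, 0.0)
        weights = w_se[:, None, None] * w_sp[None, :, None] * w_p[None, None, :]
        oracle = float((useful * weights).sum())

        draws = sample_posterior(counts, n_draws=200_000, seed=17)
        assert prob_useful(draws, t) == pytest.approx(oracle, abs=0.01)


class TestCalibration:
    def test_credible_interval_coverage_near_nominal(self):
        """95% CrIs for (Se, Sp, p) cover the truth ~95% of the time.

        400 replicate cohorts of 2,000 patients drawn from the binomial model
        at a realistic operating point; coverage must land in [91%, 99%].
        """
        true = {"se": 0.663, "sp": 0.984, "prev": 0.067}
        n_rep, n_draws = 400, 2000
        hits = {k: 0 for k in true}
        master = np.random.SeedSequence(2024)
        for child in master.spawn(n_rep):
            seed = int(child.generate_state(1)[0] % 2**31)
            counts = generate_counts(2000, true["prev"], true["se"], true["sp"],
                                     seed=seed)
            draws = sample_posterior(counts, n_draws=n_draws, seed=seed + 1)
            for key, arr in (("se", draws.se), ("sp", draws.sp),
                             ("prev", draws.prev)):
                lo, hi = credible_interval(arr, 0.95)
                hits[key] += lo <= true[key] <= hi
        for key, count in hits.items():
            assert 0.91 <= count / n_rep <= 0.99, (key, count / n_rep)
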